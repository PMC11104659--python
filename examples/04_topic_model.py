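"""Fit collapsed-Gibbs LDA on an LDA-generated corpus and pick K.

The corpus is drawn from the exact LDA generative process with 5 topics, so
the fitted topic-word rows should align with the true ones and validation
perplexity should bottom out at K=5.
"""

from cravingminer import synthetic_data as sd
from cravingminer import topic_model as tm

bow, phi_true, _ = sd.generate_topic_corpus(
    K=5, V=200, D=1000, doc_len=80, alpha=0.3, beta=0.05, seed=0
)
model = tm.fit(bow, tm.LDAConfig(K=5, iterations=300, burn_in=200, thin=10, seed=0))
summary = tm.summarize(model, bow, top_n=8)
print("fitted topics (sorted by NPMI coherence; word share = % of vocabulary")
print("whose most probable topic this is):")
for _, row in summary.table.iterrows():
    words = " ".join(row["top_words"][:6])
    print(f"  topic {row['topic']}: coh={row['coherence']:+.3f} "
          f"share={row['word_share_pct']:5.1f}%  {words} ...")

selection = tm.select_num_topics(
    bow, [2, 5, 10], base_config={"iterations": 300, "burn_in": 200, "thin": 10}, seed=0
)
print("\nmodel selection (lowest validation perplexity wins):")
print(selection.to_string(index=False))
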