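"""Generate a synthetic forum corpus and run the craving filter on it.

The generator plants craving mentions (the six seed synonyms and their
inflected/compound forms) in ~16% of posts; the word-form pattern should
retrieve almost exactly that planted subset.
"""

from cravingminer import craving_filter as cf
from cravingminer import synthetic_data as sd
from cravingminer.corpus_io import LabeledPost

posts, truth = sd.generate_corpus(sd.GeneratorConfig(seed=1, n_authors=2000))
print(f"corpus: {len(posts)} posts by 2000 authors")

pattern = cf.compile_pattern(cf.Lexicon("craving", cf.SEED_TERMS))
result = cf.filter_corpus(posts, pattern)
print(f"retrieved {len(result.craving_posts)} craving posts "
      f"({100 * result.rate:.1f}% of the corpus; planted rate was 16%)")

predictions = {p.id: False for p in posts}
for p in result.craving_posts:
    predictions[p.id] = True
labels = [LabeledPost(p.id, truth.craving[p.id]) for p in posts]
ev = cf.evaluate(predictions, labels)
print(f"against ground truth: accuracy={ev.accuracy}, "
      f"precision={ev.precision}, recall={ev.recall}")
print("(injection is collision-free, so precision and recall are exactly 1)")
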