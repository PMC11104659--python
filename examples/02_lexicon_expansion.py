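"""Expand the craving lexicon with embedding nearest neighbors.

Trains skip-gram vectors on a corpus where 'urge' and 'craving' are used
interchangeably in identical contexts; the distributional hypothesis then
puts 'urge' among the closest neighbors of 'craving', so lexicon expansion
recovers it automatically.
"""

import numpy as np

from cravingminer import craving_filter as cf
from cravingminer import embeddings as emb
from cravingminer.corpus_io import TokenDoc

rng = np.random.default_rng(5)
background = [f"bg{i}" for i in range(30)]
context = ["strong", "tonight", "resist", "wine"]
docs = []
for i in range(400):
    member = "craving" if rng.random() < 0.5 else "urge"
    order = list(rng.permutation(context))
    docs.append(TokenDoc(f"d{i}", order[:2] + [member] + order[2:]
                         + [background[j] for j in rng.integers(30, size=3)]))
for i in range(400, 900):
    docs.append(TokenDoc(f"d{i}", [background[j] for j in rng.integers(30, size=10)]))

model = emb.train(docs, emb.TrainConfig(dim=32, window=3, epochs=3, min_count=2, seed=5))
print("nearest neighbors of 'craving':")
for term, score in emb.most_similar(model, "craving", 5):
    print(f"  {term:10s} {100 * score:6.2f}%")

raw = cf.expand_lexicon(model, seeds=("craving",), k=5, min_score=0.0)
print(f"uncurated expansion: {raw.terms}")
strict = cf.expand_lexicon(model, seeds=("craving",), k=5, min_score=0.9)
print(f"with min_score=0.9:  {strict.terms}")
print("('urge' survives the score cutoff; incidental background neighbors do not)")
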