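"""Sanity check: attribution matrices are not random noise.

Pairs every saliency residue-impact matrix from a synthetic corpus with a
moment-matched Gaussian matrix, featurizes both by bilinear resampling to
a 32 x 32 grid, and trains an RBF-kernel SVM on an 80% split.  Structured
explanations separate perfectly from noise; this is the floor any
informative explanation pipeline must clear.
"""

import protattr as pa
from protattr.attribution import AttributionConfig
from protattr.models import as_handle
from protattr.stats import random_separability_check

embedder = pa.build_toy_embedder(e=8, lam=1.0, seed=9)
handle = as_handle(embedder)
cfg = AttributionConfig(method="saliency")
corpus = pa.generate_synthetic_proteins(40, (30, 44), 0.3, seed=1)
matrices = [
    pa.compute_embedding_attribution(handle, embedder.embed(r.sequence), cfg,
                                     stream=True).XE
    for r in corpus
]
acc = random_separability_check(matrices, seed=1, train_fraction=0.8)
print(f"{len(matrices)} attribution matrices + {len(matrices)} moment-matched "
      f"random matrices")
print(f"held-out SVM accuracy: {acc:.3f}")
print("1.000 means explanation maps carry structure an RBF classifier "
      "separates from noise with margin.")
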