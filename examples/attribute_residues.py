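"""Residue-on-residue influence for an embedder, from one attribution pass.

Builds a toy protein language model (n x e embedder with locality decay 1),
runs saliency over every output scalar of a random 20-residue protein, and
collapses the 4-D influence tensor E[i,k,j,l] to the n x n residue-impact
matrix XE, whose (i, j) entry is the summed effect of residue j on residue
i's embedding vector.
"""

import numpy as np

import protattr as pa
from protattr.attribution import AttributionConfig
from protattr.models import as_handle

embedder = pa.build_toy_embedder(e=8, lam=1.0, seed=0)
record = pa.generate_synthetic_proteins(1, (20, 20), 0.3, seed=1)[0]
print(f"protein {record.name}: {record.sequence}")

x = embedder.embed(record.sequence)
handle = as_handle(embedder)
E = pa.compute_embedding_attribution(handle, x, AttributionConfig(method="saliency"))
XE = pa.collapse_to_XE(E)

print(f"E tensor shape: {E.shape}  ->  XE shape: {XE.X.shape}")
for i in (0, 10, 19):
    j = int(np.argmax(np.abs(XE.X[i])))
    print(f"residue {i:2d} ({record.sequence[i]}): strongest influence from "
          f"residue {j:2d} ({record.sequence[j]}), XE[{i},{j}] = {XE.X[i, j]:+.3f}")
# With locality decay 1 the dominant influence on each residue is itself or
# an immediate neighbour; the off-diagonal entries fall off as exp(-|i-j|).
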