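"""Tensor algebra collapsing element-level attributions to residue level.

The embedder influence tensor E[i, k, j, l] (effect of input element
(j, l) on output element (i, k)) reduces to:

* XE[i, j] = sum_k sum_l E[i, k, j, l] -- the residue-impact matrix for
  embedding computation (effect of residue j on residue i's embedding);
* T[i, k, j] = sum_l E[i, k, j, l] -- the effect of residue j on embedding
  element (i, k), the piece needed to push predictor attributions back to
  input residues.

The predictor tensor P[i, k, l] (effect of window slot (k, l) on residue
i's interaction propensity) composes with T into the prediction
residue-impact matrix.  In 1-based notation:

    XP[i, j] = sum_{k=1}^{2w+1} sum_{l=1}^{e} P[i, k, l] * T[i+k-(w+1), l, j]

Internally everything is 0-based; the window-slot offset becomes
``i + k - w``.  Window positions falling outside the sequence contribute
zero by default, consistent with zero-padded prediction windows.  All sums
are raw and signed: no absolute value, no normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ResidueImpactMatrix:
    """An n x n residue-on-residue influence matrix.

    Entry (i, j) is the summed effect of source residue j on target residue
    i's embedding vector (mode ``embedding``, XE) or interaction propensity
    (mode ``prediction``, XP).
    """

    X: np.ndarray
    mode: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] != self.X.shape[1]:
            raise ValueError(f"residue-impact matrix must be square, got {self.X.shape}")
        if self.mode not in ("embedding", "prediction"):
            raise ValueError(f"mode must be 'embedding' or 'prediction', got {self.mode!r}")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite entries in residue-impact matrix")


def _check_finite(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError(f"non-finite entries in {name}")
    return arr


def collapse_to_T(E: np.ndarray) -> np.ndarray:
    """T[i, k, j] = sum_l E[i, k, j, l]  (shape n x e x n)."""
    E = _check_finite(E, "E")
    if E.ndim != 4:
        raise ValueError(f"E must be 4-dimensional, got shape {E.shape}")
    return E.sum(axis=3)


def collapse_to_XE(E: np.ndarray, provenance: dict | None = None) -> ResidueImpactMatrix:
    """XE[i, j] = sum_k sum_l E[i, k, j, l]  (summed via T for a single,
    reproducible accumulation order shared with the streaming path)."""
    X = collapse_to_T(E).sum(axis=1)
    return ResidueImpactMatrix(X, "embedding", provenance or {})


def xe_from_T(T: np.ndarray, provenance: dict | None = None) -> ResidueImpactMatrix:
    """Residue-impact matrix from an already-collapsed T tensor."""
    T = _check_finite(T, "T")
    return ResidueImpactMatrix(T.sum(axis=1), "embedding", provenance or {})


def compose_XP(P: np.ndarray, T: np.ndarray, w: int,
               boundary_policy: str = "zero",
               provenance: dict | None = None) -> ResidueImpactMatrix:
    """Compose predictor attributions P with the embedder reduction T.

    ``P`` has shape (n, 2w+1, e); ``T`` has shape (n, e, n).  Window slot k
    of residue i refers to sequence position i + k - w (0-based); slots
    referring to positions outside [0, n) contribute according to
    ``boundary_policy`` (only ``"zero"`` is defined: they contribute
    nothing, the sequence has no residues there).
    """
    P = _check_finite(P, "P")
    T = _check_finite(T, "T")
    if boundary_policy != "zero":
        raise ValueError(f"unknown boundary policy {boundary_policy!r}")
    if P.ndim != 3 or T.ndim != 3:
        raise ValueError("P must be (n, 2w+1, e) and T must be (n, e, n)")
    n, width, e = P.shape
    if width != 2 * w + 1:
        raise ValueError(f"P window dimension {width} inconsistent with w={w}")
    if T.shape != (n, e, n):
        raise ValueError(f"T shape {T.shape} inconsistent with P shape {P.shape}")
    XP = np.zeros((n, n))
    for i in range(n):
        for k in range(width):
            pos = i + k - w
            if 0 <= pos < n:
                XP[i] += P[i, k] @ T[pos]
    return ResidueImpactMatrix(XP, "prediction", provenance or {})


def write_impact_tsv(matrix: ResidueImpactMatrix, sequence: str | None, path) -> None:
    """Write a residue-impact matrix as TSV with residue letters as headers."""
    n = matrix.X.shape[0]
    headers = list(sequence) if sequence else [f"r{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(headers) + "\n")
        for i in range(n):
            row = "\t".join(repr(float(v)) for v in matrix.X[i])
            fh.write(f"{headers[i]}\t{row}\n")
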