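"""Explanation infidelity: how well an attribution predicts output change.

For a scalar predictor f, input x and attribution map Phi, the infidelity
under a perturbation distribution mu_I is

    INFD(Phi, f, x) = E_{I ~ mu_I} ( I . Phi  -  (f(x) - f(x - I)) )^2,

estimated by Monte Carlo.  Perturbations are Gaussian, mean 0, standard
deviation 0.01 by default (in raw activation units), applied to the
embedding-layer output activations of the embedder and to the embedding
window of the predictor.

Aggregation: per-element embedding infidelities form the n x e matrix I_E
with scalar INFD_E = mean(I_E); per-residue prediction infidelities form
the length-n vector I_P, combined with I_E through a window-multiplicity
weighting into the scalar INFD_P:

    S = (sum_{i=w+1}^{n-w} sum_j I_E[i,j] + sum_{i=w+1}^{n-w} I_P[i]) * (2w+1)
        + sum_{i=1}^{w} ((sum_j I_E[i,j] + sum_j I_E[n-i+1,j]
                          + I_P[i] + I_P[n-i+1]) * (w+i))
    INFD_P = S / ((n - 2w)(2w+1) + w(3w+1))          [1-based indices]

The printed denominator term w(3w+1) differs from the algebraic value of
the boundary weight sum, sum_{i=w+1}^{2w} i = w(3w+1)/2; both variants are
implemented (``denominator="as_printed"`` is the default, ``"derived"``
selects the algebraically consistent one) rather than silently correcting
either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PerturbationSpec:
    """Gaussian perturbation ensemble for infidelity estimation."""

    std: float = 0.01
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError("perturbation std must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def draw(self, shape, rng=None) -> np.ndarray:
        """All n_samples perturbations, shape (n_samples, *shape)."""
        rng = np.random.default_rng(self.seed) if rng is None else rng
        return rng.normal(0.0, self.std, size=(self.n_samples, *shape))


@dataclass
class InfidelityRecord:
    """Per-element and aggregate infidelities for one (model, method) run."""

    I_E: np.ndarray  # n x e embedding-explanation infidelities
    I_P: np.ndarray | None  # length-n prediction-explanation infidelities
    INFD_E: float
    INFD_P: float | None
    n: int
    e: int
    w: int | None
    denominator: str | None = None

    def to_dict(self) -> dict:
        return {
            "INFD_E": self.INFD_E,
            "INFD_P": self.INFD_P,
            "n": self.n,
            "e": self.e,
            "w": self.w,
            "denominator": self.denominator,
        }


def infidelity_score(f, x, phi, perturbation: PerturbationSpec,
                     draws: np.ndarray | None = None) -> float:
    """Monte-Carlo estimate of INFD(phi, f, x) for a scalar function f.

    ``draws`` may supply the perturbation sample explicitly (shape
    (n_samples, *x.shape)) so independent oracles can share the ensemble.
    """
    x = np.asarray(x, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if phi.shape != x.shape:
        raise ValueError("attribution map must be shaped like the input")
    if draws is None:
        draws = perturbation.draw(x.shape)
    fx = float(f(x))
    if not np.isfinite(fx):
        raise ArithmeticError("non-finite model evaluation at x")
    acc = 0.0
    for I in draws:
        fv = float(f(x - I))
        if not np.isfinite(fv):
            raise ArithmeticError("non-finite model evaluation at perturbed input")
        resid = float((I * phi).sum()) - (fx - fv)
        acc += resid * resid
    return acc / draws.shape[0]


def embedding_infidelity(handle_embedder, x, per_scalar_attributions,
                         perturbation: PerturbationSpec) -> tuple[np.ndarray, float]:
    """Infidelity of the attribution map explaining each embedder output (i, k).

    ``per_scalar_attributions`` is the full influence tensor E of shape
    (n, e, n, e_in): E[i, k] explains output element (i, k).  One shared
    perturbation ensemble drawn on the input activations serves every
    output scalar, so the whole matrix I_E costs n_samples forward passes.
    """
    x = np.asarray(x, dtype=np.float64)
    E = np.asarray(per_scalar_attributions, dtype=np.float64)
    y0 = handle_embedder.forward(x)
    n, e = y0.shape
    if E.shape[:2] != (n, e) or E.shape[2:] != x.shape:
        raise ValueError(f"expected E of shape ({n}, {e}, *{x.shape}), got {E.shape}")
    draws = perturbation.draw(x.shape)
    acc = np.zeros((n, e))
    for I in draws:
        yv = handle_embedder.forward(x - I)
        proj = np.tensordot(E, I, axes=([2, 3], [0, 1]))  # (n, e)
        resid = proj - (y0 - yv)
        acc += resid * resid
    I_E = acc / draws.shape[0]
    return I_E, float(I_E.mean())


def _window(padded: np.ndarray, i: int, width: int) -> np.ndarray:
    return padded[i:i + width]


def prediction_infidelity(handle_predictor, embeddings, per_residue_attributions,
                          I_E, w: int, perturbation: PerturbationSpec,
                          denominator: str = "as_printed") -> InfidelityRecord:
    """Per-residue predictor-attribution infidelities and the scalar INFD_P.

    ``per_residue_attributions`` is P of shape (n, 2w+1, e); residue i's
    map explains the predictor output on its zero-padded window.  Requires
    n > 2w.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    P = np.asarray(per_residue_attributions, dtype=np.float64)
    I_E = np.asarray(I_E, dtype=np.float64)
    n, e = emb.shape
    width = 2 * w + 1
    if n <= 2 * w:
        raise ValueError(f"need n > 2w, got n={n}, w={w}")
    if P.shape != (n, width, e):
        raise ValueError(f"P shape {P.shape} inconsistent with (n, 2w+1, e)")
    if I_E.shape != (n, e):
        raise ValueError(f"I_E shape {I_E.shape} != ({n}, {e})")

    padded = np.zeros((n + 2 * w, e))
    padded[w:w + n] = emb
    rng = np.random.default_rng(perturbation.seed)
    I_P = np.empty(n)
    for i in range(n):
        win = _window(padded, i, width)
        f = lambda z: handle_predictor.forward(z)[0]
        draws = perturbation.draw(win.shape, rng=rng)
        I_P[i] = infidelity_score(f, win, P[i], perturbation, draws=draws)

    S, denom = combine_infidelities(I_E, I_P, w, denominator)
    return InfidelityRecord(I_E=I_E, I_P=I_P, INFD_E=float(I_E.mean()),
                            INFD_P=S / denom, n=n, e=e, w=w, denominator=denominator)


def combine_infidelities(I_E: np.ndarray, I_P: np.ndarray, w: int,
                         denominator: str = "as_printed") -> tuple[float, float]:
    """The window-multiplicity weighted sum S and its normalizer.

    Interior residues (1-based i in [w+1, n-w]) appear in 2w+1 prediction
    windows; the i-th residue from either end appears in only w+i.
    """
    I_E = np.asarray(I_E, dtype=np.float64)
    I_P = np.asarray(I_P, dtype=np.float64)
    n = I_P.shape[0]
    if n <= 2 * w:
        raise ValueError(f"need n > 2w, got n={n}, w={w}")
    row_E = I_E.sum(axis=1)
    # 1-based interior [w+1, n-w] -> 0-based slice [w, n-w)
    S = (row_E[w:n - w].sum() + I_P[w:n - w].sum()) * (2 * w + 1)
    for i in range(1, w + 1):  # 1-based boundary index
        S += (row_E[i - 1] + row_E[n - i] + I_P[i - 1] + I_P[n - i]) * (w + i)
    if denominator == "as_printed":
        denom = (n - 2 * w) * (2 * w + 1) + w * (3 * w + 1)
    elif denominator == "derived":
        denom = (n - 2 * w) * (2 * w + 1) + w * (3 * w + 1) / 2.0
    else:
        raise ValueError(f"denominator must be 'as_printed' or 'derived', got {denominator!r}")
    return float(S), float(denom)
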