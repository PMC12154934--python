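"""Nine feature-attribution operators over the differentiable-model contract.

Every operator explains one scalar model output and returns an importance
score for each element of the continuous input activations.  Three families
are implemented:

* gradient-based: saliency, deconvolution, guided backpropagation,
  input x gradient;
* reference-based path methods: DeepLIFT (rescale rule), integrated
  gradients (midpoint rule), GradientShap;
* local surrogate methods: LIME (proximity-weighted ridge surrogate on
  binary-mask perturbations) and KernelShap (Shapley-kernel weighted least
  squares with the efficiency constraint).

The drivers at the bottom iterate an operator over every scalar output of
an embedder (building the 4-D influence tensor E, or streaming its
residue-collapsed reductions) and over every residue of a windowed
predictor (building the n x (2w+1) x e tensor P).

The baseline convention throughout is all-zero activations: the natural
reference for an absent token at the embedding-layer output.  Stochastic
operators are bit-reproducible under a fixed seed; per-scalar seeds are
derived from (config.seed, scalar index) so maps are independent yet
deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from math import comb

import numpy as np

from .models import ContractError, DifferentiableModelHandle

METHODS = (
    "saliency",
    "deconvolution",
    "guided_backprop",
    "input_x_gradient",
    "deeplift",
    "integrated_gradients",
    "lime",
    "kernelshap",
    "gradientshap",
)

#: methods whose handle must carry a specific backward rule
_RULE_FOR_METHOD = {
    "saliency": "true_gradient",
    "input_x_gradient": "true_gradient",
    "deconvolution": "deconvolution",
    "guided_backprop": "guided",
}

_EXACT_ENUMERATION_LIMIT = 4096  # enumerate all coalitions when 2^d <= this


class AttributionNumericError(RuntimeError):
    """Non-finite or degenerate numerics inside an attribution operator."""


@dataclass
class AttributionConfig:
    """Hyperparameters for the attribution operators.

    None of these are dictated by the analysis itself; they are module
    defaults chosen to match common practice and are recorded in the
    provenance of every map produced.
    """

    method: str = "saliency"
    baseline: np.ndarray | None = None  # default: all-zeros, shape of input
    ig_steps: int = 50
    mc_samples: int = 200
    gradientshap_samples: int = 50
    noise_std: float = 0.1
    lime_kernel_width: float | None = None  # default 0.75 * sqrt(d)
    surrogate_ridge: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.ig_steps < 2:
            raise ValueError("ig_steps must be >= 2")


@dataclass
class AttributionMap:
    """Importance scores shaped like the model input, with provenance."""

    values: np.ndarray
    output_selector: tuple
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise AttributionNumericError(
                f"non-finite attribution values for output {self.output_selector}"
            )


def _zero_baseline(x: np.ndarray, baseline) -> np.ndarray:
    if baseline is None:
        return np.zeros_like(x)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != x.shape:
        raise ValueError("baseline shape must match input shape")
    return baseline


def _require_rule(handle: DifferentiableModelHandle, method: str) -> None:
    want = _RULE_FOR_METHOD.get(method)
    if want is not None and handle.backprop_rule != want:
        raise ContractError(
            f"{method} requires a handle with backprop_rule={want!r}, "
            f"got {handle.backprop_rule!r}"
        )


# ---------------------------------------------------------------------------
# gradient family
# ---------------------------------------------------------------------------

def saliency(handle, x, output_selector) -> AttributionMap:
    """Gradient of the selected output with respect to the input."""
    _require_rule(handle, "saliency")
    g = handle.scalar_gradient(x, output_selector)
    return AttributionMap(g, tuple(np.atleast_1d(output_selector)), "saliency")


def input_x_gradient(handle, x, output_selector) -> AttributionMap:
    """Gradient multiplied elementwise with the input."""
    _require_rule(handle, "input_x_gradient")
    g = handle.scalar_gradient(x, output_selector)
    return AttributionMap(g * np.asarray(x), tuple(np.atleast_1d(output_selector)),
                          "input_x_gradient")


def deconvolution(handle, x, output_selector) -> AttributionMap:
    """Backward signal with rectifiers passing only positive upstream signal."""
    _require_rule(handle, "deconvolution")
    g = handle.scalar_gradient(x, output_selector)
    return AttributionMap(g, tuple(np.atleast_1d(output_selector)), "deconvolution")


def guided_backprop(handle, x, output_selector) -> AttributionMap:
    """Backward signal masked by both forward activation and upstream sign."""
    _require_rule(handle, "guided_backprop")
    g = handle.scalar_gradient(x, output_selector)
    return AttributionMap(g, tuple(np.atleast_1d(output_selector)), "guided_backprop")


# ---------------------------------------------------------------------------
# reference-based path methods
# ---------------------------------------------------------------------------

def deeplift(handle, x, baseline, output_selector) -> AttributionMap:
    """Rescale-rule contributions relative to a reference input.

    Satisfies summation-to-delta: the scores sum to f(x) - f(baseline).
    """
    x = np.asarray(x, dtype=np.float64)
    b = _zero_baseline(x, baseline)
    vals = handle.rescale_attribution(x, b, output_selector)
    return AttributionMap(vals, tuple(np.atleast_1d(output_selector)), "deeplift")


def integrated_gradients(handle, x, baseline, ig_steps, output_selector) -> AttributionMap:
    """(x - baseline) times the path integral of gradients, midpoint rule."""
    if ig_steps < 2:
        raise ValueError("ig_steps must be >= 2")
    x = np.asarray(x, dtype=np.float64)
    b = _zero_baseline(x, baseline)
    delta = x - b
    acc = np.zeros_like(x)
    for m in range(ig_steps):
        t = (m + 0.5) / ig_steps
        acc += handle.scalar_gradient(b + t * delta, output_selector)
    vals = delta * acc / ig_steps
    return AttributionMap(vals, tuple(np.atleast_1d(output_selector)),
                          "integrated_gradients", {"ig_steps": ig_steps})


def gradientshap(handle, x, baseline_sampler, mc_samples, noise_std, seed,
                 output_selector=()) -> AttributionMap:
    """Expected (x - b) * grad f at jittered points on random paths.

    ``baseline_sampler`` is an array of candidate baselines (rows selected
    uniformly) or a callable rng -> baseline.  With a single zero baseline
    and no noise this converges to integrated gradients.
    """
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    rng = np.random.default_rng(seed)

    if baseline_sampler is None:
        draw = lambda: np.zeros_like(x)
    elif callable(baseline_sampler):
        draw = lambda: np.asarray(baseline_sampler(rng), dtype=np.float64)
    else:
        pool = np.asarray(baseline_sampler, dtype=np.float64)
        if pool.ndim == x.ndim:
            pool = pool[None]
        if pool.shape[1:] != x.shape or pool.shape[0] < 1:
            raise ValueError("degenerate baseline sampler")
        draw = lambda: pool[rng.integers(pool.shape[0])]

    acc = np.zeros_like(x)
    for _ in range(mc_samples):
        b = draw()
        t = rng.uniform()
        z = b + t * (x - b)
        if noise_std > 0:
            z = z + rng.normal(0.0, noise_std, size=x.shape)
        acc += (x - b) * handle.scalar_gradient(z, output_selector)
    return AttributionMap(acc / mc_samples, tuple(np.atleast_1d(output_selector)),
                          "gradientshap",
                          {"mc_samples": mc_samples, "noise_std": noise_std})


# ---------------------------------------------------------------------------
# local surrogate methods
# ---------------------------------------------------------------------------

def _mask_matrix(d: int, mc_samples: int, rng, include_extremes: bool):
    """Binary perturbation masks; full enumeration when feasible."""
    if 2 ** d <= mc_samples:
        Z = np.array(list(itertools.product((0, 1), repeat=d)), dtype=np.float64)
        return Z, True
    Z = rng.integers(0, 2, size=(mc_samples, d)).astype(np.float64)
    if include_extremes:
        Z[0] = 1.0
        Z[-1] = 0.0
    return Z, False


def lime(handle, x, mc_samples, lime_kernel_width=None, surrogate_ridge=1e-3,
         seed=0, output_selector=(), baseline=None) -> AttributionMap:
    """Proximity-weighted ridge linear surrogate on binary-mask perturbations.

    Masked elements are set to the baseline (zero by default); the surrogate
    coefficient of element i is its importance score.
    """
    x = np.asarray(x, dtype=np.float64)
    b = _zero_baseline(x, baseline)
    d = x.size
    if mc_samples < d + 1:
        raise ValueError(f"mc_samples must be >= d+1 = {d + 1}")
    kw = 0.75 * np.sqrt(d) if lime_kernel_width is None else float(lime_kernel_width)
    rng = np.random.default_rng(seed)
    Z, _ = _mask_matrix(d, mc_samples, rng, include_extremes=True)

    xf, bf = x.reshape(-1), b.reshape(-1)
    y = np.empty(Z.shape[0])
    for r, z in enumerate(Z):
        y[r] = handle.forward((bf + z * (xf - bf)).reshape(x.shape))[output_selector]

    dist = 1.0 - Z.mean(axis=1)  # hamming distance to the unmasked instance
    wgt = np.exp(-(dist ** 2) / kw ** 2)
    X = np.column_stack([np.ones(Z.shape[0]), Z])
    sw = np.sqrt(wgt)
    A = X * sw[:, None]
    rhs = y * sw
    if surrogate_ridge > 0:
        pen = np.full(d + 1, np.sqrt(surrogate_ridge))
        pen[0] = 0.0  # do not penalize the intercept
        A = np.vstack([A, np.diag(pen)])
        rhs = np.concatenate([rhs, np.zeros(d + 1)])
    beta, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < d + 1:
        raise AttributionNumericError("singular weighted design in LIME surrogate fit")
    vals = beta[1:].reshape(x.shape)
    return AttributionMap(vals, tuple(np.atleast_1d(output_selector)), "lime",
                          {"mc_samples": mc_samples, "kernel_width": kw,
                           "ridge": surrogate_ridge})


def _shapley_kernel_weights(d: int, sizes: np.ndarray) -> np.ndarray:
    return (d - 1) / (np.array([comb(d, int(s)) for s in sizes]) * sizes * (d - sizes))


def _sample_coalitions(d: int, budget: int, rng):
    """Coalition design under a finite evaluation budget.

    Complete coalition sizes are enumerated outright (smallest and largest
    first, where the Shapley kernel concentrates its mass) while they fit
    in the budget; remaining sizes are sampled from the renormalized kernel
    size distribution, each sampled row carrying an equal share of the
    leftover kernel mass.
    """
    sizes = np.arange(1, d)
    size_mass = (d - 1) / (sizes * (d - sizes))  # kernel mass per size (x comb(d,s) rows)
    order = []
    lo, hi = 1, d - 1
    while lo <= hi:
        order.append(lo)
        if hi != lo:
            order.append(hi)
        lo += 1
        hi -= 1
    remaining = budget
    enum_sizes = []
    for s in order:
        if comb(d, s) <= remaining:
            enum_sizes.append(s)
            remaining -= comb(d, s)
        else:
            break
    rows, wgts = [], []
    for s in enum_sizes:
        for idx in itertools.combinations(range(d), s):
            z = np.zeros(d)
            z[list(idx)] = 1.0
            rows.append(z)
        wgts.extend([size_mass[s - 1] / comb(d, s)] * comb(d, s))
    left = [s for s in sizes if s not in enum_sizes]
    if left and remaining > 0:
        p = np.array([size_mass[s - 1] for s in left])
        p = p / p.sum()
        leftover_mass = sum(size_mass[s - 1] for s in left)
        per_row = leftover_mass / remaining
        for _ in range(remaining):
            s = int(rng.choice(left, p=p))
            z = np.zeros(d)
            z[rng.choice(d, size=s, replace=False)] = 1.0
            rows.append(z)
            wgts.append(per_row)
    return np.array(rows), np.array(wgts)


def kernelshap(handle, x, mc_samples=200, seed=0, output_selector=(),
               baseline=None) -> AttributionMap:
    """Shapley values via kernel-weighted least squares over coalitions.

    Solves the weighted regression with the efficiency constraint
    sum(values) = f(x) - f(baseline) eliminated exactly.  All 2^d - 2
    non-trivial coalitions are enumerated when 2^d <= 4096; otherwise
    coalitions are sampled from the Shapley-kernel size distribution with
    paired (complement) draws.
    """
    x = np.asarray(x, dtype=np.float64)
    b = _zero_baseline(x, baseline)
    d = x.size
    if d < 2:
        raise ValueError("kernelshap requires at least 2 input elements")
    rng = np.random.default_rng(seed)

    if 2 ** d <= _EXACT_ENUMERATION_LIMIT:
        Z = np.array(list(itertools.product((0, 1), repeat=d)), dtype=np.float64)
        Z = Z[(Z.sum(axis=1) > 0) & (Z.sum(axis=1) < d)]
        wgt = _shapley_kernel_weights(d, Z.sum(axis=1))
    else:
        Z, wgt = _sample_coalitions(d, mc_samples, rng)

    xf, bf = x.reshape(-1), b.reshape(-1)
    f0 = float(handle.forward(b)[output_selector])
    fx = float(handle.forward(x)[output_selector])
    delta = fx - f0
    y = np.empty(Z.shape[0])
    for r, z in enumerate(Z):
        y[r] = handle.forward((bf + z * (xf - bf)).reshape(x.shape))[output_selector] - f0

    # eliminate phi_{d-1} via the efficiency constraint
    zl = Z[:, -1]
    Xc = Z[:, :-1] - zl[:, None]
    yc = y - zl * delta
    sw = np.sqrt(wgt)
    phi_head, _, rank, _ = np.linalg.lstsq(Xc * sw[:, None], yc * sw, rcond=None)
    if rank < d - 1:
        raise AttributionNumericError("degenerate coalition draws in KernelShap")
    phi = np.empty(d)
    phi[:-1] = phi_head
    phi[-1] = delta - phi_head.sum()
    return AttributionMap(phi.reshape(x.shape), tuple(np.atleast_1d(output_selector)),
                          "kernelshap", {"mc_samples": mc_samples})


def exact_shapley(handle, x, output_selector=(), baseline=None) -> np.ndarray:
    """Brute-force Shapley values by averaging marginal contributions.

    Independent oracle for KernelShap on small inputs; O(2^d * d) model
    evaluations.
    """
    x = np.asarray(x, dtype=np.float64)
    b = _zero_baseline(x, baseline)
    d = x.size
    xf, bf = x.reshape(-1), b.reshape(-1)

    vals = {}
    for bits in itertools.product((0, 1), repeat=d):
        z = np.array(bits, dtype=np.float64)
        vals[bits] = float(handle.forward((bf + z * (xf - bf)).reshape(x.shape))[output_selector])

    phi = np.zeros(d)
    from math import factorial
    for i in range(d):
        for bits, v in vals.items():
            if bits[i] == 1:
                continue
            s = sum(bits)
            with_i = tuple(1 if j == i else bj for j, bj in enumerate(bits))
            weight = factorial(s) * factorial(d - s - 1) / factorial(d)
            phi[i] += weight * (vals[with_i] - v)
    return phi.reshape(x.shape)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def attribute(handle, x, output_selector, config: AttributionConfig) -> AttributionMap:
    """Run the configured operator on one scalar output."""
    m = config.method
    if m == "saliency":
        return saliency(handle, x, output_selector)
    if m == "input_x_gradient":
        return input_x_gradient(handle, x, output_selector)
    if m == "deconvolution":
        return deconvolution(handle, x, output_selector)
    if m == "guided_backprop":
        return guided_backprop(handle, x, output_selector)
    if m == "deeplift":
        return deeplift(handle, x, config.baseline, output_selector)
    if m == "integrated_gradients":
        return integrated_gradients(handle, x, config.baseline, config.ig_steps,
                                    output_selector)
    if m == "gradientshap":
        return gradientshap(handle, x, config.baseline, config.gradientshap_samples,
                            config.noise_std, config.seed, output_selector)
    if m == "lime":
        return lime(handle, x, config.mc_samples, config.lime_kernel_width,
                    config.surrogate_ridge, config.seed, output_selector,
                    baseline=config.baseline)
    if m == "kernelshap":
        return kernelshap(handle, x, config.mc_samples, config.seed, output_selector,
                          baseline=config.baseline)
    raise ValueError(f"unknown method {m!r}")


def _scalar_config(config: AttributionConfig, index: int) -> AttributionConfig:
    # derive an independent, deterministic seed per explained scalar
    return replace(config, seed=(int(config.seed), int(index)))


# ---------------------------------------------------------------------------
# drivers: E and P tensors
# ---------------------------------------------------------------------------

@dataclass
class StreamedEmbeddingAttribution:
    """Residue-collapsed reductions of E accumulated without materializing it.

    ``T[i, k, j]`` is the summed influence of residue j on embedding element
    (i, k); the residue-impact matrix follows as ``T.sum(axis=1)``.
    """

    T: np.ndarray

    @property
    def XE(self) -> np.ndarray:
        return self.T.sum(axis=1)


def compute_embedding_attribution(handle, x, config: AttributionConfig,
                                  stream: bool = False):
    """Drive an operator over every embedder output scalar (i, k).

    Returns the full influence tensor ``E`` of shape (n, e_out, n, e_in)
    when ``stream=False``, or a :class:`StreamedEmbeddingAttribution`
    holding only the residue-collapsed ``T`` when ``stream=True``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError(f"expected n x e input activations, got shape {x.shape}")
    n, e_in = x.shape
    out_shape = handle.output_shape(x)
    n_out, e_out = out_shape
    E = None if stream else np.empty((n_out, e_out, n, e_in))
    T = np.empty((n_out, e_out, n)) if stream else None
    for i in range(n_out):
        for k in range(e_out):
            idx = i * e_out + k
            try:
                amap = attribute(handle, x, (i, k), _scalar_config(config, idx))
            except Exception as exc:
                raise AttributionNumericError(
                    f"{config.method} failed for output element ({i}, {k}): {exc}"
                ) from exc
            if stream:
                T[i, k, :] = amap.values.sum(axis=1)
            else:
                E[i, k] = amap.values
    return StreamedEmbeddingAttribution(T=T) if stream else E


def compute_prediction_attribution(handle_predictor, embeddings, w: int,
                                   config: AttributionConfig) -> np.ndarray:
    """Drive an operator over each residue's windowed prediction.

    ``embeddings`` is the n x e embedding matrix; windows extending past the
    sequence ends are zero-padded, matching the zero-baseline convention.
    Returns P of shape (n, 2w+1, e).
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[0] < 1:
        raise ValueError(f"expected n x e embeddings, got shape {emb.shape}")
    n, e = emb.shape
    width = 2 * w + 1
    padded = np.zeros((n + 2 * w, e))
    padded[w:w + n] = emb
    P = np.empty((n, width, e))
    for i in range(n):
        window = padded[i:i + width]
        try:
            amap = attribute(handle_predictor, window, (0,), _scalar_config(config, i))
        except Exception as exc:
            raise AttributionNumericError(
                f"{config.method} failed for residue {i}: {exc}"
            ) from exc
        P[i] = amap.values
    return P
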