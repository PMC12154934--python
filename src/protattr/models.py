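"""Small differentiable sequence models exposing a value-and-gradient contract.

These are desk-scale stand-ins for transformer protein language models
(embedder: length-n sequence -> n x e embedding matrix) and for windowed
interaction-site predictors (input: the (2w+1) x e embedding window centred
on a residue, output: an interaction propensity in (0, 1)).

Two design constraints drive the architecture:

* attribution is taken with respect to the *embedding-layer output
  activations* -- a continuous n x e array obtained from a per-letter
  look-up table -- never the discrete letters;
* all nonlinearities are rectified-linear (plus a terminal sigmoid on the
  predictor) so that the deconvolution and guided-backpropagation backward
  rules are well defined.

The locality of the embedder is controlled by a decay rate ``lam``:
output position i depends on input position j through a mixing kernel
``exp(-lam * |i - j|)``.  An optional *planted property channel* makes
model outputs genuinely depend on one physicochemical property of the
input residues, which the downstream statistical harness should then be
able to recover.

Reverse mode is hand-written layer by layer.  Besides the true gradient,
each rectifier supports the deconvolution rule (propagate only positive
upstream signal, ignoring the forward activation) and the guided rule
(zero the signal where either the forward activation or the upstream
signal is non-positive).  The same machinery propagates rescale-rule
multipliers for reference-based attribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .data import AA_ALPHABET, NUMERICAL_PROPERTIES, load_property_table

BACKPROP_RULES = ("true_gradient", "deconvolution", "guided")

_DLIFT_EPS = 1e-9  # |delta z| below this falls back to the local derivative


class ContractError(RuntimeError):
    """A model does not satisfy the requested differentiable-model contract."""


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    params: tuple[str, ...] = ()

    def forward(self, x):
        """Return (output, cache)."""
        raise NotImplementedError

    def backward(self, g, cache, rule):
        """Propagate an upstream signal g to the layer input."""
        raise NotImplementedError

    def multipliers(self, g, cache_x, cache_b):
        """Propagate rescale-rule multipliers given caches at x and baseline."""
        # linear layers: identical to gradient backprop
        return self.backward(g, cache_x, "true_gradient")

    def has_rectifier(self) -> bool:
        return False


class Dense(Layer):
    """Affine map along the last axis: y = x @ W + b."""

    params = ("W", "b")

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = np.asarray(W, dtype=np.float64)
        self.b = np.asarray(b, dtype=np.float64)

    def forward(self, x):
        return x @ self.W + self.b, None

    def backward(self, g, cache, rule):
        return g @ self.W.T


class SeqMix(Layer):
    """Positional mixing y = K x with K[i, j] = exp(-lam |i - j|).

    The kernel is built at forward time from the sequence length, so one
    embedder serves sequences of any length.
    """

    def __init__(self, lam: float):
        if lam < 0:
            raise ValueError(f"locality decay must be >= 0, got {lam}")
        self.lam = float(lam)

    def kernel(self, n: int) -> np.ndarray:
        idx = np.arange(n)
        return np.exp(-self.lam * np.abs(idx[:, None] - idx[None, :]))

    def forward(self, x):
        K = self.kernel(x.shape[0])
        return K @ x, K

    def backward(self, g, cache, rule):
        return cache.T @ g


class ReLU(Layer):
    def forward(self, x):
        return np.maximum(x, 0.0), x

    def backward(self, g, cache, rule):
        if rule == "true_gradient":
            return g * (cache > 0)
        if rule == "deconvolution":
            return g * (g > 0)
        if rule == "guided":
            return g * (g > 0) * (cache > 0)
        raise ValueError(f"unknown backprop rule {rule!r}")

    def multipliers(self, g, cache_x, cache_b):
        dz = cache_x - cache_b
        dy = np.maximum(cache_x, 0.0) - np.maximum(cache_b, 0.0)
        m = np.where(np.abs(dz) > _DLIFT_EPS, dy / np.where(dz == 0, 1.0, dz), cache_x > 0)
        return g * m

    def has_rectifier(self) -> bool:
        return True


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, g, cache, rule):
        return g * cache * (1.0 - cache)

    def multipliers(self, g, cache_x, cache_b):
        dz_raw = None  # recover pre-activations from stored outputs
        # cache stores y; invert for delta computation
        zx = np.log(cache_x / (1.0 - cache_x))
        zb = np.log(cache_b / (1.0 - cache_b))
        dz = zx - zb
        dy = cache_x - cache_b
        m = np.where(np.abs(dz) > _DLIFT_EPS, dy / np.where(dz == 0, 1.0, dz),
                     cache_x * (1.0 - cache_x))
        return g * m


class Flatten(Layer):
    def forward(self, x):
        return x.reshape(-1), x.shape

    def backward(self, g, cache, rule):
        return g.reshape(cache)

    def multipliers(self, g, cache_x, cache_b):
        return g.reshape(cache_x)


class Stack(Layer):
    """A sequential composition of layers; itself usable as a layer."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, g, caches, rule):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            g = layer.backward(g, c, rule)
        return g

    def multipliers(self, g, caches_x, caches_b):
        for layer, cx, cb in zip(reversed(self.layers), reversed(caches_x), reversed(caches_b)):
            g = layer.multipliers(g, cx, cb)
        return g

    def has_rectifier(self) -> bool:
        return any(layer.has_rectifier() for layer in self.layers)


class ResidualBlock(Layer):
    """y = main(x) + x @ S, a linear bypass matrix around a sub-stack.

    Used to carry a planted property channel through the embedder's hidden
    layers unchanged, so planted signals reach the output with a known
    monotone path whatever the random hidden weights do.
    """

    def __init__(self, main: Stack, S: np.ndarray):
        self.main = main
        self.S = np.asarray(S, dtype=np.float64)

    def forward(self, x):
        y_main, cache = self.main.forward(x)
        return y_main + x @ self.S, cache

    def backward(self, g, cache, rule):
        return self.main.backward(g, cache, rule) + g @ self.S.T

    def multipliers(self, g, cache_x, cache_b):
        return self.main.multipliers(g, cache_x, cache_b) + g @ self.S.T

    def has_rectifier(self) -> bool:
        return self.main.has_rectifier()


class LinearSkipHead(Layer):
    """y = main(x) + x @ skip, a scalar head with an additive linear bypass.

    The bypass carries any planted property signal around the rectifier
    block, so a planted sensitivity survives whatever the hidden layer does.
    """

    def __init__(self, main: Stack, skip: np.ndarray):
        self.main = main
        self.skip = np.asarray(skip, dtype=np.float64)  # shape (d, 1)

    def forward(self, x):
        y_main, cache = self.main.forward(x)
        return y_main + x @ self.skip, cache

    def backward(self, g, cache, rule):
        return self.main.backward(g, cache, rule) + g @ self.skip.T

    def multipliers(self, g, cache_x, cache_b):
        return self.main.multipliers(g, cache_x, cache_b) + g @ self.skip.T

    def has_rectifier(self) -> bool:
        return self.main.has_rectifier()


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _property_channel(name: str) -> np.ndarray:
    """Per-letter channel encoding of a property (alphabetical order).

    A positive affine transform (standardized to unit spread, then shifted
    to a minimum of 0.5): rank-preserving, so a rank-based detector targets
    the same ordering, and strictly positive, so the planted signal keeps a
    consistent sign through products of activations along the
    attribution-composition path.
    """
    if name not in NUMERICAL_PROPERTIES:
        raise ValueError(
            f"unknown property {name!r}; expected one of {NUMERICAL_PROPERTIES}"
        )
    table = load_property_table()
    v = table[name].to_numpy(dtype=np.float64)
    v = (v - v.mean()) / v.std()
    return v - v.min() + 0.5


@dataclass
class ToyEmbedderModel:
    """Differentiable embedder: n x e activations -> n x e embeddings.

    The look-up table maps each letter to a base activation vector.  With a
    planted ``property_sensitivity`` ``(name, beta)``, activation channel 0
    carries ``beta *`` the standardized property value of the letter, making
    downstream outputs genuinely property-dependent.
    """

    embedding_dim: int
    locality_decay: float
    hidden_dim: int = 16
    property_sensitivity: tuple[str, float] | None = None
    seed: int = 0
    alphabet_size: int = 20
    lookup: np.ndarray = field(init=False, repr=False)
    stack: Stack = field(init=False, repr=False)

    def __post_init__(self) -> None:
        e, h = self.embedding_dim, self.hidden_dim
        if e < 2:
            raise ValueError(f"embedding_dim must be >= 2, got {e}")
        rng = np.random.default_rng(self.seed)
        self.lookup = rng.normal(0.0, 1.0, size=(self.alphabet_size, e))
        if self.property_sensitivity is not None:
            name, beta = self.property_sensitivity
            self.lookup[:, 0] = beta * _property_channel(name)
        W1 = rng.normal(0.0, 1.0 / np.sqrt(e), size=(e, h))
        b1 = rng.normal(0.0, 0.1, size=h)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, e))
        b2 = rng.normal(0.0, 0.1, size=e)
        body = Stack([Dense(W1, b1), ReLU(), Dense(W2, b2)])
        if self.property_sensitivity is not None:
            # identity bypass on the planted channel: the property signal
            # reaches the output with a known monotone path
            S = np.zeros((e, e))
            S[0, 0] = 1.0
            body = ResidualBlock(body, S)
        self.stack = Stack([SeqMix(self.locality_decay), body])

    def embed(self, sequence: str) -> np.ndarray:
        """Embedding-layer output activations for a sequence (n x e)."""
        idx = [AA_ALPHABET.index(c) for c in sequence]
        return self.lookup[idx]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.stack.forward(np.asarray(x, dtype=np.float64))
        return y


@dataclass
class WindowPredictor:
    """Windowed interaction-propensity head: (2w+1) x e window -> (0, 1).

    A planted ``property_sensitivity`` ``(name, beta)`` adds a linear bypass
    of weight ``beta`` on channel 0 of the centre residue, the channel where
    a paired planted embedder stores the property signal.
    """

    embedding_dim: int
    half_window: int
    hidden_dim: int = 16
    property_sensitivity: tuple[str, float] | None = None
    seed: int = 0
    output_bias_shift: float = 0.0
    stack: Stack = field(init=False, repr=False)

    def __post_init__(self) -> None:
        e, w, h = self.embedding_dim, self.half_window, self.hidden_dim
        if w < 0:
            raise ValueError(f"half_window must be >= 0, got {w}")
        d = (2 * w + 1) * e
        rng = np.random.default_rng(self.seed)
        W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, h))
        b1 = rng.normal(0.0, 0.1, size=h)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, 1))
        b2 = rng.normal(0.0, 0.1, size=1) + self.output_bias_shift
        skip = np.zeros((d, 1))
        if self.property_sensitivity is not None:
            name, beta = self.property_sensitivity
            _property_channel(name)  # validates the name
            skip[w * e + 0, 0] = beta
        main = Stack([Dense(W1, b1), ReLU(), Dense(W2, b2)])
        self.stack = Stack([Flatten(), LinearSkipHead(main, skip), Sigmoid()])

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.stack.forward(np.asarray(x, dtype=np.float64))
        return y  # shape (1,)

    def predict(self, window: np.ndarray) -> float:
        return float(self.forward(window)[0])


# ---------------------------------------------------------------------------
# handles
# ---------------------------------------------------------------------------

@dataclass
class DifferentiableModelHandle:
    """The contract the attribution operators require.

    ``forward(x)`` maps input activations to outputs; ``scalar_gradient(x,
    selector)`` returns the (rule-modified) backward signal of the selected
    scalar output with respect to the input; ``rescale_attribution`` supports
    reference-based attribution via rescale-rule multipliers.
    """

    model: object
    backprop_rule: str = "true_gradient"

    def __post_init__(self) -> None:
        if self.backprop_rule not in BACKPROP_RULES:
            raise ValueError(f"unknown backprop rule {self.backprop_rule!r}")
        if self.backprop_rule != "true_gradient" and not self.model.stack.has_rectifier():
            raise ContractError(
                f"rule {self.backprop_rule!r} requires a model with rectifier units"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.model.forward(x)

    def output_shape(self, x: np.ndarray) -> tuple[int, ...]:
        return self.forward(x).shape

    def _seed_output(self, y_shape, selector) -> np.ndarray:
        seed = np.zeros(y_shape)
        seed[selector] = 1.0
        return seed

    def scalar_gradient(self, x: np.ndarray, selector) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        y, caches = self.model.stack.forward(x)
        seed = self._seed_output(y.shape, selector)
        return self.model.stack.backward(seed, caches, self.backprop_rule)

    def rescale_attribution(self, x: np.ndarray, baseline: np.ndarray, selector) -> np.ndarray:
        """Rescale-rule contributions relative to a reference input."""
        x = np.asarray(x, dtype=np.float64)
        baseline = np.asarray(baseline, dtype=np.float64)
        if baseline.shape != x.shape:
            raise ValueError("baseline shape must match input shape")
        y_x, cx = self.model.stack.forward(x)
        y_b, cb = self.model.stack.forward(baseline)
        seed = self._seed_output(y_x.shape, selector)
        m = self.model.stack.multipliers(seed, cx, cb)
        return m * (x - baseline)


def as_handle(model, backprop_rule: str = "true_gradient") -> DifferentiableModelHandle:
    """Wrap a model in the differentiable-model contract with a backward rule."""
    return DifferentiableModelHandle(model=model, backprop_rule=backprop_rule)


def build_toy_embedder(
    e: int,
    lam: float,
    property_sensitivity: tuple[str, float] | None = None,
    seed: int = 0,
    hidden_dim: int = 16,
) -> ToyEmbedderModel:
    return ToyEmbedderModel(
        embedding_dim=e,
        locality_decay=lam,
        hidden_dim=hidden_dim,
        property_sensitivity=property_sensitivity,
        seed=seed,
    )


def build_window_predictor(
    e: int,
    w: int,
    property_sensitivity: tuple[str, float] | None = None,
    seed: int = 0,
    hidden_dim: int = 16,
    output_bias_shift: float = 0.0,
) -> WindowPredictor:
    return WindowPredictor(
        embedding_dim=e,
        half_window=w,
        hidden_dim=hidden_dim,
        property_sensitivity=property_sensitivity,
        seed=seed,
        output_bias_shift=output_bias_shift,
    )


def build_planted_pair(
    property_name: str,
    beta: float = 3.0,
    predictor_beta: float = 0.5,
    e: int = 8,
    w: int = 4,
    lam: float = 1.0,
    seed: int = 0,
) -> tuple[ToyEmbedderModel, WindowPredictor]:
    """An embedder/predictor pair sharing one planted property channel.

    The embedder stores ``beta x`` the property-channel encoding on
    activation channel 0 (default 3x the typical scale of the other
    channels, a strongly property-aware model); the predictor reads that
    channel of its centre residue through a linear bypass of weight
    ``predictor_beta`` (moderate by default, keeping the sigmoidal head in
    its responsive range).  This is the default planted-effect
    configuration used in parameter-recovery simulations.
    """
    emb = build_toy_embedder(e, lam, property_sensitivity=(property_name, beta), seed=seed)
    # the planted channel is strictly positive; compensate the head's output
    # bias by the expected bypass contribution (channel mean x locality
    # kernel mass) so the sigmoid stays in its responsive range
    channel_mean = float(_property_channel(property_name).mean())
    kernel_mass = 1.0 + 2.0 / np.expm1(lam) if lam > 0 else float("inf")
    shift = -predictor_beta * beta * channel_mean * kernel_mass
    pred = build_window_predictor(
        e, w, property_sensitivity=(property_name, predictor_beta), seed=seed + 1,
        output_bias_shift=shift,
    )
    return emb, pred


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a toy model's parameters to HDF5 with a JSON manifest."""
    if isinstance(model, ToyEmbedderModel):
        kind = "embedder"
        meta = {
            "embedding_dim": model.embedding_dim,
            "locality_decay": model.locality_decay,
            "hidden_dim": model.hidden_dim,
            "property_sensitivity": model.property_sensitivity,
            "seed": model.seed,
        }
    elif isinstance(model, WindowPredictor):
        kind = "predictor"
        meta = {
            "embedding_dim": model.embedding_dim,
            "half_window": model.half_window,
            "hidden_dim": model.hidden_dim,
            "property_sensitivity": model.property_sensitivity,
            "seed": model.seed,
        }
    else:
        raise TypeError(f"cannot serialize {type(model)}")
    with h5py.File(path, "w") as fh:
        fh.attrs["kind"] = kind
        fh.attrs["manifest"] = json.dumps(meta)


def load_model(path):
    """Rebuild a toy model from its HDF5 manifest (parameters are seed-derived)."""
    with h5py.File(path, "r") as fh:
        kind = fh.attrs["kind"]
        meta = json.loads(fh.attrs["manifest"])
    ps = meta["property_sensitivity"]
    ps = tuple(ps) if ps is not None else None
    if kind == "embedder":
        return ToyEmbedderModel(
            embedding_dim=meta["embedding_dim"],
            locality_decay=meta["locality_decay"],
            hidden_dim=meta["hidden_dim"],
            property_sensitivity=ps,
            seed=meta["seed"],
        )
    return WindowPredictor(
        embedding_dim=meta["embedding_dim"],
        half_window=meta["half_window"],
        hidden_dim=meta["hidden_dim"],
        property_sensitivity=ps,
        seed=meta["seed"],
    )
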