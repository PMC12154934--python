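import numpy as np
import pytest

import protattr as pa
from protattr.models import Dense, Flatten, ReLU, Sigmoid, Stack


class LinearModel:
    """A purely affine model (y = x @ A): handle-contract minimal case."""

    def __init__(self, A, b=None):
        self.A = np.asarray(A, dtype=np.float64)
        b = np.zeros(self.A.shape[1]) if b is None else b
        self.stack = Stack([Dense(self.A, b)])

    def forward(self, x):
        return self.stack.forward(np.asarray(x, dtype=np.float64))[0]


class LinearScalarModel:
    """Affine scalar function f(x) = a . x + c over a flattened input."""

    def __init__(self, a, c=0.0):
        a = np.asarray(a, dtype=np.float64).reshape(-1, 1)
        self.a = a
        self.stack = Stack([Flatten(), Dense(a, np.array([c]))])

    def forward(self, x):
        return self.stack.forward(np.asarray(x, dtype=np.float64))[0]


class PositiveRegimeNet:
    """Rectifier net kept strictly in its affine regime for small inputs.

    Non-negative weights and large positive first-layer biases mean every
    pre-activation and every upstream backward signal is positive on the
    test domain, so all nine attribution operators must agree with the
    plain gradient family.
    """

    def __init__(self, d_in, hidden=6, seed=0):
        rng = np.random.default_rng(seed)
        W1 = rng.uniform(0.1, 1.0, size=(d_in, hidden))
        b1 = np.full(hidden, 10.0)
        W2 = rng.uniform(0.1, 1.0, size=(hidden, 1))
        self.stack = Stack([Flatten(), Dense(W1, b1), ReLU(), Dense(W2, np.zeros(1))])
        self.gradient = (W1 @ W2).reshape(-1)  # affine-regime gradient

    def forward(self, x):
        return self.stack.forward(np.asarray(x, dtype=np.float64))[0]


class TinyReluNet:
    """Small mixed-activation scalar net used for oracle comparisons."""

    def __init__(self, shape, hidden=8, seed=0):
        d = int(np.prod(shape))
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0, 1 / np.sqrt(d), size=(d, hidden))
        self.b1 = rng.normal(0, 0.3, size=hidden)
        self.W2 = rng.normal(0, 1 / np.sqrt(hidden), size=(hidden, 1))
        self.b2 = rng.normal(0, 0.1, size=1)
        self.stack = Stack([
            Flatten(),
            Dense(self.W1, self.b1),
            ReLU(),
            Dense(self.W2, self.b2),
        ])

    def forward(self, x):
        return self.stack.forward(np.asarray(x, dtype=np.float64))[0]


class IdentityEmbedder:
    """Embedder whose output equals its input activations."""

    def __init__(self):
        self.stack = Stack([])

    def forward(self, x):
        return self.stack.forward(np.asarray(x, dtype=np.float64))[0]


@pytest.fixture(scope="session")
def property_table():
    return pa.load_property_table()


@pytest.fixture(scope="session")
def manifest():
    return pa.load_protein_manifest()


@pytest.fixture(scope="session")
def reported():
    return pa.load_reported_pvalues()


@pytest.fixture
def toy_embedder():
    return pa.build_toy_embedder(4, 1.0, seed=11)


@pytest.fixture
def toy_predictor():
    return pa.build_window_predictor(4, 2, seed=12)


@pytest.fixture
def small_corpus():
    return pa.generate_synthetic_proteins(4, (12, 16), 0.3, seed=21)
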