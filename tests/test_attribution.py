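import numpy as np
import pytest

import protattr as pa
import protattr.attribution as at
from protattr.attribution import AttributionConfig, AttributionNumericError, attribute
from protattr.models import ContractError, as_handle

from conftest import IdentityEmbedder, LinearScalarModel, PositiveRegimeNet, TinyReluNet


@pytest.fixture
def linear_scalar():
    a = np.array([1.5, -2.0, 0.7, 3.0, -0.4, 1.1])
    return a, as_handle(LinearScalarModel(a))


@pytest.fixture
def relu_net():
    net = TinyReluNet((2, 3), seed=4)
    return net, as_handle(net)


class TestGradientFamily:
    def test_saliency_of_linear_map_is_the_coefficient(self, linear_scalar):
        a, h = linear_scalar
        x = np.random.default_rng(0).normal(size=6)
        assert np.allclose(pa.saliency(h, x, (0,)).values, a)

    def test_saliency_of_constant_function_is_zero(self):
        h = as_handle(LinearScalarModel(np.zeros(4), c=2.5))
        assert np.all(pa.saliency(h, np.ones(4), (0,)).values == 0.0)

    def test_saliency_matches_finite_differences(self, relu_net):
        net, h = relu_net
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=(2, 3))
            g = pa.saliency(h, x, (0,)).values
            j, l = rng.integers(2), rng.integers(3)
            eps = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[j, l] += eps
            xm[j, l] -= eps
            fd = (net.forward(xp)[0] - net.forward(xm)[0]) / (2 * eps)
            assert g[j, l] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_input_x_gradient_composes_saliency_with_input(self, relu_net):
        _, h = relu_net
        x = np.random.default_rng(2).normal(size=(2, 3))
        ixg = pa.input_x_gradient(h, x, (0,)).values
        sal = pa.saliency(h, x, (0,)).values
        assert np.array_equal(ixg, sal * x)
        assert np.all(pa.input_x_gradient(h, np.zeros((2, 3)), (0,)).values == 0.0)

    def test_rule_mismatch_is_a_contract_error(self, relu_net):
        _, h = relu_net  # true_gradient handle
        with pytest.raises(ContractError):
            pa.deconvolution(h, np.zeros((2, 3)), (0,))
        with pytest.raises(ContractError):
            pa.guided_backprop(h, np.zeros((2, 3)), (0,))


class TestReferenceMethods:
    def test_deeplift_zero_at_reference(self, relu_net):
        _, h = relu_net
        x = np.random.default_rng(3).normal(size=(2, 3))
        assert np.all(pa.deeplift(h, x, x, (0,)).values == 0.0)

    def test_deeplift_linear_equals_input_x_gradient(self, linear_scalar):
        a, h = linear_scalar
        x = np.random.default_rng(4).normal(size=6)
        assert np.allclose(pa.deeplift(h, x, None, (0,)).values, a * x)

    @pytest.mark.parametrize("seed", range(20))
    def test_conservation_on_seeded_rectifier_nets(self, seed):
        """DeepLIFT, IG and KernelShap satisfy summation-to-delta."""
        net = TinyReluNet((2, 3), seed=seed)
        h = as_handle(net)
        x = np.random.default_rng(seed + 100).normal(size=(2, 3))
        delta = net.forward(x)[0] - net.forward(np.zeros((2, 3)))[0]
        dl = pa.deeplift(h, x, None, (0,)).values
        assert dl.sum() == pytest.approx(delta, abs=1e-6)
        ig = pa.integrated_gradients(h, x, None, 2048, (0,)).values
        assert ig.sum() == pytest.approx(delta, abs=1e-3)
        ks = pa.kernelshap(h, x, 200, seed=seed, output_selector=(0,)).values
        assert ks.sum() == pytest.approx(delta, abs=1e-8)

    def test_integrated_gradients_linear_is_exact_at_any_step_count(self, linear_scalar):
        a, h = linear_scalar
        x = np.random.default_rng(5).normal(size=6)
        for steps in (2, 7, 50):
            ig = pa.integrated_gradients(h, x, None, steps, (0,)).values
            assert np.allclose(ig, a * x, atol=1e-12)
        assert np.all(pa.integrated_gradients(h, x, x, 8, (0,)).values == 0.0)

    def test_gradientshap_linear_closed_form(self, linear_scalar):
        a, h = linear_scalar
        x = np.random.default_rng(6).normal(size=6)
        gs = pa.gradientshap(h, x, None, 200, 0.1, seed=0, output_selector=(0,)).values
        assert np.allclose(gs, a * x, atol=1e-10)  # linear: exact per draw

    def test_gradientshap_approaches_integrated_gradients(self, relu_net):
        _, h = relu_net
        x = np.random.default_rng(7).normal(size=(2, 3))
        gs = pa.gradientshap(h, x, None, 4000, 0.0, seed=0, output_selector=(0,)).values
        ig = pa.integrated_gradients(h, x, None, 512, (0,)).values
        assert np.abs(gs - ig).max() <= 0.05 * np.abs(ig).max()

    def test_gradientshap_seed_reproducibility(self, relu_net):
        _, h = relu_net
        x = np.random.default_rng(8).normal(size=(2, 3))
        a = pa.gradientshap(h, x, None, 50, 0.1, seed=3, output_selector=(0,)).values
        b = pa.gradientshap(h, x, None, 50, 0.1, seed=3, output_selector=(0,)).values
        assert np.array_equal(a, b)


class TestSurrogateMethods:
    def test_lime_recovers_additive_function_exactly(self, linear_scalar):
        a, h = linear_scalar
        x = np.random.default_rng(9).normal(size=6)
        lm = pa.lime(h, x, 64, surrogate_ridge=0.0, seed=0, output_selector=(0,)).values
        assert np.abs(lm - a * x).max() < 1e-6

    def test_lime_constant_function_gives_zero_coefficients(self):
        h = as_handle(LinearScalarModel(np.zeros(5), c=1.0))
        lm = pa.lime(h, np.ones(5), 32, surrogate_ridge=0.0, seed=0,
                     output_selector=(0,)).values
        assert np.abs(lm).max() < 1e-6

    def test_lime_seed_reproducibility(self, relu_net):
        _, h = relu_net
        x = np.random.default_rng(10).normal(size=(2, 3))
        a = pa.lime(h, x, 40, seed=5, output_selector=(0,)).values
        b = pa.lime(h, x, 40, seed=5, output_selector=(0,)).values
        assert np.array_equal(a, b)

    def test_lime_sample_budget_precondition(self, relu_net):
        _, h = relu_net
        with pytest.raises(ValueError):
            pa.lime(h, np.zeros((2, 3)), 4, output_selector=(0,))

    def test_kernelshap_recovers_additive_function(self, linear_scalar):
        a, h = linear_scalar
        x = np.random.default_rng(11).normal(size=6)
        ks = pa.kernelshap(h, x, 4096, seed=0, output_selector=(0,)).values
        assert np.allclose(ks, a * x, atol=1e-10)

    def test_kernelshap_symmetry_axiom(self):
        # two exchangeable features receive equal values
        h = as_handle(LinearScalarModel(np.array([2.0, 2.0, -1.0])))
        x = np.array([0.7, 0.7, 0.3])
        ks = pa.kernelshap(h, x, 4096, seed=0, output_selector=(0,)).values
        assert ks[0] == pytest.approx(ks[1], abs=1e-12)

    def test_kernelshap_matches_brute_force_shapley(self, relu_net):
        net, h = relu_net  # d = 6: exact enumeration regime
        x = np.random.default_rng(12).normal(size=(2, 3))
        ks = pa.kernelshap(h, x, 4096, seed=0, output_selector=(0,)).values
        bf = pa.exact_shapley(h, x, output_selector=(0,))
        assert np.abs(ks - bf).max() < 1e-10

    def test_kernelshap_sampling_close_to_enumeration(self, monkeypatch):
        # d = 10 under a genuinely partial coalition budget
        net = TinyReluNet((5, 2), seed=9)
        h = as_handle(net)
        x = np.random.default_rng(13).normal(size=(5, 2))
        exact = pa.kernelshap(h, x, 4096, seed=0, output_selector=(0,)).values
        monkeypatch.setattr(at, "_EXACT_ENUMERATION_LIMIT", 2)
        samp = pa.kernelshap(h, x, 500, seed=1, output_selector=(0,)).values
        assert np.abs(samp - exact).max() <= 0.05 * np.abs(exact).max()

    def test_kernelshap_seed_reproducibility_when_sampling(self, monkeypatch):
        net = TinyReluNet((5, 2), seed=9)
        h = as_handle(net)
        x = np.random.default_rng(14).normal(size=(5, 2))
        monkeypatch.setattr(at, "_EXACT_ENUMERATION_LIMIT", 2)
        a = pa.kernelshap(h, x, 300, seed=2, output_selector=(0,)).values
        b = pa.kernelshap(h, x, 300, seed=2, output_selector=(0,)).values
        assert np.array_equal(a, b)


class TestCrossMethodConsistency:
    def test_all_nine_methods_agree_on_affine_regime_net(self):
        """In the rectifiers' affine regime every operator reduces to the
        gradient (saliency family) or gradient * input (the rest)."""
        net = PositiveRegimeNet(6, seed=0)
        x = np.random.default_rng(15).uniform(0.01, 0.2, size=6)
        a = net.gradient
        grads = {
            "saliency": pa.saliency(as_handle(net), x, (0,)).values,
            "deconvolution": pa.deconvolution(as_handle(net, "deconvolution"), x, (0,)).values,
            "guided_backprop": pa.guided_backprop(as_handle(net, "guided"), x, (0,)).values,
        }
        for name, g in grads.items():
            assert np.allclose(g, a, atol=1e-10), name
        scaled = {
            "input_x_gradient": pa.input_x_gradient(as_handle(net), x, (0,)).values,
            "deeplift": pa.deeplift(as_handle(net), x, None, (0,)).values,
            "integrated_gradients": pa.integrated_gradients(as_handle(net), x, None, 16, (0,)).values,
            "kernelshap": pa.kernelshap(as_handle(net), x, 100, seed=0, output_selector=(0,)).values,
            "lime": pa.lime(as_handle(net), x, 64, surrogate_ridge=0.0, seed=0,
                            output_selector=(0,)).values,
            "gradientshap": pa.gradientshap(as_handle(net), x, None, 100, 0.0, seed=0,
                                            output_selector=(0,)).values,
        }
        for name, g in scaled.items():
            assert np.allclose(g, a * x, atol=1e-6), name


class TestTensorDrivers:
    def test_identity_embedder_yields_kronecker_delta(self):
        h = as_handle(IdentityEmbedder())
        x = np.random.default_rng(16).normal(size=(3, 2))
        E = pa.compute_embedding_attribution(h, x, AttributionConfig(method="saliency"))
        expected = np.zeros((3, 2, 3, 2))
        for i in range(3):
            for k in range(2):
                expected[i, k, i, k] = 1.0
        assert np.array_equal(E, expected)

    def test_tensor_equals_stack_of_per_scalar_maps(self, toy_embedder):
        h = as_handle(toy_embedder)
        x = toy_embedder.embed("ACD")
        cfg = AttributionConfig(method="saliency")
        E = pa.compute_embedding_attribution(h, x, cfg)
        for i in range(3):
            for k in range(4):
                single = attribute(h, x, (i, k), cfg).values
                assert np.array_equal(E[i, k], single)

    @pytest.mark.parametrize("method", ["saliency", "input_x_gradient", "deeplift",
                                        "integrated_gradients"])
    def test_streamed_reductions_bit_equal_materialized(self, toy_embedder, method):
        h = as_handle(toy_embedder)
        x = toy_embedder.embed("ACDEFGH")
        cfg = AttributionConfig(method=method, ig_steps=8)
        E = pa.compute_embedding_attribution(h, x, cfg)
        streamed = pa.compute_embedding_attribution(h, x, cfg, stream=True)
        assert np.array_equal(pa.collapse_to_T(E), streamed.T)
        assert np.array_equal(pa.collapse_to_XE(E).X, streamed.XE)

    def test_input_blind_predictor_gives_zero_attributions(self):
        h = as_handle(LinearScalarModel(np.zeros(6), c=0.3))
        emb = np.random.default_rng(17).normal(size=(5, 2))
        P = pa.compute_prediction_attribution(h, emb, 1, AttributionConfig(method="saliency"))
        assert P.shape == (5, 3, 2)
        assert np.all(P == 0.0)

    def test_degenerate_window_w0(self):
        h = as_handle(LinearScalarModel(np.array([1.0, -2.0])))
        emb = np.random.default_rng(18).normal(size=(4, 2))
        P = pa.compute_prediction_attribution(h, emb, 0, AttributionConfig(method="saliency"))
        assert P.shape == (4, 1, 2)
        assert np.allclose(P, np.array([1.0, -2.0]))

    def test_linear_predictor_saliency_rows_are_the_weights(self):
        a = np.random.default_rng(19).normal(size=6)
        h = as_handle(LinearScalarModel(a))
        emb = np.random.default_rng(20).normal(size=(7, 2))
        P = pa.compute_prediction_attribution(h, emb, 1, AttributionConfig(method="saliency"))
        for i in range(7):
            assert np.allclose(P[i].reshape(-1), a)

    def test_per_scalar_failure_names_the_offending_element(self, toy_embedder):
        h = as_handle(toy_embedder)
        x = toy_embedder.embed("ACDE")
        cfg = AttributionConfig(method="lime", mc_samples=3)  # below d+1
        with pytest.raises(AttributionNumericError, match=r"\(0, 0\)"):
            pa.compute_embedding_attribution(h, x, cfg)
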