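"""Explanation infidelity: how well attributions predict output change.

Perturbs the embedding-layer activations with Gaussian noise (sigma =
0.01) and scores each attribution map by the expected squared gap between
its linear prediction of the output change and the actual change.  Exact
gradients of a near-linear model score close to zero; a method's score
rises with the model's curvature and the method's approximation error.
"""

import protattr as pa
from protattr.attribution import AttributionConfig
from protattr.infidelity import PerturbationSpec, embedding_infidelity, prediction_infidelity
from protattr.models import as_handle

w = 2
embedder = pa.build_toy_embedder(e=6, lam=1.0, seed=0)
predictor = pa.build_window_predictor(e=6, w=w, seed=1)
record = pa.generate_synthetic_proteins(1, (15, 15), 0.3, seed=3)[0]
x = embedder.embed(record.sequence)
spec = PerturbationSpec(std=0.01, n_samples=100, seed=0)

print(f"protein {record.name} (n={record.length}); sigma={spec.std}, "
      f"{spec.n_samples} perturbations")
print(f"{'method':<22} {'INFD_E':>12} {'INFD_P':>12}")
for method in ("saliency", "input_x_gradient", "deeplift", "integrated_gradients"):
    cfg = AttributionConfig(method=method, ig_steps=16)
    handle = as_handle(embedder)
    E = pa.compute_embedding_attribution(handle, x, cfg)
    I_E, infd_e = embedding_infidelity(handle, x, E, spec)
    emb_out = embedder.forward(x)
    P = pa.compute_prediction_attribution(as_handle(predictor), emb_out, w, cfg)
    rec = prediction_infidelity(as_handle(predictor), emb_out, P, I_E, w, spec)
    print(f"{method:<22} {infd_e:12.3e} {rec.INFD_P:12.3e}")
# The pure gradient scores lowest on this mildly nonlinear embedder; the
# windowed sigmoid head adds curvature, so INFD_P sits higher than INFD_E
# for every method.
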