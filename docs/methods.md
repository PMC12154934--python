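# Methods

This note records the models, procedures, parameter defaults and design
choices behind `protattr`, in the order the pipeline runs them.

## Toy models and the differentiable contract

The attribution operators only require a *handle*: `forward(x)`,
`scalar_gradient(x, selector)` honouring one of three rectifier backward
rules, and a rescale-multiplier pass for reference-based attribution.
Anything implementing that contract — including adapters around real
pretrained models — runs through the entire pipeline unchanged; the test
suite exercises this with a plain linear adapter.

The bundled stand-ins are deliberately small:

- **Embedder** (n × e → n × e, default e = 8, hidden width 16): a
  per-letter look-up table produces the input activations; a positional
  mixing layer `K[i,j] = exp(−λ|i−j|)` (locality decay λ, default 1.0 —
  influence drops to ~5% three residues away) feeds a one-hidden-layer
  ReLU network applied position-wise. Attribution is always taken with
  respect to the look-up output activations, the continuous object, never
  the discrete letters (a look-up table has no gradient).
- **Window predictor** ((2w+1) × e → (0,1), default w = 4, matching the
  odd-window convention of sequence-based interaction-site predictors):
  flatten, one ReLU hidden layer, sigmoid head. w is a configuration
  parameter throughout, never hard-coded.
- All nonlinearities are rectifiers (plus the terminal sigmoid) because
  deconvolution and guided backpropagation are *defined* by rectifier
  backward rules; on smooth nonlinearities those two operators have no
  canonical meaning. Requesting a modified rule on a rectifier-free model
  is a contract error rather than a silent no-op.

**Planted property channels.** For power studies the embedder can carry a
dedicated activation channel holding an affine encoding of one numerical
property (standardized to unit spread, shifted to minimum 0.5). The
encoding is rank-preserving — Kendall-based detection targets the same
ordering as the raw property — and strictly positive, so the planted
signal keeps a consistent sign through the products of activations that
arise when predictor attributions are composed back through the
embedder (a zero-mean encoding enters those products partially squared
and scrambles the sign). An identity bypass carries the channel through
the hidden layers; the paired predictor reads the channel of its centre
residue through a linear bypass whose expected contribution (channel
mean × locality kernel mass, both known in closed form) is subtracted
from the output bias so the sigmoid stays responsive. Default effect
sizes: embedder channel weight 3.0 (three times the typical scale of the
other channels — a strongly property-aware model), predictor bypass 0.5.
With these defaults the planted hydrophobicity signal is detected
(Kendall p < 0.05) in ≥ 90% of seeded replicates in all four
mode × role readouts.

## Attribution operators

All nine operators explain one scalar output. Hyperparameter defaults
(none are canonical to the analysis itself; all are recorded in each
map's provenance): integrated gradients 50 midpoint steps; LIME and
KernelShap 200 perturbation samples; GradientShap 50 samples with jitter
σ = 0.1; LIME kernel width 0.75·√d on Hamming distance, ridge 10⁻³
(intercept unpenalized); baseline all-zero activations everywhere — the
natural reference for an absent token at the embedding-layer output.

Implementation notes:

- DeepLIFT implements the rescale rule only; multipliers chain exactly
  through linear layers, so summation-to-delta holds to float precision.
- KernelShap solves the Shapley-kernel weighted least squares with the
  efficiency constraint eliminated exactly. All 2^d − 2 coalitions are
  enumerated when 2^d ≤ 4096; under a finite budget, complete coalition
  sizes are enumerated outright (smallest/largest first, where the kernel
  mass concentrates) and only the remaining sizes are sampled, each
  sampled row carrying an equal share of the leftover kernel mass.
- LIME and KernelShap use one feature per input element, matching the
  element-level influence tensor.
- Stochastic operators derive a per-scalar seed from (config seed, scalar
  index): maps are independent across outputs yet bit-reproducible.

**Tensor drivers.** The embedding driver either materializes
E (n, e, n, e) or streams per-scalar maps directly into the collapsed
T (n, e, n) without holding E — at real-model scale E is the object that
runs to terabytes, so the streamed path is the production one. Both paths
share one accumulation order and agree bit-exactly. Prediction windows at
the sequence ends are zero-padded, consistent with the zero baseline.

## Aggregation

The published formulas are 1-based; internally everything is 0-based
with the window offset `i + k − (w+1)` → `i + k − w`, property-tested
against a literal 1-based loop oracle at both sequence ends. Window
positions outside the sequence contribute zero. X matrices keep raw
signed sums: no absolute value, no symmetrization, no normalization;
downstream consumers choose their transform.

## Statistical evaluation

- **Unit of observation.** Mann–Whitney tests pool *per-residue* scores
  across all proteins (residue-level sample sizes are what make extreme
  p-values attainable); Kendall tests use the 20-dimensional
  per-amino-acid mean-score vectors, as the four-vector construction
  prescribes. Letters absent from a corpus are flagged missing, and a
  test whose category is empty (or whose score vector is constant) is
  marked not-evaluable — never silently passed.
- **Transforms.** Signed scores for property tests (the formulas are
  plain sums); absolute values for distance profiles (magnitude decay is
  the quantity of interest). Both are configurable and recorded.
- **Mann–Whitney:** midrank ties; exact null enumeration when
  n₁·n₂ ≤ 200 without ties, otherwise the tie-corrected normal
  approximation with continuity correction.
- **Kendall:** τ-b with tie correction; exact p for short tie-free
  inputs, tie-corrected asymptotic otherwise (scipy's switching rule,
  which is also the convention the reference p-value tables follow — the
  property columns contain ties, so those tests take the asymptotic
  path).
- **Pass rule:** p < α with α = 0.05; no multiple-testing correction
  (matching the published evaluation design). α ≥ 1 is treated as the
  degenerate always-pass threshold so that summary totals reduce to grid
  sizes.
- **Percentages** round half away from zero to integer percent.
- **Exclusivity denominators.** The published exclusivity percentages
  mix two denominators: the categorical figure is exactly-one-model
  passes over the *full* test grid, while the numerical and overall
  figures are over the tests passed by *at least one* model (the only
  reading under which all three printed values are arithmetically
  consistent with the printed counts). The summary therefore reports
  both fractions explicitly.
- **Separability check.** One moment-matched Gaussian matrix (same
  shape, mean, standard deviation) per real matrix; variable-size
  matrices are featurized by bilinear resampling to a 32 × 32 grid and
  flattening; features are standardized on the training split; RBF-kernel
  SVM (C = 1, γ = scale) on a seeded stratified 80/20 split. The random
  ensemble and featurization are this package's choices — the original
  evaluation specifies neither.

**Calibration, measured by the test suite.** Null rejection rates of
both tests sit in [0.04, 0.06] at α = 0.05 over 5000 replicates. For the
no-planted-signal embedder, the pooled per-property Kendall rejection
rate stays within a 3σ binomial band of 0.05; note that "no property is
significant" across four correlated property tests is a familywise event
with null probability ≈ 0.85, not 0.95, and is asserted at that level.

## Infidelity

Monte-Carlo estimate with Gaussian perturbations, mean 0, σ = 0.01 in
raw activation units (the activation scale of the toy models is ~1, so
this is a small-signal probe), 100 samples by default (the sample count
is a package default; doubling it moves toy-scale estimates by < 5%).
One shared perturbation ensemble serves every output scalar of an
embedder, so the whole n × e infidelity matrix costs n_samples forward
passes; the per-scalar definition is recovered exactly by feeding the
same draws to a scalar-by-scalar oracle.

For the prediction-mode aggregate, per-residue infidelities are scored
against the predictor attribution P[i,:,:] of each residue's window (the
quantity that scores the predictor's explanations; scoring the embedder
reduction T against the predictor function would be type-inconsistent)
and combined with the embedding infidelities by window multiplicity:
interior residues appear in 2w+1 windows, the i-th residue from either
end in w+i. The printed normalizer contains the term w(3w+1), although
the boundary weight sum it abbreviates, Σ_{i=w+1}^{2w} i, equals
w(3w+1)/2; both variants are implemented behind a flag
(`denominator="as_printed"` is the default, `"derived"` the algebraic
one) rather than silently correcting either. The hand-evaluable case
n = 5, w = 1, constant infidelities a and b, gives S = 13(a+b) and
normalizer 13 under the as-printed variant, hence INFD_P = a + b.

## Synthetic data: what it does and does not emulate

The generator draws residues i.i.d. uniform over the 20 letters
(optionally composition-biased) and labels i.i.d. Bernoulli(0.3) — an
interaction-site prevalence typical of annotated interface datasets —
with lengths uniform on [30, 44], the length window of the real test
manifest. It reproduces the *statistical shape* of the analysis inputs
(alphabet, lengths, label rates) but none of the biology: no sequence
autocorrelation, no real interface chemistry, no coupling between labels
and composition. Passing tests therefore certify the correctness and
calibration of the machinery — the algebra, the tests, the detection
power on planted signals — not any claim about what real protein
language models have learned. The bundled 34-chain manifest carries no
interaction labels (the originals derive from an external annotation
set not redistributed here); synthetic records always carry labels.

## Problem sizes

Everything is sized for a single CPU: toy dimensions e = 8, hidden 16,
w = 2–4; corpora of 10–20 proteins for power studies and 100 proteins
for the separability computation; 20 seeded replicates for recovery
rates; 5000 replicates for type-I calibration; the full
3 × 9 × 2 pipeline grid runs on miniature models in the suite. The
algebra is size-independent, so these choices affect runtime and Monte
Carlo error only.

## Known limitations

- The toy models are one-hidden-layer networks; they validate operators
  and algebra, not transformer-specific behaviour (attention, deep
  feature mixing).
- Deconvolution and guided backpropagation are only defined for
  rectifier models; adapters for smooth real models can serve the other
  seven operators.
- LIME/KernelShap at element granularity become expensive for large
  n × e inputs (the sample budget must exceed the element count);
  residue-level grouping would be the practical variant at scale but is
  not the default because the influence tensor is defined at element
  level.
- The infidelity aggregate inherits the printed normalizer ambiguity
  described above; comparisons across packages should state which
  variant they use.
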