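# Methods

## Model

A CRE is an ordered string of single-character binding-site codes, padded
5' with `O` to a fixed number of site positions and suffixed with a basal
promoter character, so that all sequences in a dataset share one length L.
The latent phenotype of sequence s is

    φ(s) = θ₀ + Σᵢ θ_add[i, sᵢ] + Σ_{(i,j) ∈ P} θ_pair[i, j, sᵢ, sⱼ]

where the pair set P is empty (additive), adjacent positions only
(nearest-neighbor), or all i < j (pairwise). Parameters exist only for
characters that can actually occur at a position: promoter letters carry
parameters only at the promoter position, and a position where a single
character ever occurs carries no free parameter at all. A "black box"
variant replaces the linear map with a multilayer perceptron (two hidden
layers of 32 tanh units) on the additive one-hot block; it makes no
assumption about interaction order and serves as a capacity ceiling when
comparing architectures.

The measurement process maps φ to the most probable measurement through a
monotone saturating nonlinearity

    g(φ) = a + Σₖ bₖ tanh(cₖ φ + dₖ),  bₖ, cₖ ≥ 0  (K = 20 by default),

and models the observed log2 activity y around ŷ = g(φ) with either

- a **skewed-t** density (Jones–Faddy family) whose log scale and two log
  shape parameters are each degree-≤2 polynomials of ŷ (heteroskedasticity
  order 2). The density is mode-centred: the standard Jones–Faddy mode
  (a−b)√(a+b)/(√(2a+1)√(2b+1)) is subtracted so that ŷ is the most
  probable value. With equal shapes it reduces to a scaled Student-t and
  is symmetric about ŷ. Samples use the Beta representation
  T = √(a+b)(2B−1)/(2√(B(1−B))), B ~ Beta(a,b), verified against the
  implemented density by a Kolmogorov–Smirnov test; or
- a **gaussian** with log σ a polynomial of ŷ, used as a faster and
  better-conditioned family for benchmarks whose generative noise is
  gaussian.

## Identifiability and gauges

Two redundancies are resolved explicitly.

1. *Affine redundancy between φ and g*: rescaling φ can be absorbed by g.
   At export the fitted φ is standardized to mean 0 / SD 1 over the
   training rows and the inverse affine map is folded into (cₖ, dₖ), so
   GP-map parameters are comparable across restarts and bootstrap refits.
2. *Gauge freedom of the parameterization*: adding a constant to all
   characters at one position (and analogous shifts of pair blocks)
   leaves φ unchanged. The **uniform gauge** makes every position's
   additive parameters zero-mean and every pair block's rows and columns
   zero-mean, by closed-form mean subtraction. The **consensus gauge**
   (anchored, for the CRX–NRL encoding, on the all-pad + Hsp68 sequence
   `OOOOH`) is computed by finite differences of φ around the consensus;
   every parameter touching only consensus characters is exactly zero and
   θ₀ = φ(consensus), so the basal sequence itself scores zero once θ₀ is
   referenced to baseline. Both projections are verified in the tests by
   exhaustive φ comparison (|Δφ| < 10⁻⁹) rather than trusted
   algebraically. Gauge fixing is idempotent.

When interpreting uniform-gauge summaries, note that single-character
additive values are relative to the position average (which includes the
pad), and that the mean-subtraction moves part of strong homotypic pair
blocks into the additive terms; sign statements about *interactions* are
gauge-stable in practice, additive comparisons are cleanest in the
consensus gauge.

## Fitting

All parameters — GP map, nonlinearity, and noise polynomials — are fit
jointly by maximizing the training log likelihood with minibatch Adam
(defaults: learning rate 0.001, batch 200, up to 1000 epochs, early
stopping patience 30 on the validation loss), followed by a deterministic
full-batch L-BFGS polish that is kept only if the validation loss does not
degrade. Two numerical choices matter:

- *Noise warm-up*: for the first 100 epochs the noise-model parameters are
  frozen. Otherwise the optimizer can settle into a local optimum where
  the heteroskedastic scale inflates in the tails instead of the mean
  model fitting them.
- *L-BFGS polish*: with a jointly learned noise scale the loss sharpens as
  residuals shrink, and fixed-step Adam ends up oscillating short of the
  optimum; the polish removes this floor, which matters most for
  low-noise data and for bootstrap standard deviations.

Monotonicity of g is enforced by parameterizing bₖ and cₖ through a
softplus. Data are split 80/10/10 into train/validation/test by a seeded
permutation (validation and test sizes floored, remainder to train); the
same split is reused across restarts, and `multi_restart_fit` returns the
restart with the best validation likelihood (switchable in principle to
validation R²; the likelihood is the default selection objective). A
replicate mode treats each (sequence, replicate) measurement as its own
row, for datasets where averaging replicates first discards too much
signal. Divergence (non-finite loss) raises an error naming the epoch.
Training is bit-reproducible given the seed: the backend is pure numpy
with a seeded generator.

## Metrics

Predictive information is estimated as I = H(y) − H(y|φ), with
H(y|φ) = −(1/N) Σ log₂ p(yᵢ | g(φᵢ)) under the fitted noise model and
H(y) from the Kozachenko–Leonenko k-nearest-neighbor differential entropy
estimator with k = 5 (the per-row spread of the conditional term gives a
standard error). On a simulated gaussian channel with SNR 3 at N = 10,000
the estimator reproduces the closed form ½log₂(1+SNR) = 1 bit to within
±0.05. Fit quality on held-out rows is reported as R² = 1 − SS_res/SS_tot
(which can be negative for a model worse than the mean) and Pearson r.

Parameter uncertainties use a parametric bootstrap: measurements are
resimulated from the fitted noise model at each sequence's ŷ (sequences
and split fixed), the model is refit from a fresh random initialization,
and per-parameter SDs are taken across refits **after uniform gauge
fixing**, so they do not depend on the gauge of the original fit.

## Synthetic data

`sample_ground_truth` draws either random effects (additive i.i.d.
normal; pairwise normal × Bernoulli sparsity) or a structured "retina-like"
pattern: positive additive site effects scaled by affinity (1.0 / 0.7 /
0.4 for high / medium / low), negative homotypic pair effects (−0.8 ×
product of affinity scales), positive CRX–NRL heterotypic effects (+0.5 ×
scale), a CRX–Rho-promoter antagonism (−0.3), and a Rho-promoter additive
boost (+1.2), each entry multiplied by a per-entry lognormal-style jitter
(1 + N(0, 0.1)) that preserves the sign pattern. The stored truth is
uniform-gauge fixed; the as-constructed values are kept alongside for
sign-pattern checks. The truth readout is a single gently saturating tanh
component that is near-identity over the phenotype range, and benchmark
noise defaults to a gaussian with SD 0.1 × SD(φ).

The `crx_nrl_like` preset reproduces the shape of the CRX–NRL library:
584 exhaustive one- to three-site arrangements over the 8-token alphabet
plus 715 sampled four-site arrangements (1,299 CREs), each assigned a Rho
or Hsp68 promoter and encoded to four site positions plus the promoter
letter. `cdnrm_like` gives five-site forward-only mixtures over the
11-token CRX/NEUROD1/NRL/RORB/MAZ alphabet; `liver_like` gives binned
encodings of variable-position sites over two background letters.

`simulate_counts` emulates barcode-level structure: DNA (plasmid) reads
negative-binomial around the target depth, RNA reads Poisson with mean
proportional to DNA × 2^activity, 3 barcodes per CRE and 90 for the basal
construct. These count laws are a modeling choice to exercise the
filtering and normalization paths, not an inference target; at depth 10⁶
the full processing chain recovers true log2 activities to within 0.02.

What the synthetic benchmarks do *not* emulate: position-specific effect
heterogeneity beyond the jitter, higher-than-pairwise interactions (except
in dedicated parity-style tests), sequence-level effects below the token
resolution (flanking bases, motif variants), barcode-specific biases, and
replicate batch structure. Passing tests therefore demonstrate that the
estimators recover the truth under the model's own assumptions, not that
those assumptions hold for any particular real library.

## Benchmark scales and expected behavior

Problem sizes used in the test suite were chosen to exercise each property
at the smallest scale where it is statistically clean: parameter recovery
uses the full 1,299-CRE benchmark with 3 restarts (uniform-gauge additive
parameters correlate with truth at r ≥ 0.95, pairwise at r ≥ 0.90, and the
pairwise fit beats additive and nearest-neighbor validation likelihoods);
bootstrap behavior uses a 300-CRE additive-truth benchmark with n = 5
refits, where halving the generative noise roughly halves the parameter
SDs. The bootstrap benchmark deliberately matches the fitted architecture
to the truth: when the fitted model is misspecified (e.g. an additive fit
to pairwise truth), its noise model absorbs the unexplained structure and
bootstrap SDs track that structure rather than the measurement noise —
with the side effect that a nearest-neighbor model's validation
*likelihood* can trail an additive model's on strongly non-neighbor truth
even while its point predictions are better, because its overfit noise
scale is miscalibrated on held-out rows. Likelihood-nesting checks
therefore use data whose truth matches the nested architecture.

## Known limitations

- The trainer is CPU-bound pure numpy; it is comfortable at the scale of
  these libraries (~10³–10⁴ sequences, ~10²–10³ features) but not intended
  for genome-scale models or raw-nucleotide inputs.
- The skewed-t shape polynomials can be weakly identified when the data
  are nearly gaussian; the gaussian family is the recommended default for
  gaussian-noise benchmarks.
- The CDNRM-style designer enumerates 3-1-1 and 2-2-1 compositions with a
  configurable set of CRX-affinity multisets; the exact affinity-mixture
  rule of the original 6,600-CRE library is not recoverable from its
  description, so the library size is reported, not asserted.
- Bootstrap SDs include a small optimizer-noise floor from random
  re-initialization; the L-BFGS polish keeps it well below the
  data-driven component at the benchmark scales.
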