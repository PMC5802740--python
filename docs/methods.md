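# Methods

## Model

A single observed result is summarized by a test statistic whose sampling
distribution belongs to one of four families: normal Z, Student's t,
chi-square, or F.  The statistic's departure from the point null is
governed by a noncentrality γ that scales a *standardized* effect size δ
(effect in standard-deviation units) by the effective sample size
N = 1/(1/n₁ + 1/n₂), half the harmonic mean of the two group sizes:
γ = √N·δ for the signed families, γ = N·δ² for the nonnegative ones.
A replication study is an independent draw of the same statistic at the
same γ (or, when δ itself is random, at a fresh δ from the same
population of effects).

Three interval constructions are implemented, all equal-tailed at level
1−α (probability α/2 outside each endpoint of the predictive
distribution):

1. **Classical P-interval.**  z_obt ± z₁₋α/₂·√2 on the statistic scale.
   Its endpoints are mapped to the P scale through the one-sided upper
   tail of the null distribution.  It is the σ0² → ∞ limit of the
   conjugate interval and carries that flat-prior assumption implicitly.

2. **Conjugate Bayes.**  With μ ~ N(m0, σ0²) on the statistic scale
   (σ0² = N·s0², s0² the prior variance of δ), the posterior is N(θ, s²)
   with θ = z_obt·σ0²/(1+σ0²) + m0/(1+σ0²) and s² = σ0²/(1+σ0²), and the
   predictive for the replication statistic is N(θ, 1+s²).  The default
   prior mean is zero: in the intended applications the direction of an
   unknown effect is a priori symmetric.  A related closed form gives the
   posterior probability of the directional null,
   Pr(H0 | z) = 1 − Φ(z/√(1 + 1/(N·ϑ²))), with ϑ² the prior variance of
   the standardized mean; it tends to the one-sided P-value as N grows.

3. **Mixture Bayes.**  Any prior on δ is expressed as a finite grid
   (δᵢ, Pr(δᵢ)).  Posterior weights are Pr(δⱼ)·f(t_obt | γⱼ) normalized
   over the grid, with f the family's noncentral density; the predictive
   CDF is the posterior-weighted mixture of noncentral CDFs, and interval
   endpoints are its α/2 and 1−α/2 quantiles.  This requires no conjugacy
   and therefore extends to chi-square and F statistics and to empirical,
   asymmetric, fat-tailed priors.

## Discretization of a normal prior

The conjugate prior is discretized for the mixture machinery by
truncating N(m0, σ0²) at its 10⁻⁶ and 1−10⁻⁶ quantiles and cutting the
range into contiguous bins of width σ0/8.  The span is 2·4.753424·σ0, or
76.05 bin widths; we take the 76 full-width bins and stretch the last one
to the upper truncation point, so the component count is exactly B = 76
for every σ0 > 0.  Each component sits at its bin midpoint and carries
the exact prior mass of its bin (CDF difference), renormalized over the
truncated range — a rule under which the probabilities sum to one by
construction.  `step_fraction` and `tail_quantile` are exposed; the
defaults are adequate for moderate prior variances (endpoint agreement
with the conjugate closed form is within 10⁻³ on the statistic scale for
observations up to |z| ≈ 3).  Two regimes need a finer grid and are
documented rather than silently patched: observations beyond the prior's
truncation quantile (the discrepancy grows to ~10⁻² at |z| ≈ 5.6, an
inherent consequence of truncating the prior), and very diffuse priors
(σ0² ≫ 1), where the default bin width σ0/8 exceeds the unit sampling
noise and the posterior collapses onto single grid points — recovering
the classical interval in the σ0² → ∞ limit requires a bin width small
relative to 1 (e.g. `step_fraction=5e-4` at σ0² = 10⁶).

All posterior-weight arithmetic is carried out in log space with a
log-sum-exp normalization: at genome-wide-significant observations the
component densities are of order 10⁻⁸⁰ and direct normalization would
underflow.  Quantiles are found by bracketing the root of F_p(x) = q
between the smallest and largest component-wise q-quantiles (widened
geometrically if needed) and solving with Brent's method; the inversion
residual is required to be below 10⁻¹⁰ in CDF units.  Noncentralities
below 10⁻¹² are routed to the central distribution, where scipy's
noncentral chi-square and F implementations are not reliable at nc = 0.

## Effect-size bounds for odds ratios

For a 2×2 case/control design with outcome frequencies p₁, p₂ and case
proportion v, δ = log(OR)/√(1/(v·p₁q₁) + 1/((1−v)·p₂q₂)) (pooled
approximation: δ ≈ log(OR)·√(p̃(1−p̃)v(1−v))).  Maximizing over all
consistent designs gives the closed form
δ_max(OR) = ln(OR)/(2√(2+(1+OR)/√OR)), verified in the test suite against
brute-force maximization of the exact form over a (p₂, v) grid.  Its
global maximum, found by one-dimensional maximization over log OR, is the
Laplace Limit constant 0.662743… at OR ≈ 121.35.  Inverting a tail
statement Pr(OR ≥ x) = β under a zero-mean normal prior yields the
largest compatible prior variance s0² = (δ_max(x)/Φ⁻¹(1−β))².  Variance
of any prior supported on [L, U] is bounded by Popoviciu's inequality,
(U−L)²/4.

The weighted-variance estimator for s0² from a tabulated OR distribution
(locus counts Lᵢ at ORᵢ out of M tests; residual mass at OR 1.005 and its
inverse, split evenly) is the weighted variance of the δ values.  The
printed form Σ wᵢ(γᵢ/√(2N) − m_w)² reduces to this under the two-group
convention γ = √(2N)·δ, making the estimate independent of N, as a
standardized quantity should be.  The δ map uses the pooled approximation
at a balanced design (p̃ = 0.5, v = 0.5) unless a frequency context is
supplied.

## Coverage simulation

The generative model is the unique one under which the conjugate method
is exactly calibrated: per experiment, γ ~ N(0, σ0²), z_obt ~ N(γ, 1),
and z_rep ~ N(γ, 1) independently given the same γ.  Selection rules:

- **window / threshold** — the experiment is retained only if the
  two-sided P of z_obt falls in [p_low, p_high] (threshold is a window
  from zero).  Selection on the two-sided P — i.e. on |z_obt| — is the
  default because it is the selection under which the published coverage
  behavior of this model is reproduced; one-sided selection is available
  via `sided="one"`.
- **min_of_L** — L independent (γⱼ, zⱼ) pairs are drawn, the pair with
  the smallest one-sided P (largest z) is selected, and z_rep is drawn at
  the selected pair's γ.  This is simulated literally.

Window/threshold selection uses an exact conditional sampler rather than
rejection: z_obt follows the marginal N(0, 1+σ0²) truncated to the
z-image of the constraint (for two-sided constraints, the magnitude is
drawn from the truncated positive branch and given a random sign), after
which γ | z_obt ~ N(z_obt·σ0²/(1+σ0²), σ0²/(1+σ0²)).  This is
distributionally identical to rejection sampling — the test suite checks
the equality with two-sample Kolmogorov–Smirnov tests on 10⁵ draws — but
stays O(n) for windows at genome-wide significance where rejection is
hopeless.  The rejection sampler is retained as a test oracle.

Coverage is the binomial proportion of replicates whose z_rep falls in
the interval built from z_obt, reported with its Monte-Carlo standard
error √(p̂(1−p̂)/reps).  Mixture-interval coverage uses a vectorized
bisection on the weighted-CDF equation across all replicates at once.
Default problem sizes: 50,000 replicates for plain cells (20,000 in the
routine test suite) and 2,000–5,000 experiments for min-of-L cells at
L = 10,000, with the Monte-Carlo standard error always reported alongside.

## What the synthetic data does and does not capture

The generator emulates exchangeable two-sample Z-tests with a zero-mean
normal distribution of standardized effects and independent tests within
a min-of-L experiment.  It does not model correlated tests (linkage
disequilibrium between loci), non-normal sampling distributions of the
observed statistic, asymmetric or point-mass-plus-tail effect-size
distributions in the generating mechanism (asymmetric priors are
supported on the analysis side via tabulated priors), or any systematic
error in the underlying studies (confounding, model misspecification of
the P-values themselves).  Passing coverage tests therefore demonstrate
calibration under the stated sampling model, not robustness to violations
of it; the prior-misspecification scenarios (halved and doubled analysis
variance) probe the first-order sensitivity, showing that over-specifying
the prior variance is safer than under-specifying it.

The shipped fixture generator writes a synthetic L-shaped odds-ratio
table (heavy mass at OR ≈ 1.005, thin tail to OR ≈ 1.5) with the
qualitative shape of empirical genome-wide effect-size distributions; it
is labelled synthetic and is not a transcription of any published table.

## Conventions and degenerate inputs

Observed P-values are interpreted under an explicit sidedness convention;
the default is one-sided upper, the natural convention for replication
(which targets the direction of an effect).  Both two-sided roots are
available because published worked examples use both.  Interval endpoints
are always reported ascending on the P scale as one-sided upper-tail
(for chi-square/F, omnibus upper-tail) probabilities of the statistic
endpoints.  On the −log10 scale, converting two-sided to one-sided bounds
subtracts log10(2), applied only on request.  P-values below 10⁻³⁰⁰ are
clamped with a warning rather than mapped to infinite statistics.  A zero
prior variance is not an error: it encodes a point mass (the pure-null
predictive).  Conjugate priors accept either s0² (effect scale) or σ0²
(statistic scale) and reject inconsistent pairs.

## Known limitations

- Tail accuracy is double-precision only; no arbitrary-precision
  arithmetic.
- The mixture grid is fixed, not adaptive; users supplying very diffuse
  priors or analyzing extreme observations should refine
  `step_fraction` / `tail_quantile` as described above.
- The min-of-L simulator draws L pairs literally, so cost grows linearly
  in L; replicate counts are scaled down accordingly at L = 10,000.
- Nonzero prior means are supported in the conjugate algebra but none of
  the calibration experiments exercise them.
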