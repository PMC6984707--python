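# Methods

This note documents the models, estimators and design choices behind
`tailsplit`, and states what the synthetic experiments can and cannot
show.

## Scale combinatorics

The Alda score combines an A subscale (single ordinal rating, 0–10)
with five B criteria scored 0–2 each; the total is
`max(0, A − ΣB)`.  This scoring rule is not unique a priori — clinical
manuals differ in how partial credit is handled — but it is the only
integer-valued rule under which a total ≥ 7 is reachable by exactly 79
of the 11·3⁵ = 2673 raw item tuples and a total ≤ 3 by 2159, the two
counts the scale is known for.  The module asserts this reproduction at
import time and counts over raw tuples (A, B₁..B₅), not distinct
(A, ΣB) pairs.  Half-point B items and missing items are out of scope.

## Empirical rating model

Observed scores per gold-standard score *k* are multinomial with
parameter θ⁽ᵏ⁾ under a symmetric Dirichlet(α) prior.  The smoothed
conditional is the posterior mode

θ̂ᵢ = max(0, α + nᵢ⁽ᵏ⁾ − 1) / Σⱼ max(0, α + nⱼ⁽ᵏ⁾ − 1).

*Clamping.*  The numerator is negative when α < 1 and nᵢ = 0; clamping
at zero is the standard simplex-boundary MAP solution and keeps the
α → 0 limit computable.  A conditional whose numerators all clamp to
zero raises a `DegenerateDistributionError` rather than silently
returning garbage.  For α ≥ 1 clamping never activates, so the choice
cannot move the crossover (which sits well above 1 in all data seen).

*Imputation.*  Gold scores with no vignette (for the standard gold
vector: 0, 2, 4 and 10) borrow counts — boundary scores copy their
inner neighbour, interior gaps take the element-wise mean of their two
neighbours.  Adjacent interior gaps would require chained imputation;
the code refuses them explicitly instead of guessing.

*Dichotomization.*  Responder ⇔ score ≥ τ (τ = 7 by convention), applied
to both axes of the count tables.  The binary conditionals use a
2-cell Dirichlet(ξ) MAP with the pairing ξ = 11α/2, which equalizes the
total prior pseudo-count mass (11α = 2ξ) so both representations face
the same a-priori observation noise.  The joint distributions take a
uniform 1/11 prior over gold scores, hence a (7/11, 4/11) class prior
at τ = 7 (this follows from the score prior, not from the vignette
labels; `joint_binary` accepts other τ for sensitivity analysis).

*MI and crossover.*  Mutual information is reported in nats; the
crossover location is base-invariant.  `crossover_alpha` scans a
400-point geometric grid on [0.5, 100] for the first sign change of
(binary − raw) MI and refines it by bisection to 10⁻³.  Absence of a
crossing on the bracket is a valid result, not an error.

**What the crossover does and does not mean.**  At α = ξ = 1 both
estimates are purely empirical and the 2×2 MI can never exceed the
11×11 MI (coarsening a fixed joint cannot create information; the test
suite asserts this on random count tables).  The reversal at larger α
therefore comes from the *interaction of smoothing with coarseness*:
spreading the same prior mass over 2 cells dilutes the signal less than
over 11 cells.  A consequence worth stating plainly, because the test
suite measures it: a finite crossover exists for almost any rating
matrix under this pairing — symmetric-dispersion fixtures cross at
α ≈ 4.5–6 and even a noiseless identity table crosses at α ≈ 15.
Asymmetric reliability (tight agreement above τ) pulls the crossover
earlier and raises the binary curve, but it is not the sole cause of
the crossover's existence.  Claims that asymmetry *alone* produces the
reversal are not supported by this model and are not asserted anywhere
in the package.

*Input schema.*  Rating CSVs carry a header of vignette ids, one row
per rater, an optional leading `site` column; gold standards are
supplied separately (default: the 12-vignette consensus vector
8, 9, 6, 7, 9, 3, 5, 9, 3, 9, 5, 1).  Blank cells are dropped from the
counts — individual ratings are never imputed — and the dropped-cell
count is logged and recorded in provenance sidecars.

## Synthetic agreement generator

Ground truth x is uniform on [0, 10]; the observation is

y = ω·f(x) + (1 − ω)·U(0, 10),   0 ≤ ω ≤ 1,

so ω is the coupling to ground truth (ω = 0: pure background noise).
The diagonal term is f(x) = x + U(−σ, σ), with the noise term — and
only the noise term — multiplied by the logistic profile
1/(1 + e^(−0.75x + 5)) in the asymmetric condition (β = 1).  Scaling
the whole of (x + noise) instead would pin low-x observations near zero
and destroy the y ≈ x diagonal that defines the agreement model; the
noise-only reading keeps observations tight around the truth at the
low end and noisy at the high end, which is the intended asymmetric
reliability.  β = 1 denotes the asymmetric branch throughout.

Out-of-range values are reflected at the bounds in the asymmetric
branch; the symmetric branch rescales the pooled noisy sample
affinely into [0, 10] (a no-op when the sample is already in range,
e.g. at σ = 0).  Noise is drawn first, range handling applied last.
Each dataset records its full parameter set and seed; a fixed seed
gives a bit-identical dataset.

The discrete rating fixture draws each rating from a normal centred on
the vignette's gold score — sd 0.8 for gold ≥ 7, sd 2.0 below, rounded
and clipped to [0, 10].  The two defaults were chosen once to mimic the
visual spread of published per-vignette rating histograms (tight,
near-degenerate histograms for responder vignettes; 4–5-point spreads
below); tests rely only on the ordering sd_high < sd_low, never the
exact values.  The fixture reproduces the qualitative asymmetry of the
real inter-rater data but not its site structure, rater-specific
biases, or any non-normal shape of real disagreement — results on the
fixture demonstrate that the pipeline detects asymmetric reliability,
not that the real data have any particular crossover value.

## Mutual-information estimators

*Continuous.*  A bivariate Gaussian KDE (Scott bandwidth) is fitted to
(x, y) and univariate KDEs, each with its own Scott bandwidth, to the
marginals.  I = E[log p(x,y) − log p(x) − log p(y)] is estimated by
direct Monte-Carlo averaging over draws from the fitted joint —
a Gaussian mixture admits exact sampling, so no Markov chain is needed
— with the Monte-Carlo standard error reported (default 10,000 draws).
Estimates are not clipped at zero; independent data legitimately
produce small negative values, and clipping would bias the error model.
Calibration, asserted in the test suite: on 750-point bivariate-normal
samples the estimator matches −½ln(1−r²) within 0.08 nats (10-seed
means, r ∈ {0, 0.4, 0.8}), and the 27×27 regular grid yields |MI| <
0.02 nats.

*Dichotomized.*  The 2×2 histogram at threshold τ (upper class = value
≥ τ on both axes, matching the rating model's convention) gives an
exact discrete MI for the sample.  If a class is empty on either axis
the MI is defined as 0 with a warning.

*Sweep.*  `threshold_sweep` replicates both estimators over
independent datasets (defaults: n = 750, τ ∈ {1..9}, 10 runs) and
reports means with 1.96·SE confidence half-widths; all seeds derive
from one master seed, so means are bit-reproducible.

**Limitation worth knowing.**  Because dichotomization is a
deterministic coarsening, the *true* 2×2 MI is always below the true
continuous MI (data-processing inequality); large-sample histogram
estimates at the asymmetric σ = 20 setting put them at ≈ 0.03 vs
≈ 0.14 nats.  A continuous estimator can only appear to lose to the
dichotomized one if it is strongly biased downward.  This package's
calibrated KDE estimator is not, so sweeps here show the dichotomized
MI below the continuous reference across the whole grid — reports of
the opposite ordering in the literature reflect the bias of particular
continuous-MI estimators at high noise, not a property of the
distributions.  The informative quantity that *does* survive here is
the location of the best threshold: as asymmetric noise grows, the
optimal τ moves toward the reliable low tail (argmax-τ at σ = 20 ≤
argmax-τ at σ = 5).

## Power analysis

*Pearson.*  Power of the two-sided correlation test from the Fisher-Z
normal approximation, Φ(√(n−3)·|ζ(ρ̂)| − z_{1−α/2}), with ρ̂ the sample
correlation of each simulated dataset (plug-in).  The √(n−3) factor is
the standard variance-stabilized scaling; a formulation without it
(power independent of n) is available via `scaled=False` for
auditability, but is not the default because it cannot produce
high-power curves at any realistic effect size.

*Fisher's exact test.*  Conditional on both margins, the
(x<τ, y<τ) cell count follows Fisher's noncentral hypergeometric
distribution (scipy's `nchypergeom_fisher`); η = 1 gives the null, and
the alternative uses the sample odds ratio with the Haldane–Anscombe
0.5 correction on zero cells.  The discrete inverse survival function
is taken conservatively — the smallest support value t with S(t) ≤ q —
so the upper-tail branch (η̂ ≥ 1) rejects X > t at q = α/2 and the
lower-tail branch rejects below the 1−α/2 point with a one-step
offset; both keep the size at or below α (balanced tables yield power
≤ α/2 per branch, verified in tests), and power is the alternative's
mass in the rejection region.  The survival values agree with direct
weighted summation of C(m₁,t)·C(N−m₁,n₁−t)·ηᵗ to 10⁻¹⁰ across every
margin configuration with N ≤ 60.

*Sweep.*  Defaults mirror the experimental grid: σ ∈ {1..20},
ω ∈ {0.3, 0.5, 0.7}, τ ∈ {3, 5}, n = 750, 100 runs per cell with
1.96·SE ribbons (the bundled acceptance checks use 25 runs to keep a
single-CPU run in minutes; the CLI exposes `--runs` for the full 100).

**Limitation worth knowing.**  At n = 750 the scaled Pearson power
saturates at 1.0 (to ~12 decimal places) whenever the global sample
correlation exceeds ≈ 0.3, which it does for every asymmetric setting
in which the tail split has power — the reliable low tail alone
contributes that much correlation.  Strict orderings of the form
"tail-split power > Pearson power" are therefore comparisons of
floating-point ties in this regime and are not achievable with a
size-valid Fisher test and the n-scaled Pearson formula; what the
sweep does robustly show is the symmetric-condition ordering (Pearson
≥ both Fisher variants at every σ) and, within the dichotomized
family, the tail split matching or beating the median split under
asymmetry.

## Problem sizes and numerics

Bundled checks use: 59 raters × 12 vignettes for the empirical stage;
n = 750 per synthetic dataset; 10 replicates for MI sweeps and 25 for
power sweeps; 10,000 Monte-Carlo draws per KDE-MI estimate.  These
sizes give confidence half-widths comfortably inside every asserted
ordering while keeping a full run on one CPU in minutes.  Probability
tables are validated to sum to 1 within 10⁻¹²; 0·log 0 terms are
defined as 0; MI grids must be strictly ascending; all stochastic
components accept explicit integer seeds and spawn child seeds via
`numpy.random.SeedSequence`.
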