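# Methods

This note documents the models, the synthetic-data conditions, and the
numerical choices made where the design was genuinely open.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task environment

The three-armed probabilistic reversal learning schedule is deterministic
given its configuration: contingencies (0.9, 0.5, 0.1) on trials 1–80 and
(0.8, 0.4, 0.2) from trial 81, with the assignment of contingencies to
arms permuted at unsignalled reversal trials.  Reversal positions vary
across deployments of this task, so they are configuration
(`reversal_trials`, default 41 and 121, rotating the assignment; explicit
permutations may be supplied).  Win-switch and lose-stay rates exclude the
final trial from their denominators — no successor choice exists — and
are undefined (NaN) when the denominator is empty.

## Hierarchical Gaussian filter

Three levels for a 3-armed bandit with binary outcomes.  Per arm *a*,
level 2 holds (μ₂ᵃ, σ₂ᵃ); a shared level 3 holds (μ₃, σ₃).

Prediction, each trial:

- μ̂₂ᵃ = μ₂ᵃ + φ(m − μ₂ᵃ)  (AR(1) attraction; the autoregressive variant)
- σ̂₂ᵃ = σ₂ᵃ + exp(κμ₃ + ω₂)
- μ̂₃ = μ₃,  σ̂₃ = σ₃ + exp(ω₃)
- μ̂₁ᵃ = logistic(μ̂₂ᵃ)

Update, chosen arm *c* only (unchosen arms keep their predicted state):

- δ₁ = y − μ̂₁ᶜ;  σ̂₁ᶜ = μ̂₁ᶜ(1 − μ̂₁ᶜ)
- π₂ = 1/σ̂₂ᶜ + σ̂₁ᶜ;  σ₂ᶜ ← 1/π₂;  μ₂ᶜ ← μ̂₂ᶜ + σ₂ᶜ δ₁
- w₂ = exp(κμ₃ + ω₂)/σ̂₂ᶜ;  δ₂ = (σ₂ᶜ + (μ₂ᶜ − μ̂₂ᶜ)²)/σ̂₂ᶜ − 1
- π₃ = 1/σ̂₃ + (κ²/2) w₂ (w₂ + (2w₂ − 1) δ₂)
- μ₃ ← μ̂₃ + (κ/2) w₂ δ₂ / π₃;  σ₃ ← 1/π₃

A non-positive π₃ (or numerical overflow in the diffusion term) raises a
divergence signal; during fitting such parameter vectors are rejected with
an effectively infinite objective rather than clamped.  The response model
is a softmax over the three μ̂₁ with inverse temperature β(t) = exp(−μ̂₃(t)):
stronger volatility expectations produce noisier choice.  The filter's
inner loop is numba-compiled; a pure-scalar re-derivation in the test
suite pins its output to ~1e−12 relative accuracy.

Defaults: μ₂⁰ = 0 per arm, σ₂⁰ = σ₃⁰ = 1, κ = 1, ω₂ = −0.5, ω₃ = −6,
φ = 0.1, m = 0, μ₃⁰ = −3.  Because the softmax temperature is coupled to
μ₃, plausibly sharp human choice requires μ₃ well below zero; the package's
operating range μ₃⁰ ∈ [−4.5, −1.5] spans win-switch rates ≈ 0.005–0.35 and
lose-stay rates ≈ 0.75–0.26, monotone in μ₃⁰ in the directions reported
for this task (this was verified by simulation before the population
defaults were frozen).  Far above this range (κμ₃ + ω₂ ≳ 1.2) the filter's
volatility dynamics genuinely diverge; see the generator policy below.

Fitting: MAP with free parameters {μ₃⁰, ω₂} by default (all other
parameters fixed at the defaults; downstream analyses interpret only μ₃⁰).
Gaussian priors μ₃⁰ ~ N(−3, 2²), ω₂ ~ N(−0.5, 1²) in natural space (both
unconstrained); multi-start L-BFGS-B with 8 starts by default (prior mean
plus prior-scaled perturbations).  A fit in which every start fails
returns a failure record, never an exception.  Halves: trials 1–⌊n/2⌋ and
⌊n/2⌋+1–n; the first-half μ₃⁰ is the headline estimate consumed by the
cohort analyses (either half, or the full session, can be selected
instead).

Parameter recovery follows the simulate-and-refit protocol with 10
iterations per parameter set by default; the recovery table reports
true values, estimate means/SDs, and across-set Pearson correlations.

## Ego-network features

Graph conventions, chosen per each measure's verbal definition and
switchable in code:

- **density** — alters-only graph: present alter-alter ties (weak or
  strong; "stranger" is absence) over A(A−1)/2.  Undefined for A < 2.
- **centralization** — Freeman degree centralization Σ(d_max − dᵢ) /
  ((n−1)(n−2)) on the ego-inclusive graph (1 for a star on the ego,
  0 for regular graphs).  Undefined below 3 nodes.
- **constraint** — Burt's constraint of the ego on the ego-inclusive
  binary graph (networkx); dyad → 1, star over k alters → 1/k.
- **kinship** — share of alters with kinship ∈ {parent, sibling, spouse}.
- **assumed shared belief** — B̈ = Σⱼ wⱼ(aⱼ/e) with w_strong = 0.75,
  w_weak = 0.25 (tie weights are a modelling choice, configurable
  within (0, 1)).  The similarity ratio a/e is used exactly as
  defined — asymmetric and unbounded above — and B̈ is a weighted *sum*, so
  it scales with network size; 0 for an empty network.

Parsing mirrors the survey's constraints: egos listing a duplicate alter
name are excluded (their structure cannot be reconstructed), and
alter-alter edges beyond the first 15 listed alters are dropped with a
warning.  (An alternative reading of the survey caps edges at the first
ten alters; the 15-person cap is used here.)

## Synthetic cohort

The generator emulates a cross-sectional online cohort; its defaults *are*
the study conditions.

- **Latent traits.**  (paranoia, volatility prior, conspiracy mindset)
  from a Gaussian copula.  Configured correlations are target *Spearman*
  coefficients (converted via r = 2 sin(πρ/6)), matching the rank-based
  statistics used throughout; defaults ρ = 0.24 (paranoia–μ₃⁰), 0.41
  (paranoia–general conspiracy), 0.17 (μ₃⁰–conspiracy).
- **Instruments.**  Monotone quantile maps onto the printed scales:
  R-GPTS part B (10 items, 0–4) maps the paranoia latent so that exactly
  the configured top fraction (default 62/372) scores ≥ 11, the clinical
  cutoff; part A shares the same latent monotonically, so configured rank
  correlations carry through to the A+B total.  General conspiracy: five
  1–5 items; COVID-vaccine: five 1–7 items; QAnon: single 0–100 — the two
  latter couple to the conspiracy latent with noise.  Item-level totals
  are spread across items by bounded rationing.
- **Networks.**  Size 1 + Poisson(mean − 1) (mean 5); ego-alter ties
  strong with p = 0.70; alter-alter pairs present with density 0.35 (no
  descriptives exist for this; free choice), weak/strong equally.
  Attributed alter responses = ego's responses + a per-ego projection
  shift ~ N(0, `asb_heterogeneity_sd`²) + per-alter discretised jitter
  with SD 1/`asb_concordance`, clipped to 1–5.  The per-ego shift encodes
  that egos differ in how strongly they project their own beliefs onto
  others; without it the ASB sum is ≈ 0.9-correlated with network size and
  the SIZE×BELIEF interaction column is statistically indistinguishable
  from SIZE×TIES at realistic cohort sizes.
- **Volatility priors.**  μ₃⁰ ~ N(−3, 0.75²), ω₂ ~ N(−0.5, 0.5²), plus a
  negative three-way modulation (β = −0.3 per SD) by
  paranoia × strong-ties × belief, residualised against the intercept and
  main effects so it carries only unique three-way signal (the raw triple
  product covaries with paranoia and would distort the configured marginal
  correlation).  Agents whose simulated dynamics diverge (precision
  collapse; possible only several SDs above the mean) have their prior
  shrunk 20% toward the population mean and re-simulated; the realised
  value is the recorded ground truth.
- **Psychopathology.**  η = 0.5·z_paranoia − 0.3·SIZE − 0.3·BELIEF −
  0.5·std(SIZE×BELIEF), noise SD 1 per instrument, mapped linearly onto
  BAI/BDI mid-scale (30 + 5x) so the 0–63 bounds are essentially never
  hit.  Effects are specified per SD of each term; with the raw unbounded
  product, extreme egos saturate the instrument floor and the clipping
  removes precisely the protective-tail signal.

What the generator does **not** emulate: item-level response styles and
measurement error structure, homophily or network dynamics, missingness,
frame effects (social and nonsocial sessions share mechanics by design),
or any causal pathway between network structure and behaviour — the
encoded effects are correlational by construction.  Passing tests
therefore show that the pipeline recovers what the generative model puts
in at the configured effect sizes; they cannot show that real cohorts
carry those effects.

## Statistics

Group contrasts use the unpaired two-sample Wilcoxon rank-sum test
(midranks; W as printed by R's `wilcox.test`), correlations are Spearman,
all two-sided at α = 0.05.  The psychopathology composite is the mean of
the three instruments' within-cohort z-scores.  Mean splits label values
strictly above the mean "high" (ties low).  The ASB mean-split contrasts
are additionally summarised with a JZS default-prior Bayes factor (Cauchy
scale √2/2, via pingouin; pinned in tests to a direct quadrature of the
Rouder integral).

Clustering z-standardises the seven features (required across mixed
scales), runs seeded k-means over k = 1…10 with 10 restarts, and selects
the elbow as the point of maximum distance below the chord joining the
WCSS curve's endpoints — an automated reading of "the bend in the plot".
PCA on the standardised features supplies the two-component visualisation
coordinates and loadings.

The two printed reduced models are fitted by OLS exactly as structured:
7 predictors for psychopathology (SIZE, TIES, KIN, BELIEF + SIZE:TIES,
TIES:KIN, SIZE:BELIEF) and 13 for μ₃⁰ (adding PARANOIA, its two-ways, and
the PARANOIA:TIES:BELIEF / PARANOIA:KIN:BELIEF three-ways).  Features are
z-scored before entering.  Backward stepwise elimination uses AIC (BIC is
available as an alternative), dropping the
single term whose removal most lowers the criterion, never violating
marginality, stopping at no improvement.  Greedy elimination stops at
local AIC optima by design; the acceptance suite compares it against an
exhaustive search over backward-reachable subsets on the designs where
the two are equivalent, against an independently coded greedy eliminator
on all designs, and certifies local optimality otherwise.  Rank-deficient
designs are rejected naming the collinear terms.

## Problem sizes

The shipped checks use: 100 parameter sets × 160 trials × 10 refits for
recovery; 50 (tests) or 30 (acceptance script) seeded cohorts of 400 egos
for directional replication, fitting first-half μ₃⁰ with 4 optimizer
starts; cohorts of 10,000 egos (traits and networks only) for convergence
of the configured conditions; 3 × 70 points in 7 features for planted
clusters.  These sizes were chosen so each check's sampling error is small
relative to the margin it asserts.

## Known limitations

- MATLAB/TAPAS implementations of this model family pin many defaults
  (free-parameter sets, priors, the softmax sign convention) that vary
  across studies; this package commits to the conventions documented above
  and exposes them as configuration.  Bit-for-bit compatibility with any
  other toolbox is a non-goal.
- μ₃⁰ and ω₂ are partially confounded in 80-trial fits; recovery of ω₂ is
  weak and only μ₃⁰ is interpreted.
- The B̈ score divides by the ego's mean belief, so egos near the scale
  floor inflate similarity ratios; the score is used as defined rather
  than symmetrised.
- Backward stepwise inherits the usual post-selection inference caveats;
  reported p-values for reduced models are conditional on the selected
  structure.
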