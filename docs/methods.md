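# Methods

## Growth model and normalization

Growth signals (backscatter or total-absorption values, arbitrary units)
are normalized per replicate to the initial value. The default is the log
mode, y = ln(signal/signal₀), so that the fitted maximum slope μₘ is a
specific growth rate in h⁻¹; the linear mode y = signal/signal₀ is retained
because some workflows fit the raw OD ratio directly (in that mode the
package fits the rise y − 1, and μₘ is an absolute, not specific, rate).
Times are hours everywhere; readers convert a declared input unit
(s/min/h) on load. Signals must be strictly positive; values below 10⁻⁶ of
the curve maximum are rejected as sub-detection rather than clipped, since
clipping would silently distort the log transform.

The primary model is the modified Gompertz equation in the
Zwietering parameterization,

    y(t) = A · exp(−exp((μₘ·e/A)·(λ − t) + 1)),

chosen because its parameters are directly the quantities of interest:
asymptote A (dimensionless), maximum specific growth rate μₘ (h⁻¹, the
maximal slope of y), and lag time λ (h, where the maximal-slope tangent
crosses y = 0). The curve is monotone non-decreasing, bounded by A, and
y(λ) = A·e^(−e). Note y(0) > 0 for finite λ, while an experimentally
normalized curve has y(0) = 0 exactly; this model–data mismatch at the
first point is part of the residual, not an error.

A curve whose normalized maximum stays below a growth threshold (default
0.05 log-units, ≈5% signal rise, configurable) is classified no-growth and
excluded from rate statistics; replicate aggregation reports the mean and
sample sd of μₘ over growing replicates and counts the excluded ones.

## Fitting engine

All fits minimize the RMSD sqrt(mean((ŷ−y)²)). Each fit runs a
deterministic multi-start scheme: data-driven initial guesses
(A₀ = max y; μ₀ = largest finite-difference slope; λ₀ = tangent intercept
clamped to ≥0) perturbed by ±50% per parameter (27 starts), each refined
with a bounded trust-region least-squares solver (scipy `least_squares`,
xtol = ftol = gtol = 10⁻¹⁵ by default). Bounds: A ∈ (0, 2·max y],
μₘ ∈ (0, 10·μ₀], λ ∈ [0, max t]. The best final RMSD wins; exact ties are
broken by the lexicographically smallest parameter vector so results are
reproducible bit for bit. A fit is converged when the refined optimum is at
least as good as the best raw start. The secondary models use the same
engine with their own heuristics (Monod: K_S guessed at the half-maximal
rate; inhibition: slope through the baseline and the highest level).

**Bootstrap.** Parameter uncertainty uses n_boot refits (default 1000) on
resampled data, each started from the point estimate:

- residual resampling for single-curve (time-series) fits — residuals
  around the fitted curve are resampled with replacement and added back to
  the fitted values;
- case resampling stratified by concentration level for rate-table fits —
  replicates are resampled with replacement within each level, preserving
  the design.

These are standard choices for the two data shapes; the alternative
(case resampling a single time series) would break the time structure.
Failed refits are dropped and counted; >50% failures aborts. Summaries are
mean, sample sd and percentile intervals (default 2.5/97.5%).

**Monte-Carlo propagation.** Derived quantities (e.g. the inhibitory
concentration 1/K) are summarized by drawing rows of the bootstrap matrix
n_mc times (default 10 000), evaluating the derived function, and dropping
(with a count) non-finite draws. The point estimate of P_inhib is exactly
1/K; the Monte-Carlo mean is slightly larger, as expected for a convex
transform (for K ~ N(0.1, 0.005), E[1/K] ≈ 10.025, not 10).

Every stochastic step takes its generator from the configured master seed
(default 1291007; mandatory in pipeline configs), so a rerun of the same
config reproduces the report byte for byte.

## Secondary models

Monod: μ = μ_max·S/(K_S + S), fitted on (S, μ) pairs in a two-stage
procedure (Gompertz per curve first, then the rate model) rather than
jointly on raw curves — the rates are the quantity the secondary model is
about, and the two-stage route keeps per-curve diagnostics. A flat rate
profile drives K_S to its lower bound (10⁻⁶ g/L) and is flagged rather
than raised.

Linear inhibition: μ = μ_max·(1 − K·P). The fit uses the unclamped line on
levels where growth occurred; the clamp max(0, ·) applies to prediction
only. No-growth wells are excluded by default (configurable): the model is
a linear trend in measured rates extrapolated to zero growth, and hard
zeros from below-threshold wells would bias the slope. Rates are usually
normalized to the mean baseline (0 g/L) rate of the replicates, making
μ_max dimensionless ≈ 1. P_inhib = 1/K; a fitted slope ≤ 10⁻⁸ L/g is
treated as numerically zero ("not reached"). The reported uncertainty of
P_inhib is the Monte-Carlo sd over the bootstrap K distribution; the
percentile CI is also emitted since 1/K is skewed.

Significance screening uses Welch's unequal-variances t-test of each
concentration against the baseline, two-sided, with Welch–Satterthwaite
degrees of freedom, uncorrected by default (a Holm option exists). Both
groups constant and equal gives t = 0, p = 1; constant but different gives
p = 0 with a degenerate flag.

## Speciation and balances

Undissociated fraction: 1/(1 + 10^(pH − pKa)), i.e. activities are
identified with concentrations and temperature dependence of pKa is
ignored — adequate for the desk arithmetic this supports. The registry
ships caproate (pKa 4.88, 116.16 g/mol, C₆H₁₂O₂), butyrate, acetate,
lactate, glucose, ethanol, H₂, CO₂, water and a standard biomass
pseudo-compound; masses are validated against the formulas to 0.1% on
load, and a user registry can be substituted. The caproate pKa of 4.88 is
the value consistent both with CRC-handbook hexanoic-acid values and with
the total→undissociated arithmetic this package reproduces.

VSS is (m₁ − m₂)/V: the dried (105 °C) mass minus the ashed (550 °C) mass
per filtered volume, i.e. the ignition loss. (Some renderings write the
difference the other way; the ignition-loss direction is the physically
meaningful one since m₁ ≥ m₂.) Yields are Y_X/S = ΔX/ΔS with the inoculum's
VSS contribution subtracted from the final VSS; a negative ΔX warns rather
than errors.

Electron balances use the degree-of-reduction convention: 4C + H − 2O − 3N
electrons per mole, zero for CO₂ and H₂O, 4.2 per C-mol for biomass
CH₁.₈O₀.₅N₀.₂ (configurable via the registry). Entries are converted to
mmol e⁻/L (a gCOD column is derived at 8 g COD per e⁻-mol); recovery is
the product+biomass+gas electron sum over the substrate sum, with warnings
outside [0.9, 1.1]. Recovery is invariant to splitting an entry and to the
choice of extent, and equals 1 to 10⁻⁶ for any electron-balanced
stoichiometry — including the chain-elongation reaction
1.5 glucose → 1 caproate + 3 CO₂ + 2 H₂ + H₂O (36 = 32 + 0 + 4 + 0
electrons).

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (design, seed); a master seed spawns one
independent substream per replicate.

- Curves: y = Gompertz + additive Gaussian noise on the log-normalized
  scale (σ = 0.02 log-units by default), i.e. multiplicative noise on the
  raw signal, which matches the roughly scale-proportional error of
  optical instruments. Default design: quadruplicate, 60 points over
  120 h, A = 1.5, μₘ = 0.05 h⁻¹, λ = 8 h.
- Substrate-affinity design `ks_high_tryptone`: glucose
  {0, 0.05, 0.1, 0.25, 0.5, 1, 2, 4, 6} g/L, quadruplicate, Monod truth
  (μ_max = 0.06 h⁻¹, K_S = 0.35 g/L), 5% relative rate noise, no growth
  at 0 g/L.
- Inhibition designs `inhibition_lm` (caproate
  {0, 2, 4, 6, 7, 8, 9, 10, 11, 12} g/L, truth threshold 13.6 g/L) and
  `inhibition_lr` ({0, 1, 2, 3, 4, 5, 6, 8, 10, 12} g/L, threshold
  8.9 g/L), quadruplicate; levels at or beyond 1/K yield no-growth wells,
  and an optional lag inflation λ(P) = λ₀(1 + c·P) emulates lag phases
  lengthening with inhibitor concentration.
- Balance tables from any electron-balanced stoichiometry at a chosen
  extent, with optional relative noise per measured concentration change.
  With 5% noise on every entry the recovery of a two-entry balance is a
  ratio of two noisy factors (sd ≈ √2·5% ≈ 7%), which is what the moment
  tests assert.

The generators deliberately do not emulate: instrument-specific artifacts
(drift, saturation, well-edge effects), correlated noise within a curve,
plate position effects, pH drift during growth, or any coupling between
substrate depletion and the curve shape (curves are pure Gompertz).
Passing recovery tests therefore show that the estimators are correct and
well-calibrated under the assumed noise model, not that real instrument
data meet that model.

## Numerical choices and degenerate inputs

- CSV readers parse floats in round-trip mode so write→read cycles are
  bit-identical (the default pandas parser can be 1 ulp off).
- The double exponential is evaluated with its inner argument clamped at
  700 so extreme parameters underflow cleanly to 0 instead of overflowing.
- Empty curve files yield an empty collection with a warning; duplicated
  (replicate, time) rows, non-monotone times, and non-positive signals are
  hard validation errors naming the offending replicate.
- Sample sd uses ddof = 1 and is 0 for n = 1 replicate summaries.
- Problem sizes in the validation suite (e.g. 200 datasets × 300 bootstrap
  refits for CI coverage, 100 seeds for noisy-recovery checks, 40–60
  points per curve) were chosen as the smallest designs at which the
  targeted statistical properties are stable.

## Known limitations

- Only the Gompertz primary model and the Monod/linear-inhibition
  secondary models are implemented (no Baranyi, logistic, or
  Han–Levenspiel alternatives), and λ(P) is reported but not modelled.
- Analytic (Hessian) standard errors and Bayesian inference are out of
  scope; uncertainty is bootstrap/Monte-Carlo only.
- Speciation is monoprotic and ideal-solution; no ionic-strength or
  temperature corrections.
- The backscatter and total-absorption signal scales are treated as
  internally consistent within an experiment only; no cross-instrument
  calibration is attempted.
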