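# Methods notes

## Scope and data model

The toolkit operates on long-format calibration experiments: a panel of
chemicals, each injected in replicate at a series of known concentrations
(ng/mL throughout; no unit conversion layer), with raw ion abundance and,
optionally, the abundance of a co-spiked isotope-labeled internal standard
(IS).  Wide layouts are rejected deliberately: the replicate structure must
be explicit because both the prediction bands and the hierarchical bootstrap
depend on it.  Readers never drop rows silently — rejected-row counts are
logged, and accepted + rejected always equals the input row count.

## Calibration-curve inverse estimation (A1–A3)

Per chemical, ordinary least squares of log₂ abundance on log₂
concentration.  Base 2 is used on both axes so a twofold dilution series is
evenly spaced in x; downstream accuracy metrics use base 10 independently —
the two bases coexist on purpose (curve geometry vs. human-readable fold
errors in decades).

Inverse confidence limits come from the two-sided prediction band for a
**single future observation** (m = 1):

    half-width(x) = t[n−2, 1−α/2] · s · sqrt(1 + 1/n + (x − x̄)² / Sxx)

with `s` the residual SD on n−2 df.  Whether such limits should derive from
m = 1 bands or mean-response bands is genuinely open; m = 1 is adopted
because an unknown sample is a new single observation, and this choice is an
assumption of the implementation.  The limits are the x values where the
upper/lower band equals the observed log₂ abundance, found by solving the
band equation's quadratic in x exactly; a geometric-bracket bisection
fallback handles numerically unstable discriminants.  When the band never
crosses the observed abundance (slope shallow relative to noise — e.g. any
3-point fit at the 95% level, where t(0.975, 1) = 12.7) the interval is
unbounded and the code raises a specific error naming the failed limit
rather than returning a fabricated bound.  Abundances mapping outside the
calibration range are still estimated but flagged as extrapolated.

Conventions: R² is reported as 0 when the total sum of squares is 0 (a
constant response carries no explainable variance); degenerate leave-one-out
folds are skipped with a logged reason.  Weighted and quadratic calibration
models are out of scope — the log-linear form is the one with clean inverse
semantics.

A1/A2/A3 share this machinery and differ only in the abundance column:
IS-normalized (A1) versus raw (A2 from a targeted workflow, A3 from a
non-targeted workflow; on synthetic data the two are the same computation
with different labels).

## Bounded response-factor estimation (A4–A5)

Empirical RF = abundance / true concentration, one per injection.  The
surrogate RF population is resampled hierarchically — uniform chemical,
then uniform RF within that chemical, with replacement — so every chemical
has equal weight regardless of how many injections it has.  Each of the
10,000 bootstrap replicates draws a set equal in size to the **total number
of chemicals in the experiment** (26 by default), takes its α/2, 0.5 and
1−α/2 empirical quantiles, and the final RF̂ values are the medians of each
quantile across replicates.  The resample size of 26 applies in both modes,
including A4's three-surrogate pools; this is statistically unusual but is
the stated design, and it is configurable.

Quantiles use the linear-interpolation convention (numpy default, R type 7)
throughout the package; this is a documented choice, not a claim about what
any particular study used.  The analyte is always excluded from its own
surrogate pool, so every estimate is leave-one-out.  Expert selection
(A4) takes the k = 3 nearest-eluting chemicals sharing the analyte's primary
ionizing group; when fewer than k share the group, chemicals with the same
chain length fill the remaining slots, then nearest chain length.
Deterministic tie-breaks: equal |ΔRT| → earlier-eluting; equal chain-length
distance → nearest |ΔRT|; final ties → lexicographic id.

Reproducibility: each chemical's bootstrap runs on an RNG substream derived
from (seed, CRC32(chemical_id)), so results are bit-identical for a given
seed regardless of chemical ordering or parallel scheduling, and the seed is
recorded in every output table.

## Performance metrics

AQ, AAQ (= max(AQ, 1/AQ), an algebraic identity of its 10^|log₁₀| form),
CLFR, UCQ, LCQ, and the reliability percentages URP/LRP/ORP with boundary
equality counting as contained (the definitions use ≤/≥).  All five
per-observation metrics are scale-invariant.  The legacy absolute relative
error (ARE, %) is emitted as an extra column for continuity with targeted
practice but drives nothing: it saturates at 100% for severe underestimates
and is unbounded for overestimates, which makes it a poor fold-error
summary.

The theoretical CLFR benchmark is reconstructed as the fold range of a
two-sided t-interval for the mean of n replicates with relative SD `cv`:
`(1 + t·cv/√n) / (1 − t·cv/√n)`, giving 2.19 at cv = 0.30, n = 5, 95% — the
conventional maximum-acceptable-CV scenario for targeted LC-MS methods.
This reconstruction matches the conventional benchmark to its printed
precision but the derivation is the package's own.

Threshold defaults: AQ within [0.700, 1.30] (±30% relative error), CLFR ≤
the theoretical benchmark, UCQ ≤ 10 (a starting reference threshold, not a
validated guideline).

## Approach comparison

Observation-level comparisons fit Y_ij = μ + b_i + ε_ij by REML.  The
implementation profiles the restricted deviance over the variance ratio
λ = σ_b²/σ_w² and locates the stationary point by root-finding on the
analytic profile score (envelope theorem), which is numerically exact to
machine precision; variance components are constrained non-negative and a
boundary estimate is reported as exactly 0 with a flag, at which point the
test collapses (correctly) to the pooled one-sample t-test with N−1 df.
Satterthwaite df are computed from the delta method on Var(μ̂) with the
variance-component covariance taken as twice the inverse numeric Hessian
(central differences with one Richardson extrapolation) of the restricted
deviance; in balanced designs this reproduces the chemical-means t-test
with a−1 df to ~1e−8, which the tests verify against closed form and
against an independent mixed-model implementation.

UCQ/LCQ pairings exclude observations with a sub-unity value in either
approach: a log-fold comparison of a limit that already missed the truth is
not interpretable.  Exclusion counts are logged.

Per-chemical comparisons (required when the per-chemical bootstrap makes
within-chemical differences identical) collapse each chemical to its median
difference and use the two-sided Wilcoxon signed-rank test: zeros dropped
before ranking (the classical treatment), exact null distribution for
n ≤ 25 without ties, otherwise normal approximation with continuity
correction and mid-ranks; the fold is 10^(Hodges–Lehmann pseudo-median).
How any particular study handled zeros/ties is typically unstated; this
convention is the package's documented choice.  No multiple-testing
correction is applied.

## Synthetic data generator

The generator emulates the features that drive estimator behavior:

* **Inter-chemical spread** — per-chemical median RFs drawn log-uniformly
  over a 5000-fold span anchored at 10^4.3, matching the observation that
  panel medians span several decades with low responders around 10^4–10^5
  and high responders around 10^8.
* **Within-chemical spread** — a latent log-normal RF drift with
  σ = ln(4)/6 (central 99.7% range = fourfold) plus multiplicative
  injection noise at 20% CV on raw abundance.  Their combination makes the
  observed within-chemical RF range slightly wider than fourfold (~5–6-fold
  at 99.7%), a deliberate simplification.
* **Internal standard mechanism** — drift and most measurement error are
  *shared* between analyte and IS within an injection, so normalization
  cancels them, leaving a residual 5% CV.  This sharing is exactly what
  makes the IS-normalized approach outperform raw-abundance approaches; it
  is explicit in the config rather than emergent.
* **Design** — 26 chemicals, nine ~twofold levels from 0.98 to 250 ng/mL
  (250/2⁸ … 250), 3 replicate injections, IS spiked at 50 ng/mL; ionizing-
  group mix dominated by carboxylic and sulfonic acids with chain lengths
  drawn from group-typical ranges; retention times uniform on 2–18 min.
  An RF–retention-time association is available but off by default (the
  empirical association has no established mechanism).  Optional switches:
  high-concentration RF roll-off (linear attenuation toward the top level),
  a low-responder filter dropping chemicals whose top-level abundance falls
  under a threshold, and an outlier chemical whose median RF sits a
  configurable factor (default 50×) outside the population span — used to
  reproduce the near-zero per-chemical reliability that analytes with no
  RF-distribution overlap exhibit.

What the generator does **not** emulate: chromatographic peak shapes and
integration errors, matrix effects, detector saturation beyond the simple
roll-off, censoring at the detection limit, multimodal or skewed RF
distributions, and correlated errors across chemicals beyond the shared IS
mechanism.  Passing tests therefore demonstrate correctness of the
estimators and metrics under clean log-normal error structure, not
robustness to real-data pathologies.

## Interval coverage of the global-surrogate estimator

A coverage experiment (`qnta.experiments.loo_coverage_experiment`, also run
by `scripts/acceptance.py`) simulates many exchangeable panels and measures
the empirical coverage of both interval families.  Calibration LOO-CV
prediction intervals achieve their nominal 95% essentially exactly (the
generator's log-normal noise is exactly normal on the log₂ axis, ~94.8%
over 35,100 held-out points).  The bounded-RF bootstrap intervals cover
~87–88% — systematically below nominal.  This is not an implementation
defect but small-sample quantile bias: with a resample size of 26, the
interpolated 2.5th/97.5th percentile sits between the 1st/2nd (25th/26th)
order statistics, which corresponds to roughly the 5th/95th percentile of
the surrogate mixture, trimming ~2–3 points of coverage from each tail.
The effect shrinks as the panel grows and is a property of the estimator at
this panel size; empirical studies of this estimator on panels of ~26
chemicals report overall reliability below 90% for the same reason.  The
pooled ORP over both families is ~91%.

## Problem sizes and tolerances

Default experiment sizes were chosen to make Monte-Carlo error comfortably
smaller than the assertions they support: 50 simulated panels (70,200
held-out observations) for coverage; 200,000 bootstrap replicates for the
enumeration oracle (where the replicate-median distribution has point mass
at the target values, making the sample median exact for practical
purposes); 150–1,000 repeats for random-effects calibration checks.  REML
root-finding uses brentq at xtol 1e−14; band inversion bisection at
xtol 1e−13; CSV output carries 12 significant digits so round-trips
preserve values to that precision.
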