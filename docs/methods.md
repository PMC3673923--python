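# Methods

## The estimation problem

A clade's oldest fossil gives a minimum age for its origin; the interval
between the true origin and that oldest preserved occurrence — the missing
history `t₁` — is the quantity this package estimates.  The model treats
the clade as a homogeneous linear birth–death process observed through an
imperfect fossil record: one lineage at the (unknown) origin, `a` true
lineages in the oldest occupied stratigraphic bin of which `n` are observed
under per-interval preservation probability `R`, and `N` extant lineages at
the present.  The likelihood of `t₁` multiplies the probability of growing
from one to `a` lineages over `t₁`, the binomial probability of observing
`n` of `a`, and the probability of ending at `N` over the observed interval
`t₂`, summed over the nuisance diversity `a` from `n` up to a cap.

Assumptions worth keeping in view:

- Origination, extinction and preservation rates are constant through time.
- Fossil taxa are correctly assigned to the (monophyletic) clade; the
  operational lineage unit is whatever rank the input uses (typically
  genera); no rank checking is done.
- The latent first-bin diversity is assumed not to exceed the extant
  diversity (`a ≤ N`).  Clades that radiated explosively right after their
  origin violate this; the curve builder measures the latent mass above the
  cap at the curve mode and warns when it exceeds 1%.
- The likelihood is the plain product written above, not conditioned on
  clade survival through `t₁`.  A `condition_on_survival` switch on
  `CladeCalibrationInput` exposes the conditioned variant (divide the
  first factor by `1 − α(t₁)`) for sensitivity checks.

## Stratigraphic conventions

Ages are Ma before present; bins run oldest → youngest.  A numeric age is
assigned to the bin whose interval `(younger_bound, older_bound]` contains
it, so an age on a shared boundary belongs to the *younger* bin (the
boundary instant starts the younger interval in forward time); the youngest
bin is closed at 0.  The built-in `ISC_stages` scheme carries the 2004
timescale calibration of stage ages — the calibration under which the
method's reference applications were computed (e.g. Wuchiapingian base
260.4 Ma) — while `ISC_stages_2013` carries a later calibration and
`PBDB_10Ma` a uniform 10-Myr binning.  Stage ages are revised over time and
a custom `name/older_bound/younger_bound` table can override any of this.

## Rate estimation

Per-bin per-capita rates use boundary-crosser counts: with `N_bt` ranges
crossing both boundaries of a bin of length `Δt`, `N_t` crossing the top
and `N_b` the bottom, `p̂ = ln(N_t/N_bt)/Δt` and `q̂ = ln(N_b/N_bt)/Δt`.
Bins with `N_bt = 0` have undefined rates and are excluded; when fewer than
two bins have a defined origination (or extinction) rate the record is
declared insufficient (`RateEstimationFailure`) — this is the dominant
failure mode of sparse, poorly-preserved records.

Record-level rates are the **duration-weighted** mean of the defined
per-bin rates (equivalent to pooling log turnover ratios over the total
time with defined estimates).  The choice matters: the ISC scheme contains
sub-Ma Quaternary bins, and a single extant lineage whose youngest cells
happen to go unpreserved appears to go extinct in such a sliver, generating
a per-Ma rate one to two orders of magnitude above the record-wide signal.
In simulations (30 replicates of the validation generator), the unweighted
mean inflates the extinction rate enough to invert the sign of `p̄ − q̄`
(0.216 vs 0.214 at `R = 0.8` against a generating truth of 0.183 vs 0.203)
and is ~2× the truth at `R = 0.1`, while the duration-weighted mean
recovers (0.199, 0.177).  An unweighted variant remains available
(`weighting="none"`).

The youngest (Recent-containing) bin participates like any other; extant
taxa are not injected as upper-boundary crossers, because the method's
input is fossil ranges only and extant status of individual fossil taxa is
extra information the input format does not carry.

## Numerical core

Birth–death transition probabilities use the classical `α`, `β`
parameterisation, with the equal-rates closed form `α = β = pt/(1+pt)`
taken when `|p−q|·t < 1e−10`, `expm1`-style formulations elsewhere, and an
asymptotic branch for `rt > 30` to avoid overflow.  The general `a → n`
probability is a sum over `j ≤ min(a,n)` computed entirely in log space
(log-binomials via log-gamma, log-sum-exp over `j`), since lineage counts
reach the hundreds inside the likelihood sum.  Open-ended sums over lineage
counts stop once recent terms each contribute less than `1e−12` of the
running total (evaluated block-wise, blocks of 64).

The likelihood curve is evaluated on a regular grid (default step 1 Ma,
finer than any stage) from `t₁ = 0`; with no explicit extent it grows until
the likelihood has stayed below `1e−6` of its running maximum for 10
consecutive points, with a hard ceiling of `10·t_min`.  Curve values can
underflow for extreme inputs, so quantiles, fitting and reporting all use
the normalised values computed from log-likelihoods (shifted by the
maximum, rescaled to unit trapezoidal area).  A curve that is identically
zero raises `CurveFailure` (inconsistent inputs, e.g. `n` incompatible with
`R`).  `t₂` is taken equal to `t_min`: the first occurrence is placed
conservatively at the base of its bin.

## Gamma fit

The area-normalised curve is fitted by Levenberg–Marquardt least squares in
`log(shape), log(scale)`, residuals `curve − gamma_pdf`, starting from the
curve's trapezoidal moments (`shape₀ = m²/v`, `scale₀ = v/m`) with four
deterministic jittered restarts on failure.  The `t₁ = 0` grid point is
excluded from the residuals: the gamma density diverges there for
`shape < 1` (the typical decaying curve) and the curve carries a structural
zero there whenever `n ≥ 2`.  Fit quality is the residual sum of squares
normalised by the curve's sum of squares; fits above `τ_fit = 0.05`
(configurable) raise `FitFailure`, which still carries the best
non-converged parameters, and the CLI writes the raw curve for manual
fitting in that case.  The offset is never optimised — it is the
oldest-fossil minimum age.  The reported 95% density is the equal-tail
central interval of the offset gamma.

Least squares on density values is dominated by the high-density region, so
a numerically good fit (small normalised residual) can still underweight
tail mass: on heavy-tailed curves the gamma's upper 95% bound sits tens of
Ma below the curve's own central-mass bound.  When the tail matters for a
downstream analysis, compare the reported interval against the curve TSV.

Near-critical records (estimated `p̄ ≈ q̄`) produce likelihood curves with
power-law-like tails that no gamma matches closely; the best achievable
normalised residual then sits around 0.06 and such fits are reported as
failures at the default threshold.  This is a genuine model-mismatch
signal, not an optimiser artefact (global search reaches the same
minimum).

## Validation study (clade level)

`run_validation` simulates clades by a continuous-time Gillespie birth–
death process from one founder at 250 Ma, with per-interval rates 1.0
(origination) and 0.9 (extinction) converted to per-Ma by the mean stage
duration over the simulated span, conditioned on survival by rejection with
fresh derived seeds.  True lineage durations are binned on ISC stages and
each (lineage, bin) cell is preserved independently with probability `R`
(0.8, 0.45, 0.1); each replicate record is analysed with the true extant
count, the thinning `R`, and rates estimated from the record itself.  A
replicate succeeds when the normalised likelihood at the true clade age
exceeds the curve's 50% value-quantile; the 75% and 95% quantiles mark the
accurate and highly-accurate tiers (higher quantile = higher horizontal
threshold = harder).  Gamma-fit failures are tallied separately and do not
affect the tier, which is read from the curve.

Two scoring details follow from the binned resolution.  The truth is read
at the grid point nearest `max(origin − t_min, 0)`; when that is the
`t₁ = 0` point and `n ≥ 2` (structural zero), the first positive grid
point is used instead — ages inside the oldest occupied bin are simply not
resolvable from binned data.  Second, the tier thresholds are empirical
quantiles of the multiset of curve values, so they depend on how far the
tail grid extends; with the automatic extension rule above, the thresholds
are conservative (shorter grids than a fixed generous extent, hence higher
thresholds).  Sensitivity runs comparing the automatic rule with a fixed
`10·t_min` grid move the highly-accurate tier by 5–45 percentage points
depending on the arm, so tier rates should be compared across
implementations only qualitatively.

Default scale in the test suite and acceptance script: 200 replicates per
arm as 100 clades × 2 thinnings.  Spreading replicates over more clades
(rather than the 100 × 10 full design scaled to 20 × 10) keeps the
small-clade tail — which drives rate-estimation failures at low
preservation — adequately sampled at this budget; conditioned on survival
the extant count is near-geometric, and only the few-percent smallest
clades produce records too sparse for rate estimation.

## Sensitivity study (occurrence level)

`run_sensitivity` emulates the degradation of occurrence data: each taxon
range receives its endpoint occurrences plus `K ~ round(Exp(mean 14))`
extra occurrences placed by mapping `Beta(2,2)` draws onto the range's bins
(interiors occurrence-rich, tails poor); occurrences are sub-sampled
independently at rates 0.2–0.8, ranges are rebuilt from survivors (taxa
with none drop out), and a prior is re-estimated using the same rate as the
preservation parameter.  The informativeness statistic is the width of the
95% density interval; median width decreases monotonically with increasing
preservation on all bundled synthetic datasets.  The synthetic datasets are
complete-preservation binnings of simulated slow-diversifying clades
(origin 220 Ma, rates 0.05/0.038 per Ma, a few dozen to a few hundred
taxa) — labelled `synthetic_*` throughout.

## What the generators do and do not emulate

The validation generator reproduces the study conditions exactly as stated
(origin age, rates, binning, preservation model, replicate structure) but
several details of the original protocol are not recoverable: the
simulator's time discretisation, its survival conditioning, and the grid
extent behind the quantile tiers.  Success and accurate-tier rates are
robust to these choices; the highly-accurate tier and the exact
rate-failure count are not, and the package's numbers for those should be
read as one defensible protocol among several.  Neither generator emulates
real-record features such as temporally autocorrelated preservation,
taxonomic lumping/splitting, or stage-boundary dating error, so passing
validation here demonstrates internal consistency of the estimator, not
robustness to those effects.

FreqRat is exact when true ranges span a geometric number of whole bins and
degradation is per-cell Bernoulli; when continuous lifetimes are binned
with uniform phases the estimator is biased upward (recovering ~1.0 at a
true `R` of 0.7 in our checks).  Its estimates on real data should be
treated with the caution its authors advised; the package clamps estimates
above 1 and warns.

## Known limitations

- Constant-rate birth–death only; no time-varying rates, no tree-aware
  conditioning, no joint estimation of `R`.
- The gamma family cannot represent multi-modal or heavy-tailed curves;
  such fits fail loudly and the raw curve is exported for manual use.
- Rate estimation needs overlapping ranges in at least two bins; very
  sparse records fail by design rather than returning wild estimates.
- The prior is only as good as the stage-age calibration of the timescale
  used; ship-your-own tables are supported for exactly this reason.
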