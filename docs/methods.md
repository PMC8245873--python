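# Methods

## Model

Each theoretical subject is an open, linear, constant-coefficient
compartmental system for whole-body vitamin A metabolism.  `L(i,j)` (1/day)
is the fraction of compartment *j*'s content transferred to compartment *i*
per day; `L(0,j)` is irreversible loss.  The default topology has eight
compartments:

| # | role | notes |
|---|------|-------|
| 1 | gut (dosing) | oral dose enters here through an absorptive delay |
| 2 | chylomicron plasma | fast transit (~0.5 h) |
| 3 | hepatic processing | slow release to plasma (~0.2/d total outflow); also recycles plasma retinol |
| 4 | fast extravascular pool | exchanges with plasma; feeds the disposal path |
| 5 | plasma retinol | the measured compartment; pool size M(5) μmol |
| 6 | hepatic stores | storage; turnover ~0.03/d (adults) |
| 7 | extrahepatic stores | storage; turnover ~0.06/d (adults) |
| 8 | utilization | receives from 4; sole site of irreversible loss |

Total body stores (TBS) is the steady-state vitamin A mass in compartments
6 + 7.  The absorptive delay is a chain of first-order stages (default 3)
with total mean transit equal to the configured duration; material in
transit is accounted to the gut so that mass balance holds on the visible
state.  The unabsorbed fraction of the dose (1 − absorption) is charged to
cumulative loss at t = 0, which makes the conservation identity
Σq + loss = 1 hold unconditionally.

Plasma→liver recycling (`L(3,5)`) makes hepatic processing an exchange pool
rather than a one-way chain.  This is deliberate: retinol recycles
extensively between plasma and liver, and tracer parked in non-storage
exchange pools is what keeps plasma specific activity above the stores'
for the first two weeks.  Without it the plasma curve reaches a
quasi-steady state within ~3 days in which the RID coefficient *FaS* is
nearly the same for every subject, and early sampling would (wrongly)
look as accurate as late sampling.

**Solver.** Because the model class is linear with constant coefficients,
tracer trajectories are evaluated with the matrix exponential at each
requested time — exact up to floating point, no integration error.  The
state is augmented with a loss accumulator so cumulative loss is computed
by the same exponential, making the mass-balance check (tolerance 1e-6) a
genuine test of the numerics rather than an identity.  The test suite
verifies the solver against an independent eigendecomposition solution on
random open systems (observed agreement ~1e-14, asserted at 1e-8).

**Steady state.** Tracee masses solve `A m + u = 0` with dietary intake
*u* entering via the absorption path.  By linearity, anchoring on the
plasma pool size M(5) instead of intake is a single rescaling; the plasma
mass then equals M(5) exactly.  Balance residuals are checked at 1e-9
(relative).

## RID quantities

At each day: `Fa` = fraction of dose in stores; `FDp` = fraction of dose in
plasma; `SAp = FDp / M(5)`; `SAs = Fa / TBS`; `S = SAp/SAs`;
`FaS = Fa × S`.  All are dimensionless or per-μmol fractions of dose, so
dose size cancels.  Where no tracer has reached the stores (`Fa = 0`,
essentially only t = 0), `S` and `FaS` are flagged undefined and excluded
from cohort summaries rather than imputed.

Two identities hold to machine precision and are enforced in tests:
`FaS = SAp × TBS` (so a subject's own coefficient recovers their own
stores exactly), and `FaS/FDp = TBS/M(5)` (so each subject's *FaS* curve is
parallel to their plasma fraction-of-dose curve).  A corollary drives the
group-level result: with the cohort geometric-mean *FaS* as the
coefficient, GM(predictions) = GM(FaS)·GM(1/SAp) = GM(FaS/SAp) =
GM(assigned TBS) — exactly, at every day.

## Cohort statistics

* Geometric mean/SD: exp of mean/SD of logs (`scipy.stats.gmean`/`gstd`).
* FaS dispersion per day: the default pairs the geometric mean with the
  **arithmetic** SD and CV% = 100·SD/mean; a `geometric` convention
  (geometric SD, log-scale CV% = 100·√(exp σ² − 1)) is available as a
  switch.  The arithmetic default was chosen because, on right-skewed FaS
  distributions, it reproduces the familiar pattern of SD exceeding the GM
  at early days.
* Super-subject predictions: per day, GM(FaS) / SA<sub>p,i</sub>.
* Regression: OLS of predicted (y) on assigned (x) via statsmodels;
  r² is the squared Pearson correlation; p is the two-sided zero-slope
  test; no multiple-testing correction is applied.  Rank analysis is the
  squared Pearson correlation of average ranks (= squared Spearman).
* Percent-within: |pred − assigned|/assigned ≤ 10/25/50%.
* Best-day frequency: among selected days {4, 7, 10, 14, 21, 28}, the day
  with each subject's smallest absolute relative error; ties go to the
  earliest day and are logged.
* Biexponential fit `A1·e^(−k1 t) + A2·e^(−k2 t)`: nonlinear least squares
  (`scipy.optimize.curve_fit`, nonnegative bounds) initialized by classical
  curve peeling (log-linear tail fit, subtraction, log-linear fit of the
  fast residual); `k1 ≥ k2` enforced by swap.  On generated cohorts the GM
  FaS curve is biexponential to r² > 0.999 from day 2 on; day 1 carries a
  third, absorptive phase.

## Synthetic cohorts

The generator emulates cohorts of previously published theoretical
subjects.  No distributional model exists for how such subjects vary, so
the sampling law is this package's own design, fixed before the test
values were frozen:

* Each transfer coefficient is log-uniform around a group baseline with a
  per-coefficient half-range.  Most between-subject variation is placed on
  the **store-return rates** (`L(5,6)`, `L(5,7)`, ×/÷2.2) — which set store
  size relative to the plasma pool and hence TBS/M(5) — and on the
  **hepatic processing/recycling path** (×/÷2.5), which shapes the plasma
  response over the first two weeks.  Fast plumbing steps vary little
  (×/÷1.3–1.6).  This placement matters: putting the spread on store
  *uptake* rates instead makes day-7 plasma anticorrelate with TBS/M(5)
  (r ≈ −0.9) and collapses mid-time FaS dispersion, erasing the
  early-vs-late accuracy contrast the method exhibits.
* M(5) is log-uniform over 3–10 μmol (adults) or 1–3.2 μmol (children);
  absorption is uniform 0.65–0.85; the absorptive delay is 0.2–0.8 d.
* Candidates are rejected until assigned TBS lies in the group range
  (adults 160–2734 μmol, children 29–1107 μmol) **and** the terminal
  fractional catabolic rate lies in a physiologic band (adults
  0.0095–0.016/d, children 0.014–0.024/d).  The band's lower edge
  guarantees complete tracer washout within 1000 days (residual < 1e-4);
  its upper edge keeps turnover realistic and bounds late-time retention
  spread.  Children's faster store turnover, faster disposal and smaller
  plasma pools place their cohort GM FaS ~15% below the adults' at every
  day.
* Everything is reproducible from the design seed; written cohort CSVs are
  byte-identical across reruns, with a JSON sidecar recording the design.

**What the generator does and does not emulate.**  It reproduces the
qualitative structure of published theoretical cohorts — wide TBS spread,
FaS declining biexponentially with early-peaked cohort CV, group means
recovered exactly, individual accuracy improving with sampling day,
children below adults — and those properties hold across independent seeds
(validated on 12).  It does **not** reproduce published magnitudes: the
washout requirement (complete turnover within 1000 d) bounds store-return
rates from below, which caps both the largest achievable TBS/M(5) ratio
and the late-day FaS level.  Generated adult cohorts therefore have GM
TBS ≈ 420–580 μmol (printed cohorts: 641), day-28 GM FaS ≈ 0.31 (printed:
0.621), and TBS coverage of about two-thirds of the nominal log-range at
n = 200 rather than the full span.  Exact replication of printed values
requires the published per-subject parameter export
(`data/supplemental/{adults,children}.csv`), which cannot be bundled; the
replication test states precisely which numbers it would verify.
Passing tests on generated cohorts demonstrate the algebraic identities,
the numerics, and the qualitative sampling-time findings — not the printed
magnitudes.

## Numerical choices and degenerate inputs

* Openness is validated at construction: all state-matrix eigenvalues must
  have real part < −1e-12, otherwise "no path to irreversible loss".
* Negative, non-finite or self-transfer coefficients are construction
  errors; missing role designations fail at the point they are needed
  (e.g. RID quantities require plasma and storage labels) rather than
  defaulting.
* Reduced systems (one compartment, no storage set) are allowed for
  verification against closed-form solutions.
* `predict_tbs` rejects non-positive inputs; trajectory grids must be
  strictly increasing and non-negative.
* Rejection sampling has a 10,000-draw budget per subject and raises on
  exhaustion instead of looping.
* Best-day ties are broken toward the earlier day and logged.

## Problem sizes

Default analyses use 20 subjects per group on integer days 0–30, the
6-day selected set {4, 7, 10, 14, 21, 28} and thresholds {10, 25, 50}%.
The full acceptance recomputation (two cohorts, 100 solver-oracle systems,
washout checks) completes in a few seconds; the test suite in under half a
minute.

## Known limitations

* Linear, time-invariant kinetics only: no tracee perturbation by the
  dose, no nonlinearities at very high stores.
* The generator's distributional law is an invention; its parameters are
  calibrated to qualitative behavior, not fitted to data.
* The washout-vs-slow-turnover tension above means subjects with
  multi-year vitamin A half-lives (high-store adults) are outside the
  generated population.
* One dispersion convention must be chosen for Figure-style CV curves;
  both arithmetic (default) and geometric are implemented, and reported
  CV% values depend on that choice.
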