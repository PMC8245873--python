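# ridsim

Model-based evaluation of the **retinol isotope dilution (RID)** method for
assessing vitamin A status.

RID is the reference indirect assay for vitamin A total body stores (TBS) in
humans: a subject ingests a dose of stable-isotope-labeled retinyl acetate,
and days later the specific activity of plasma retinol (SA<sub>p</sub>,
fraction of dose per μmol) is measured in a single blood sample.  Stores are
then predicted with

```
TBS (μmol) = Fa × S × 1/SAp
```

where *Fa* is the fraction of the dose residing in the two storage
compartments at the sampling time and *S* = SA<sub>p</sub>/SA<sub>s</sub> is
the ratio of plasma to stores specific activity.  *Fa* and *S* cannot be
measured in a field study; they are taken from compartmental modeling, and
their composite *FaS* changes with time after dosing — so *when* to draw the
blood sample matters.

`ridsim` answers that design question in silico.  It:

1. **simulates** whole-body vitamin A tracer kinetics for cohorts of
   *theoretical subjects* — 8-compartment linear systems (gut, chylomicron
   plasma, hepatic processing, plasma retinol, a fast tissue pool, two
   storage pools, a utilization pool) with known ("assigned") stores
   obtained from the steady-state mass solution anchored at the plasma
   retinol pool size M(5);
2. **computes** the RID quantities *Fa*, FD<sub>p</sub>, SA<sub>p</sub>,
   SA<sub>s</sub>, *S*, *FaS* on every day 1–30;
3. **predicts** TBS for the group and for each individual at candidate
   sampling days using the super-subject design (the cohort geometric mean
   of *FaS* combined with each subject's own SA<sub>p</sub>); and
4. **scores** the predictions against the assigned truth: regressions,
   rank correlations, percent-of-subjects-within-10/25/50%, and best-day
   frequencies.

Two exact identities anchor the analysis and are enforced to machine
precision: a subject's own *FaS* and SA<sub>p</sub> always return their own
TBS (`FaS = SAp × TBS`), and the geometric mean of group-coefficient
predictions equals the geometric mean of assigned TBS at every day —
group means are recovered exactly at any sampling time, so the interesting
question is individual accuracy, which improves as the cohort dispersion of
*FaS* falls with time.

## Worked example

```python
import numpy as np
from ridsim import (CohortDesign, generate_cohort, solve_tracer,
                    rid_quantities, summarize_fas, evaluate_sampling_days,
                    geometric_mean)

subjects = generate_cohort(CohortDesign(n_subjects=20, group="adult", seed=42))
grid = np.arange(0.0, 31.0)
trajs = [rid_quantities(solve_tracer(s.system, grid), s) for s in subjects]
report = evaluate_sampling_days(subjects, trajs)
fas = {s.day: s for s in summarize_fas(trajs, range(1, 31))}

print(f"GM assigned TBS: {geometric_mean([s.assigned_tbs for s in subjects]):.1f} umol")
for d in (4, 7, 14, 21, 28):
    print(f"day {d:2d}: GM FaS={fas[d].gm_fas:.3f}  CV={fas[d].cv_pct:4.1f}%  "
          f"within25%={report.pct_within.loc[d, 25]:3.0f}%  "
          f"r2={report.regressions.loc[d, 'r_squared']:.3f}")
```

prints

```
GM assigned TBS: 433.6 umol
day  4: GM FaS=1.114  CV=34.1%  within25%= 35%  r2=0.253
day  7: GM FaS=0.833  CV=23.2%  within25%= 70%  r2=0.581
day 14: GM FaS=0.525  CV=14.1%  within25%= 95%  r2=0.844
day 21: GM FaS=0.409  CV=12.5%  within25%= 95%  r2=0.845
day 28: GM FaS=0.350  CV=12.4%  within25%= 95%  r2=0.837
```

Read: the composite coefficient *FaS* declines biexponentially and its
cohort CV% peaks in the first days after dosing and then falls; predictions
for individuals are poor at day 4 (35% of subjects within 25% of truth,
r² = 0.25) and good from about two weeks on (95% within 25%).  Group
geometric means are exact at every day.  For this cohort, sampling at day
14–28 is the defensible design; very early sampling only ranks subjects
coarsely.

The same analysis runs from the shell and writes a CSV report bundle
(assigned-vs-predicted summary, FaS by day, CV curve, percent-within table,
best-day frequencies, tidy trajectories, run manifest):

```bash
ridsim evaluate --generate --group adult --n 20 --seed 42 --out report/
ridsim generate --group child --n 20 --seed 7 --out cohort.csv
ridsim simulate --subjects cohort.csv --days 1-30 --out timecourses.csv
ridsim replicate --subjects cohort.csv --expected report/ --out check/
```

Cohorts of real (published) theoretical subjects can be analyzed by
supplying their kinetic parameter table as CSV (`read_parameter_table`);
the generator is the built-in stand-in that makes the full analysis
reproducible with no external data.

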