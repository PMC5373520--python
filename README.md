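# ticscircuit

A firing-rate model of the basal ganglia-cerebellar-thalamo-cortical
system that generates motor tics under striatal dopamine bursts, together
with the experimental protocol, statistical analyses, genetic-algorithm
parameter fitting and sensitivity analysis that go with it.

## The scientific problem

Motor tics - sudden involuntary movements, the cardinal symptom of
Tourette syndrome - are classically blamed on excess striatal dopamine,
but recordings show that tic-related pathological activity starts in the
basal ganglia and then sweeps through motor cortex *and* cerebellum almost
simultaneously.  `ticscircuit` is a system-level simulator for studying
that mechanism: three parallel action channels run through the direct
(StrD1 -| GPi/SNr), indirect (StrD2 -| GPe -| GPi/SNr) and hyper-direct
(M1 -> STN -> GPi/SNr, diffuse) pathways, through a two-part motor
thalamus, a three-unit primary motor cortex, and a Marr-Albus cerebellar
microcircuit (mossy fibres, 100 granule cells, Golgi, Purkinje, dentate)
reached from the basal ganglia via the subthalamo-ponto-cerebellar link
(STN -> MF).

Every population is a leaky integrator

    tau * du/dt = -u + I,      I = r + sum_i w_i a_i + n,
    a = [400 * tanh(u/400) - thr]+

integrated by forward Euler at dt = 1 ms.  A dopamine unit, clamped to
[0.01, 0.5], multiplies the striatal input excitatorily on the D1 pathway
(`b1 + d1*a_DA`) and inhibitorily on the D2 pathway
(`(b1 + d1*a_DA) / (b2 + d2*a_DA)`).  A tic is a trial in which the mean
M1 activity peak exceeds 40: it emerges only when a dopamine burst opens
the pallido-thalamic gate *and* a coincident cortical input seeds the
thalamo-cortical loop, which then amplifies exactly one channel to a
strong burst (winner-take-all by diffuse subthalamic feedback).

## Worked example

```python
import numpy as np
from ticscircuit import DEFAULT_PARAMS, SessionConfig, run_session

recs = run_session(DEFAULT_PARAMS, SessionConfig(), seed=7)
for r in recs:
    print(r.trial, r.label, round(r.m1_peak, 1), round(r.traces["DA"].max(), 2))
```

prints one line per 2-s trial of a 90-s session (ten trials, 7-s gaps,
dopamine burst 1 s into each trial):

```
0 NO-TIC 29.8 0.5
1 TIC 46.7 0.5
2 NO-TIC 26.0 0.5
3 NO-TIC 22.3 0.5
4 NO-TIC 18.5 0.5
5 NO-TIC 33.2 0.5
6 TIC 46.7 0.5
7 TIC 44.0 0.5
8 NO-TIC 18.2 0.5
9 NO-TIC 33.7 0.5
```

Each line is: trial index, tic label, the peak of the across-unit mean M1
firing rate (a tic whenever it strictly exceeds 40; in tic trials one M1
unit fires strongly while the other two stay near baseline), and the
dopamine peak - the burst drives the dopamine unit onto its 0.5 ceiling in
every trial, but only trials whose per-channel cortical input coincides
favourably with the burst ignite the selection loop.

The same runs are available from the shell:

```
ticscircuit simulate --seed 7 --subjects 3 --out out/
ticscircuit stats --subjects 20 --seed 42 --out out/stats
ticscircuit latency --subjects 10 --seed 2024 --out out/latency
ticscircuit dose-response --subjects 10 --trials 10 --out out/dose
ticscircuit make-fixtures --out out/fx
ticscircuit fit --target out/fx/reference_traces.csv --out out/fit
ticscircuit sensitivity --archive out/fit/archive.csv --out out/sens
```

Every command writes tidy CSV plus a run manifest (config snapshot, seed,
parameter digest, version) from which the run can be reproduced exactly.

See `docs/methods.md` for the model's assumptions, the calibrated
parameter set, the analyses (peak ANOVA with Tukey post hocs,
derivative cross-correlation latencies, dose-response statistics), the GA
and the sensitivity ranking.

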