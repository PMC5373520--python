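# Methods

`ticscircuit` simulates motor-tic generation in a firing-rate model of the
basal ganglia-cerebellar-thalamo-cortical system and reproduces the
accompanying experimental protocol and analyses.  This note describes the
model, its assumptions, the calibrated parameters, the synthetic-data
conditions, and the numerical and design choices a user should know about.

## The model

### Units

Every neural population is a leaky-integrator unit.  The activation
potential `u` obeys

    tau * du/dt = -u + I,          I = r + sum_i w_i * a_i + n,

integrated with forward Euler at `dt = 0.001 s`, and the emitted activity is

    a = f(u) = max(0, 400 * tanh(u / 400) - thr).

Activities represent population firing rates on a 0-400 Hz-like scale; the
activation has unit slope near the origin, so potentials, resting levels
(`r`), thresholds (`thr`), noise and external drives all live on the same
scale.  Noise `n` is drawn independently per unit per integration step from
a component-specific Gaussian; it stands for input from unmodelled cortical
areas plus intrinsic variability.  The update is synchronous: every unit
advances from the previous step's activities.

### Architecture

132 state units in three parallel "channels" (competing motor patterns):

* **Basal ganglia** - StrD1, StrD2, STN, GPe, GPi/SNr (3 units each).
  Channel-preserving (one-to-one) links implement the direct
  (StrD1 -| GPi/SNr) and indirect (StrD2 -| GPe -| GPi/SNr) pathways;
  STN projects diffusely (all-to-all) to both pallidal segments
  (hyper-direct pathway).
* **Thalamus** - ThBC (3 units; receives basal-ganglia inhibition and
  cerebellar excitation) and ThC (3 units; cerebellar input only).  Both
  excite M1 and feed back to the striatum and STN.
* **Primary motor cortex** - M1 (3 units), bidirectionally coupled with
  thalamus, projecting to striatum, STN, mossy fibres and Purkinje cells.
* **Cerebellum** - a Marr-Albus microcircuit: mossy fibres (MF, a 3-channel
  instantaneous relay of M1 and STN input with its own noise and
  threshold), 100 granule cells (GC), one Golgi cell (GO), 3 Purkinje
  cells (PC), 3 dentate units (DN).  Each granule cell listens to one
  mossy-fibre channel with a random weight and carries a random threshold
  (fixed structural seed `gc_seed`), and the Golgi cell provides diffuse
  feedback inhibition, so mossy-fibre input recruits a sparse (< 10%)
  granule code.  Granule-to-Purkinje weights are hand-set per channel:
  zero for *selectable* channels (a previously learned pattern - incoming
  drive then silences nothing and the dentate is disinhibited), positive
  otherwise.  Purkinje cells are spontaneously active (`r_PC = 35`) and
  gate the dentate; dentate output excites both thalamic populations.
  The subthalamo-ponto-cerebellar route is abstracted as STN -> MF and the
  olivary timing input as M1 -> PC.
* **Dopamine** - one leaky unit whose clamped potential (`[0.01, 0.5]`) is
  the dopamine level.  Striatal units have their whole input multiplied by

      D1:  f1 = b_StrD1 + d_StrD1 * a_DA                  (excitatory)
      D2:  f2 = f1 / (b_StrD2 + d_StrD2 * a_DA)           (inhibitory)

  The D2 factor carries `f1` in its numerator (combined D1/D2 receptor
  action) and decreases with dopamine.

Inhibitory (GABAergic) connections - StrD1->GPi/SNr, StrD2->GPe,
GPe->GPi/SNr, GPe->STN, GPi/SNr->ThBC, GO->GC, PC->DN - enter the input sum
negatively; all others positively.  The full edge list is exported by
`ticscircuit.circuit.connection_table()`.

### External inputs

Two Gaussian-shaped drives per trial, both centred 1 s after trial start:

* a **dopamine burst** (height on a 0-100 scale, SD 0.020 s in the tic
  condition) converted to DA-unit drive by `da_gain = 0.05`, so the
  tic-condition height 50 pushes the unit onto its 0.5 clamp and the burst
  height modulates the dopamine peak gradedly below roughly mid-range;
* a **cortical pulse** (height 17, SD 0.250 s in the tic condition;
  30/0.040 s in the no-tic condition), multiplied per channel by
  independent Uniform(0,1) draws and coupled into M1 by the synaptic gain
  `w_ext_M1 = 0.36`.  The coupling gain is what renders the printed input
  heights (17, 30, and the 0-900 range of the dose-response sweep)
  commensurate with the 0-400 activity scale.

## How a tic happens in the model

At rest the pallidal output is tonically active and holds ThBC below
threshold; M1 is silent.  The dopamine burst multiplies the striatal drive
(`f1` rises from ~1 to ~2.6), StrD1 activity surges, and the pallidal
output units dive toward zero - the thalamic gate opens in every channel
for roughly 150 ms.  If a cortical pulse is present during that window, the
channel with the largest per-channel input seeds its ThBC unit, and the
strong ThBC->M1 / M1->ThBC loop regeneratively amplifies it.  The growing
M1 unit drives its STN channel, whose diffuse pallidal excitation lifts
GPi/SNr back above zero and slams the gate on the two losing channels,
while the winner holds its own gate open through its corticostriatal (D1)
feedback as long as dopamine is elevated.  The result is a transient,
winner-take-all M1 burst; as dopamine decays the gate closes and activity
collapses back to baseline well before the next trial.  Without the burst
the gate never opens; without the cortical pulse nothing seeds the loop:
tics require the conjunction.

## Protocol and synthetic-data conditions

The generator reproduces the study conditions exactly: 90-s sessions
integrated continuously, ten 2-s trial windows (2000 steps) separated by
7-s gaps; a dopamine burst 1 s into every trial; cohorts of simulated
subjects distinguished only by RNG seeds (derived from a master seed via
`numpy` SeedSequence spawning); a trial is a TIC when the peak of the
across-unit mean M1 trace strictly exceeds 40.  Monitored areas are pooled
as in the target recordings: Dorsal putamen = StrD1+StrD2, Th = ThBC+ThC,
CbllCx = GC+PC (unit-count weighted), and GPi = GPi/SNr.  The dose-response
sweep runs standalone trials (0.5-s settling, then the 2-s window) at 17
dopamine-burst heights from 0 to 100 with per-trial cortical heights drawn
from Uniform(0, 900).

What the generator does *not* emulate: real tics' kinematics (no motor
read-out), cerebellar learning, dopaminergic learning, or empirical
recording noise; passing tests show that the circuit mechanism produces the
target phenomenology, not that it quantitatively matches any particular
animal's firing rates.

## Analyses

* **Peak statistics** - one randomly selected trial per subject per state;
  peak of the pooled area trace; two-way ANOVA (area x state) via
  `statsmodels` OLS/anova_lm with Tukey-HSD post hocs on the area-state
  groups; significance at p < 0.001.
* **Onset latencies** - subject-averaged TIC-trial traces are
  first-differenced and cross-correlated against M1's derivative using the
  R-`ccf` normalisation (full-series mean and variance, divided by n).
  The delay is the lag of the extremum of |ccf| within +/-0.5 s, signed so
  positive means the area precedes M1.  The absolute value matters because
  the pallidal output's onset feature is a disinhibitory *dive*: its lead
  over the M1 rise appears as an anti-correlated derivative pair.  Ties
  break toward the smallest |lag|.  One-way ANOVA plus Tukey comparisons
  against M1 test the two-cluster structure.
* **Dose-response** - one-way ANOVA of per-subject tic counts across
  dopamine levels, plus the Spearman correlation between level and mean
  count.

## Fitting and sensitivity

`fit_error` simulates the tic- and no-tic-condition trials under common
random numbers (a fixed per-evaluation seed, so the objective is
deterministic) and scores the mean-square error against reference curves,
normalised into (0,1) by the error of an all-zero prediction.  The genetic
algorithm uses tournament selection (size 3), BLX-0.5 blend crossover,
per-gene Gaussian mutation at 5% of each bound range, elitism of one, and
archives every evaluation.  The full-scale preset is ~2500 evaluations
over 300 generations with the 0.08 stopping error; tests use a reduced
pop-20 x 50-generation budget, which recovers fixture curves generated
from known parameters to error < 0.08 (typically < 0.05) in a few hundred
evaluations.  Sensitivity analysis keeps archive entries in the first
error quartile, min-max normalises each parameter over its bounds, and
ranks parameters by ascending standard deviation - a small spread among
good fits marks a parameter the behaviour depends on.

Because the upstream fitted parameter values are not available, the
shipped defaults are the package's own calibrated set: structural constants
follow classic action-selection and Marr-Albus rate models, and the
remaining weights were tuned - coordinate descent on a phenotype score, in
the same spirit as the original behaviour-targeted GA - until the circuit
reproduces the target phenomena (conjunction requirement, winner-take-all,
tic-insensitive striatal/pallidal-output peaks, basal-ganglia lead of
~0.12-0.15 s over M1, rising dose-response).  Two values deserve comment:

* `tau_M1 = 0.3 s` - a slow cortical population.  It attenuates the brief
  (SD 0.040 s) cortical pulses of the dose-response sweep so that even
  near-900 drives rarely push mean M1 over the tic threshold without
  dopamine, while the broad tic-condition pulse passes almost unattenuated.
* `tau_GPe = 0.08 s` - a slow GPe.  Its STN-driven surge then outlasts the
  subthalamic decay after a tic and cancels the residual diffuse excitation
  of GPi/SNr, keeping the pooled GPi peak tic-insensitive.

## Numerical choices and degenerate inputs

Euler integration only (`dt` must be below every `tau`; construction
rejects violations).  Noise is sampled per step without sqrt(dt) diffusion
scaling - SD values are per-step.  The dopamine unit is hard-clamped to
[0.01, 0.5] after each step.  Non-finite states raise with the step index.
`fit_error` maps any simulation failure to the worst score.  Flat traces
make the onset delay undefined (error).  The cross-correlation tie-break
is the smallest absolute lag.  All randomness flows through
`numpy.random.Generator` seeded from user-supplied integers; cohort
members get SeedSequence-derived seeds that are logged in every output.

## Known limitations

The exact two-way-ANOVA significance pattern of the seven pooled areas is
only partially reproduced by the shipped parameters: Dorsal putamen and
GPi are correctly tic-insensitive and STN, M1 and CbllCx significant at
p < 0.001, but GPe and Th show the right direction without reaching that
bar at 20 subjects.  The tension is structural: the diffuse STN projection
is simultaneously the only tic-locked excitation of GPe and the engine of
winner-take-all suppression and GPi's tic-insensitivity, so pushing the
GPe/Th effects harder breaks one of the other reproduced phenomena.  The
corresponding acceptance test asserts the full pattern and documents the
shortfall when it fails.  Other limitations: no overt movement read-out,
no learning, thalamus and cortex deliberately minimal, and the granule
sparseness property is conditional on the shipped wiring seed.
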