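"""Experimental protocol: sessions, trials, tic classification, cohorts,
and the dopamine dose-response sweep.

A *session* integrates the circuit continuously for 90 s and monitors ten
2-s trial windows separated by 7-s gaps (so that activity in one trial
cannot influence the next).  One second into each trial a dopamine burst
is applied to the dopamine unit, and a Gaussian cortical pulse (scaled per
channel by independent Uniform(0,1) draws) drives M1.  A trial is labelled
TIC when the peak of the across-unit mean M1 activity exceeds the
classification threshold of 40 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .circuit import SLICES, TicCircuit, build_network
from .inputs import PulseSpec

__all__ = [
    "AREAS",
    "PulseSpec",
    "SessionConfig",
    "TrialRecording",
    "CohortDataset",
    "run_trial",
    "run_session",
    "classify_trial",
    "run_cohort",
    "dose_response",
    "subject_seed",
]

#: Monitored areas (pooled as in the target recordings) -> model components.
AREAS = {
    "Dorsal putamen": ("StrD1", "StrD2"),
    "GPe": ("GPe",),
    "GPi": ("GPiSNr",),
    "STN": ("STN",),
    "Th": ("ThBC", "ThC"),
    "M1": ("M1",),
    "CbllCx": ("GC", "PC"),
    "DA": ("DA",),
}

_RECORD = ["StrD1", "StrD2", "STN", "GPe", "GPiSNr", "ThBC", "ThC", "M1",
           "GC", "PC", "DN", "DA"]


@dataclass(frozen=True)
class SessionConfig:
    """Protocol constants of one recording session."""

    dt: float = 0.001
    session_length: float = 90.0
    n_trials: int = 10
    trial_length: float = 2.0
    inter_trial_gap: float = 7.0
    da_burst: PulseSpec = field(
        default_factory=lambda: PulseSpec(height=50.0, sd=0.020, center=1.0)
    )
    cortical_input: PulseSpec = field(
        default_factory=lambda: PulseSpec(
            height=17.0, sd=0.250, center=1.0, per_channel_uniform_scaling=True
        )
    )
    tic_threshold: float = 40.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        span = (
            self.n_trials * self.trial_length
            + (self.n_trials - 1) * self.inter_trial_gap
        )
        if span > self.session_length + 1e-9:
            raise ValueError(
                f"{self.n_trials} trials of {self.trial_length}s separated by "
                f"{self.inter_trial_gap}s do not fit in a {self.session_length}s session"
            )
        if abs(self.trial_length / self.dt - round(self.trial_length / self.dt)) > 1e-9:
            raise ValueError("trial_length must be an integer number of steps")

    @property
    def steps_per_trial(self) -> int:
        return int(round(self.trial_length / self.dt))

    def trial_starts(self) -> np.ndarray:
        """Start times (s) of the trial windows within the session."""
        period = self.trial_length + self.inter_trial_gap
        return np.arange(self.n_trials) * period


@dataclass
class TrialRecording:
    """Pooled area traces of one 2-s trial plus its inputs and tic label."""

    traces: dict                      # area -> (T,) across-unit mean activity
    m1_units: np.ndarray              # (T, 3) per-unit M1 activity
    dt: float
    events: dict
    label: Optional[str] = None       # "TIC" | "NO-TIC" | None
    subject: Optional[int] = None
    trial: Optional[int] = None
    unit_traces: Optional[dict] = None  # component -> (T, n) when recorded

    @property
    def m1_mean(self) -> np.ndarray:
        return self.m1_units.mean(axis=1)

    @property
    def m1_peak(self) -> float:
        return float(self.m1_mean.max())


@dataclass
class CohortDataset:
    """Sessions of several simulated subjects (distinct RNG seeds)."""

    subjects: list  # list of (seed, list[TrialRecording])
    master_seed: int
    config: SessionConfig

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def recordings(self):
        for _seed, recs in self.subjects:
            yield from recs


def _pool(traces: dict, area: str) -> np.ndarray:
    """Across-unit mean trace of a (possibly pooled) area.

    Granule-cell traces are recorded as (mean, active fraction); the pooled
    cerebellar-cortex trace weights the granule mean by its 100 units.
    """
    if area not in AREAS:
        raise KeyError(f"unknown area {area!r}")
    parts, weights = [], []
    for comp in AREAS[area]:
        tr = traces[comp]
        if comp == "GC":
            parts.append(tr[:, 0])
            weights.append(100.0)
        elif comp == "DA":
            parts.append(tr[:, 0])
            weights.append(1.0)
        else:
            parts.append(tr.mean(axis=1))
            weights.append(tr.shape[1])
    w = np.asarray(weights)
    return np.tensordot(w / w.sum(), np.vstack(parts), axes=1)


def _make_recording(traces, lo, hi, dt, events, record_units=False,
                    subject=None, trial=None):
    window = {k: v[lo:hi] for k, v in traces.items()}
    pooled = {area: _pool(window, area) for area in AREAS}
    return TrialRecording(
        traces=pooled,
        m1_units=window["M1"].copy(),
        dt=dt,
        events=events,
        subject=subject,
        trial=trial,
        unit_traces={k: v.copy() for k, v in window.items()} if record_units else None,
    )


def classify_trial(rec: TrialRecording, threshold: float = 40.0) -> str:
    """Label a trial TIC iff the peak of the mean M1 trace strictly exceeds
    the threshold; the label is stored on the recording."""
    rec.label = "TIC" if rec.m1_peak > threshold else "NO-TIC"
    return rec.label


def run_session(params, config: SessionConfig = None, seed=0,
                record_units=False, classify=True, subject=None):
    """Simulate one 90-s session and extract its labelled trial recordings."""
    config = config or SessionConfig()
    circuit = params if isinstance(params, TicCircuit) else build_network(params)
    rng = np.random.default_rng(seed)
    dt = config.dt
    n_steps = int(round(config.session_length / dt))
    steps_per_trial = config.steps_per_trial
    starts = config.trial_starts()

    da_drive = np.zeros(n_steps)
    m1_drive = np.zeros((n_steps, 3))
    da_gain = circuit.params["da_gain"]
    ctx_gain = circuit.params["w_ext_M1"]
    trial_scales = []
    for t0 in starts:
        lo = int(round(t0 / dt))
        hi = lo + steps_per_trial
        burst = config.da_burst
        if burst.height > 0:
            da_drive[lo:hi] += da_gain * burst.profile(steps_per_trial, dt)
        pulse = config.cortical_input
        scales = (
            rng.uniform(0.0, 1.0, 3)
            if pulse.per_channel_uniform_scaling
            else np.ones(3)
        )
        trial_scales.append(scales)
        if pulse.height > 0:
            m1_drive[lo:hi] += ctx_gain * np.outer(
                pulse.profile(steps_per_trial, dt), scales
            )

    record = _RECORD if not record_units else _RECORD + ["MF", "GO"]
    _state, traces = circuit.simulate(
        n_steps, dt, rng, da_drive=da_drive, m1_drive=m1_drive, record=record
    )

    recordings = []
    for i, t0 in enumerate(starts):
        lo = int(round(t0 / dt))
        events = {
            "da_burst": config.da_burst,
            "cortical_input": config.cortical_input,
            "channel_scales": trial_scales[i],
            "t_start": float(t0),
        }
        rec = _make_recording(
            traces, lo, lo + steps_per_trial, dt, events,
            record_units=record_units, subject=subject, trial=i,
        )
        if classify:
            classify_trial(rec, config.tic_threshold)
        recordings.append(rec)
    return recordings


def run_trial(circuit: TicCircuit, rng, da_burst: PulseSpec,
              cortical_input: PulseSpec, dt=0.001, trial_length=2.0,
              settle=1.0, record_units=False, tic_threshold=40.0,
              classify=True):
    """Simulate one standalone trial after a settling period.

    Equivalent to one window of a session: the circuit relaxes from its
    initial state for ``settle`` seconds without inputs, then the 2-s trial
    window is recorded with the dopamine burst and cortical pulse applied.
    """
    steps_settle = int(round(settle / dt))
    steps_trial = int(round(trial_length / dt))
    n_steps = steps_settle + steps_trial
    da_drive = np.zeros(n_steps)
    if da_burst.height > 0:
        da_drive[steps_settle:] = circuit.params["da_gain"] * da_burst.profile(
            steps_trial, dt
        )
    m1_drive = np.zeros((n_steps, 3))
    scales = (
        rng.uniform(0.0, 1.0, 3)
        if cortical_input.per_channel_uniform_scaling
        else np.ones(3)
    )
    if cortical_input.height > 0:
        m1_drive[steps_settle:] = circuit.params["w_ext_M1"] * np.outer(
            cortical_input.profile(steps_trial, dt), scales
        )
    record = _RECORD if not record_units else _RECORD + ["MF", "GO"]
    _state, traces = circuit.simulate(
        n_steps, dt, rng, da_drive=da_drive, m1_drive=m1_drive, record=record
    )
    events = {
        "da_burst": da_burst,
        "cortical_input": cortical_input,
        "channel_scales": scales,
        "t_start": float(settle),
    }
    rec = _make_recording(
        traces, steps_settle, n_steps, dt, events, record_units=record_units
    )
    if classify:
        classify_trial(rec, tic_threshold)
    return rec


def subject_seed(master_seed: int, subject: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(subject),))
    return int(ss.generate_state(1)[0] % (2**31))


def run_cohort(params, config: SessionConfig = None, n_subjects: int = 40,
               master_seed: int = 0, record_units=False) -> CohortDataset:
    """One session per simulated subject, with derived per-subject seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or SessionConfig()
    circuit = params if isinstance(params, TicCircuit) else build_network(params)
    subjects = []
    for s in range(n_subjects):
        seed = subject_seed(master_seed, s)
        recs = run_session(
            circuit, config, seed=seed, record_units=record_units, subject=s
        )
        subjects.append((seed, recs))
    return CohortDataset(subjects=subjects, master_seed=master_seed, config=config)


def dose_response(params, da_heights=None, cortical_height_range=(0.0, 900.0),
                  cortical_sd=0.040, da_sd=0.020, n_subjects=40, n_trials=30,
                  master_seed=0, dt=0.001, settle=1.0, tic_threshold=40.0):
    """Tic counts per subject at increasing dopamine-burst heights.

    For each dopamine level every subject runs ``n_trials`` standalone
    trials; the dopamine burst has the given height (default sweep: 0 to
    100 in 17 steps) and the cortical pulse height is drawn per trial from
    Uniform(cortical_height_range).  Returns an ``(n_subjects, n_levels)``
    integer array of tic counts plus the level vector.
    """
    if da_heights is None:
        da_heights = np.linspace(0.0, 100.0, 17)
    da_heights = np.asarray(da_heights, dtype=float)
    if np.any(da_heights < 0) or np.any(np.diff(da_heights) < 0):
        raise ValueError("da_heights must be non-negative and sorted")
    circuit = params if isinstance(params, TicCircuit) else build_network(params)
    lo, hi = cortical_height_range
    counts = np.zeros((n_subjects, len(da_heights)), dtype=int)
    for s in range(n_subjects):
        rng = np.random.default_rng(subject_seed(master_seed, s))
        for j, level in enumerate(da_heights):
            for _ in range(n_trials):
                h = rng.uniform(lo, hi)
                burst = PulseSpec(height=float(level), sd=da_sd, center=1.0)
                pulse = PulseSpec(
                    height=float(h), sd=cortical_sd, center=1.0,
                    per_channel_uniform_scaling=True,
                )
                rec = run_trial(
                    circuit, rng, burst, pulse, dt=dt, settle=settle,
                    tic_threshold=tic_threshold,
                )
                counts[s, j] += rec.label == "TIC"
    return da_heights, counts
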