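"""Genetic-algorithm fitting of circuit parameters to reference firing-rate
curves, and the first-quartile sensitivity analysis of the evaluation
archive.

The objective simulates one tic-condition and one no-tic-condition trial
and scores the mean-square error between the simulated pooled area traces
and the reference curves, normalised into (0, 1) by the error of an
all-zero prediction.  Candidate evaluations use common random numbers (a
fixed per-run seed) so the objective is deterministic and the search is
well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import build_network
from .inputs import PulseSpec
from .params import DEFAULT_PARAMS, PARAM_BOUNDS, STARRED
from .protocol import run_trial

__all__ = [
    "CONDITIONS",
    "FitTarget",
    "GAConfig",
    "EvaluationArchive",
    "FitResult",
    "make_reference_traces",
    "fit_error",
    "genetic_fit",
    "sensitivity",
]

#: Input magnitudes of the two fitted conditions: (da burst, cortical pulse).
CONDITIONS = {
    "TIC": (PulseSpec(50.0, 0.020, 1.0), PulseSpec(17.0, 0.250, 1.0, True)),
    "NO-TIC": (PulseSpec(1.0, 0.600, 1.0), PulseSpec(30.0, 0.040, 1.0, True)),
}

#: Areas entering the fit objective.
FIT_AREAS = ["Dorsal putamen", "GPi", "GPe", "STN", "Th", "M1", "CbllCx"]


@dataclass
class FitTarget:
    """Reference firing-rate curves per (area, condition)."""

    traces: dict          # (area, condition) -> (T,) activity array
    dt: float = 0.001

    def __post_init__(self):
        if not self.traces:
            raise ValueError("fit target must contain at least one trace")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (area, cond), tr in self.traces.items():
            t = np.arange(len(tr)) * self.dt
            rows.append(
                pd.DataFrame(
                    {"area": area, "state": cond, "time_s": t, "activity": tr}
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: float = 0.001) -> "FitTarget":
        traces = {}
        for (area, state), g in df.groupby(["area", "state"]):
            traces[(area, state)] = (
                g.sort_values("time_s")["activity"].to_numpy(dtype=float)
            )
        return cls(traces=traces, dt=dt)


def make_reference_traces(params, seed=0, areas=None, settle=1.0) -> FitTarget:
    """Simulate the two conditions and emit their pooled area mean traces.

    This is the fixture generator standing in for empirical reference
    curves: closed-loop parameter-recovery experiments fit against curves
    generated from known parameters, with no external data.
    """
    circuit = build_network(params)
    areas = list(areas or FIT_AREAS)
    traces = {}
    for cond, (burst, pulse) in CONDITIONS.items():
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 1)))
        rec = run_trial(circuit, rng, burst, pulse, settle=settle, classify=False)
        for area in areas:
            traces[(area, cond)] = rec.traces[area].copy()
    return FitTarget(traces=traces)


def fit_error(params, target: FitTarget, seed=0, settle=1.0) -> float:
    """Normalised mean-square error of a candidate parameter set in (0, 1).

    The raw MSE between simulated and reference traces is divided by the
    MSE of an all-zero prediction of the same reference (so 1 means "no
    better than predicting silence") and clipped into the open interval.
    Numerical failures score the worst possible error.
    """
    eps = 1e-9
    try:
        circuit = build_network(params)
        conds = sorted({cond for _a, cond in target.traces})
        num = den = 0.0
        for cond in conds:
            burst, pulse = CONDITIONS[cond]
            rng = np.random.default_rng(np.random.SeedSequence((int(seed), 1)))
            rec = run_trial(circuit, rng, burst, pulse, settle=settle,
                            classify=False)
            for (area, c), ref in target.traces.items():
                if c != cond:
                    continue
                sim = rec.traces[area]
                n = min(len(sim), len(ref))
                num += float(np.mean((sim[:n] - ref[:n]) ** 2))
                den += float(np.mean(ref[:n] ** 2))
    except (FloatingPointError, ValueError, KeyError):
        return 1.0 - eps
    if den <= 0:
        raise ValueError("reference traces are identically zero")
    return float(np.clip(num / den, eps, 1.0 - eps))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (full-scale preset: 2500 evaluations
    over 300 generations; tests use reduced budgets)."""

    population_size: int = 20
    n_generations: int = 50
    mutation_sd: float = 0.05     # fraction of each parameter's bound range
    mutation_prob: float = 0.25   # per-gene mutation probability
    crossover_rate: float = 0.7
    blend_alpha: float = 0.5
    tournament_size: int = 3
    elitism_count: int = 1
    stop_error: float = 0.08
    seed: int = 0
    fitted_names: tuple = tuple(STARRED)

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.elitism_count < 1:
            raise ValueError("elitism_count must be >= 1")
        for name in self.fitted_names:
            lo, hi = PARAM_BOUNDS[name]
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"parameter {name} lacks finite bounds")


@dataclass
class EvaluationArchive:
    """Append-only record of every (parameter vector, error) evaluation."""

    names: list
    vectors: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def append(self, vector, error):
        if not 0.0 < error < 1.0:
            raise ValueError("archive errors must lie in (0, 1)")
        self.vectors.append(np.asarray(vector, dtype=float).copy())
        self.errors.append(float(error))

    def __len__(self):
        return len(self.errors)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors, columns=self.names)
        df.insert(0, "error", self.errors)
        return df


@dataclass
class FitResult:
    best_params: dict
    best_error: float
    archive: EvaluationArchive
    best_error_curve: np.ndarray   # per-generation best error (non-increasing)


def _clip_to_bounds(vec, bounds):
    return np.clip(vec, bounds[:, 0], bounds[:, 1])


def genetic_fit(target: FitTarget, ga: GAConfig = None,
                base_params: dict = None) -> FitResult:
    """Tournament selection + blend crossover + bounded Gaussian mutation,
    with elitism and a full evaluation archive.

    Only the parameters named in ``ga.fitted_names`` are searched; the
    remaining entries of ``base_params`` are held fixed.
    """
    ga = ga or GAConfig()
    base = dict(base_params or DEFAULT_PARAMS)
    names = list(ga.fitted_names)
    bounds = np.array([PARAM_BOUNDS[n] for n in names], dtype=float)
    span = bounds[:, 1] - bounds[:, 0]
    rng = np.random.default_rng(ga.seed)
    archive = EvaluationArchive(names=names)

    def evaluate(vec):
        p = dict(base)
        p.update({n: float(v) for n, v in zip(names, vec)})
        err = fit_error(p, target, seed=ga.seed)
        archive.append(vec, err)
        return err

    pop = rng.uniform(bounds[:, 0], bounds[:, 1], size=(ga.population_size, len(names)))
    fitness = np.array([evaluate(v) for v in pop])
    curve = [float(fitness.min())]

    for _gen in range(ga.n_generations):
        if curve[-1] < ga.stop_error:
            break
        order = np.argsort(fitness)
        elite = pop[order[: ga.elitism_count]].copy()
        children = list(elite)
        while len(children) < ga.population_size:
            # tournament selection of two parents
            picks = rng.integers(0, ga.population_size, size=(2, ga.tournament_size))
            pa = pop[picks[0][np.argmin(fitness[picks[0]])]].copy()
            pb = pop[picks[1][np.argmin(fitness[picks[1]])]].copy()
            if rng.random() < ga.crossover_rate:
                # blend (BLX-alpha) crossover
                lo = np.minimum(pa, pb)
                hi = np.maximum(pa, pb)
                d = hi - lo
                child = rng.uniform(lo - ga.blend_alpha * d, hi + ga.blend_alpha * d)
            else:
                child = pa
            mask = rng.random(len(names)) < ga.mutation_prob
            child = child + mask * rng.normal(0.0, ga.mutation_sd * span)
            children.append(_clip_to_bounds(child, bounds))
        pop = np.array(children[: ga.population_size])
        fitness = np.array(
            [fitness[order[i]] if i < ga.elitism_count else evaluate(pop[i])
             for i in range(ga.population_size)]
        )
        curve.append(min(curve[-1], float(fitness.min())))

    best_idx = int(np.argmin(archive.errors))
    best = dict(base)
    best.update({n: float(v) for n, v in zip(names, archive.vectors[best_idx])})
    return FitResult(
        best_params=best,
        best_error=float(archive.errors[best_idx]),
        archive=archive,
        best_error_curve=np.asarray(curve),
    )


def sensitivity(archive: EvaluationArchive, bounds: dict = None) -> pd.DataFrame:
    """Rank parameters by the spread of their values among the best fits.

    Keeps the archive entries whose error lies within the first quartile of
    all archived errors, min-max normalises each parameter over its bounds,
    and returns the per-parameter standard deviation in ascending order: a
    *small* spread means the parameter had to take specific values to fit
    well, i.e. it strongly influences the model's behaviour.
    """
    if len(archive) < 8:
        raise ValueError("archive too small for a quartile analysis (need >= 8)")
    errors = np.asarray(archive.errors)
    q1 = np.quantile(errors, 0.25)
    mask = errors <= q1
    if mask.all():
        import warnings

        warnings.warn("all archive errors equal; quartile filter selects everything")
    vecs = np.asarray(archive.vectors)[mask]
    bounds = bounds or PARAM_BOUNDS
    rows = []
    for j, name in enumerate(archive.names):
        lo, hi = bounds[name]
        span = hi - lo
        norm = (vecs[:, j] - lo) / span if span > 0 else np.zeros(len(vecs))
        rows.append({"parameter": name, "std_normalized": float(np.std(norm))})
    return (
        pd.DataFrame(rows)
        .sort_values("std_normalized", kind="stable")
        .reset_index(drop=True)
    )
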