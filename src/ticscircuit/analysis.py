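"""Statistics on simulated recordings: peak-amplitude tables and two-way
ANOVA with Tukey post hoc tests, onset-latency estimation by
cross-correlation of signal derivatives, and the dose-response ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .protocol import AREAS, CohortDataset, TrialRecording

__all__ = [
    "STAT_AREAS",
    "peak_amplitude",
    "onset_delay",
    "build_peak_table",
    "build_latency_table",
    "area_state_anova",
    "latency_anova",
    "dose_response_anova",
]

#: Areas entering the statistical comparisons (DA is an input, not recorded).
STAT_AREAS = ["Dorsal putamen", "GPi", "GPe", "STN", "Th", "M1", "CbllCx"]


def peak_amplitude(rec: TrialRecording, area: str) -> float:
    """Peak over time of the across-unit mean activity trace of an area."""
    if area not in rec.traces:
        raise KeyError(f"unknown area {area!r}")
    return float(np.max(rec.traces[area]))


def onset_delay(ref, other, dt: float, max_lag: float = 0.5) -> float:
    """Onset delay of ``ref`` relative to ``other`` (seconds).

    Both traces are first-differenced, then the sample cross-correlation of
    the derivatives is computed lag by lag; the returned delay is the lag
    of the correlation extremum times ``dt``, signed so that a *positive*
    value means ``other`` precedes ``ref``.  The search is restricted to
    ``|lag| <= max_lag`` seconds (sub-second onset relations; extreme lags
    with little overlap are unreliable).  Ties in the argmax are broken
    toward the smallest absolute lag.

    Raises
    ------
    ValueError
        If either derivative has zero variance (flat trace): the delay is
        undefined.
    """
    x = np.diff(np.asarray(ref, dtype=float))
    y = np.diff(np.asarray(other, dtype=float))
    if len(x) != len(y):
        raise ValueError("traces must have equal length")
    if len(x) < 2:
        raise ValueError("traces must have length >= 3")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("flat trace: onset delay undefined")
    n = len(x)
    # sample cross-correlation normalised by the full-series moments and n
    # (R ccf convention), so sparsely overlapping extreme lags are damped
    xc = np.correlate(x - x.mean(), y - y.mean(), mode="full") / (n * sx * sy)
    lags = np.arange(-(n - 1), n)
    # the onset relation may be carried by an anti-correlated derivative
    # feature (e.g. a disinhibitory dive preceding an activity rise), so the
    # delay is read at the extremum of |ccf|
    score = np.abs(xc)
    if max_lag is not None:
        score = np.where(np.abs(lags) * dt <= max_lag, score, -np.inf)
    best = np.max(score)
    candidates = np.flatnonzero(score >= best - 1e-12)
    best_lag = int(lags[candidates[np.argmin(np.abs(lags[candidates]))]])
    return best_lag * dt


def _select_trials(cohort: CohortDataset, rng) -> list:
    """One randomly selected trial per subject per movement state."""
    rows = []
    for subj, (_seed, recs) in enumerate(cohort.subjects):
        for state in ("TIC", "NO-TIC"):
            pool = [r for r in recs if r.label == state]
            if not pool:
                continue
            rows.append((subj, state, pool[rng.integers(len(pool))]))
    return rows


def build_peak_table(cohort: CohortDataset, seed=0, areas=None) -> pd.DataFrame:
    """Tidy table (subject, area, state, peak_amplitude).

    One trial per subject per state is randomly selected; subjects missing a
    state contribute only the state they have.
    """
    rng = np.random.default_rng(seed)
    areas = list(areas or STAT_AREAS)
    rows = []
    for subj, state, rec in _select_trials(cohort, rng):
        for area in areas:
            rows.append(
                {
                    "subject": subj,
                    "area": area,
                    "state": state,
                    "peak_amplitude": peak_amplitude(rec, area),
                }
            )
    return pd.DataFrame(rows)


def build_latency_table(cohort: CohortDataset, areas=None) -> pd.DataFrame:
    """Per-subject onset delays of each area relative to M1 in TIC trials.

    The delay is computed on the subject's TIC-trial-averaged area traces;
    positive delays mean the area's onset precedes M1.  M1 itself is
    included with delay 0 (the cross-correlation reference).
    """
    areas = list(areas or STAT_AREAS)
    rows = []
    for subj, (_seed, recs) in enumerate(cohort.subjects):
        tic = [r for r in recs if r.label == "TIC"]
        if not tic:
            continue
        dt = tic[0].dt
        mean_traces = {
            area: np.mean([r.traces[area] for r in tic], axis=0) for area in areas
        }
        for area in areas:
            if area == "M1":
                delay = 0.0
            else:
                delay = onset_delay(mean_traces["M1"], mean_traces[area], dt)
            rows.append({"subject": subj, "area": area, "delay_s": delay})
    return pd.DataFrame(rows)


def area_state_anova(tbl: pd.DataFrame, alpha: float = 0.001):
    """Two-way ANOVA (area x movement state) plus per-area Tukey post hocs.

    Returns a dict with the ANOVA table, the interaction F and p, and a
    DataFrame of TIC-vs-NO-TIC Tukey-adjusted comparisons per area.
    """
    counts = tbl.groupby(["area", "state"]).size().unstack(fill_value=0)
    if counts.shape[1] < 2 or (counts < 2).to_numpy().any():
        raise ValueError("need at least 2 observations per area x state cell")
    model = ols("peak_amplitude ~ C(area) * C(state)", data=tbl).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    inter = anova.loc["C(area):C(state)"]

    groups = tbl["area"] + "|" + tbl["state"]
    tuk = pairwise_tukeyhsd(tbl["peak_amplitude"].to_numpy(), groups.to_numpy())
    res = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    pair_rows = []
    for _, row in res.iterrows():
        a1, s1 = str(row["group1"]).split("|")
        a2, s2 = str(row["group2"]).split("|")
        if a1 == a2 and {s1, s2} == {"TIC", "NO-TIC"}:
            pair_rows.append(
                {
                    "area": a1,
                    "p_adj": float(row["p-adj"]),
                    "meandiff": float(row["meandiff"]),
                    "significant": float(row["p-adj"]) < alpha,
                }
            )
    pairwise = pd.DataFrame(pair_rows).set_index("area")
    return {
        "anova": anova,
        "interaction_F": float(inter["F"]),
        "interaction_p": float(inter["PR(>F)"]),
        "pairwise": pairwise,
    }


def latency_anova(tbl: pd.DataFrame, alpha: float = 0.001):
    """One-way ANOVA of onset delays across areas + Tukey pairwise vs M1."""
    if tbl["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    samples = [g["delay_s"].to_numpy() for _, g in tbl.groupby("area")]
    F, p = sps.f_oneway(*samples)
    tuk = pairwise_tukeyhsd(tbl["delay_s"].to_numpy(), tbl["area"].to_numpy())
    res = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    rows = []
    for _, row in res.iterrows():
        pair = {str(row["group1"]), str(row["group2"])}
        if "M1" in pair:
            area = (pair - {"M1"}).pop()
            rows.append(
                {
                    "area": area,
                    "p_adj": float(row["p-adj"]),
                    "significant": float(row["p-adj"]) < alpha,
                }
            )
    vs_m1 = pd.DataFrame(rows).set_index("area")
    means = tbl.groupby("area")["delay_s"].mean()
    return {"F": float(F), "p": float(p), "vs_m1": vs_m1, "means": means}


def dose_response_anova(counts: np.ndarray, levels=None):
    """One-way ANOVA of tic counts with the dopamine level as factor."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be a (subjects x levels) table with >= 2 levels")
    F, p = sps.f_oneway(*(counts[:, j] for j in range(counts.shape[1])))
    out = {"F": float(F), "p": float(p)}
    if levels is not None:
        rho, rho_p = sps.spearmanr(np.asarray(levels), counts.mean(axis=0))
        out["spearman_rho"] = float(rho)
        out["spearman_p"] = float(rho_p)
    return out
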