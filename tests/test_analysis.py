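"""Statistics: onset-delay cross-correlation, peak tables, and the ANOVA
operations against brute-force sum-of-squares oracles."""

import numpy as np
import pandas as pd
import pytest

from ticscircuit.analysis import (
    area_state_anova,
    dose_response_anova,
    latency_anova,
    onset_delay,
    peak_amplitude,
)
from ticscircuit.protocol import AREAS, TrialRecording


def _gauss(center, sd=0.05, n=2000, dt=0.001, h=1.0):
    t = np.arange(n) * dt
    return h * np.exp(-0.5 * ((t - center) / sd) ** 2)


class TestOnsetDelay:
    def test_identical_traces_zero_delay(self):
        x = _gauss(1.0)
        assert onset_delay(x, x, 0.001) == 0.0

    @pytest.mark.parametrize("shift_steps", [126, 40, -80])
    def test_constructed_shift(self, shift_steps):
        ref = _gauss(1.2)
        other = np.roll(ref, -shift_steps)  # positive: other earlier
        assert onset_delay(ref, other, 0.001) == pytest.approx(
            shift_steps * 0.001, abs=0.002
        )

    def test_antisymmetric(self):
        ref, other = _gauss(1.2), _gauss(1.074)
        d1 = onset_delay(ref, other, 0.001)
        d2 = onset_delay(other, ref, 0.001)
        assert d1 == pytest.approx(-d2, abs=0.002)
        assert d1 == pytest.approx(0.126, abs=0.002)

    def test_offset_invariance(self):
        ref, other = _gauss(1.0), _gauss(0.9)
        base = onset_delay(ref, other, 0.001)
        shifted = onset_delay(ref + 57.0, other - 13.0, 0.001)
        assert base == shifted

    def test_anticorrelated_feature_detected(self):
        # a dive preceding a rise carries the same onset information
        ref = _gauss(1.2)
        other = -_gauss(1.074)
        assert onset_delay(ref, other, 0.001) == pytest.approx(0.126, abs=0.002)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            onset_delay(np.ones(100), _gauss(0.05, n=100), 0.001)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            onset_delay(np.zeros(10), np.zeros(11), 0.001)


class TestPeakAmplitude:
    def _rec(self, traces):
        full = {a: np.zeros(10) for a in AREAS}
        full.update(traces)
        return TrialRecording(
            traces=full, m1_units=np.zeros((10, 3)), dt=0.001, events={}
        )

    def test_constant_trace(self):
        rec = self._rec({"M1": np.full(10, 7.0)})
        assert peak_amplitude(rec, "M1") == 7.0

    def test_gaussian_bump_height(self):
        rec = self._rec({"GPe": _gauss(0.005, sd=0.002, n=10, h=55.0)})
        assert peak_amplitude(rec, "GPe") == pytest.approx(55.0, rel=1e-6)

    def test_unknown_area(self):
        with pytest.raises(KeyError):
            peak_amplitude(self._rec({}), "Hippocampus")


def _two_way_f_oracle(tbl):
    """Brute-force two-way ANOVA sums of squares (balanced design)."""
    grand = tbl["peak_amplitude"].mean()
    n = len(tbl)
    areas = tbl["area"].unique()
    states = tbl["state"].unique()
    n_cell = n / (len(areas) * len(states))
    ss_a = sum(
        len(g) * (g["peak_amplitude"].mean() - grand) ** 2
        for _k, g in tbl.groupby("area")
    )
    ss_b = sum(
        len(g) * (g["peak_amplitude"].mean() - grand) ** 2
        for _k, g in tbl.groupby("state")
    )
    ss_cells = sum(
        len(g) * (g["peak_amplitude"].mean() - grand) ** 2
        for _k, g in tbl.groupby(["area", "state"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((g["peak_amplitude"] - g["peak_amplitude"].mean()) ** 2).sum()
        for _k, g in tbl.groupby(["area", "state"])
    )
    df_ab = (len(areas) - 1) * (len(states) - 1)
    df_err = n - len(areas) * len(states)
    return (ss_ab / df_ab) / (ss_err / df_err)


class TestAreaStateAnova:
    def _table(self, means, n_per_cell=5, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for subj in range(n_per_cell):
            for (area, state), mu in means.items():
                rows.append(
                    {
                        "subject": subj,
                        "area": area,
                        "state": state,
                        "peak_amplitude": mu + rng.normal(0, sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_null_case_not_significant(self):
        means = {(a, s): 10.0 for a in "AB" for s in ("TIC", "NO-TIC")}
        tbl = self._table(means, n_per_cell=10, seed=1)
        res = area_state_anova(tbl)
        assert res["interaction_p"] > 0.01
        assert not res["pairwise"]["significant"].any()

    def test_interaction_f_matches_brute_force(self):
        means = {
            ("A", "TIC"): 12.0, ("A", "NO-TIC"): 10.0,
            ("B", "TIC"): 30.0, ("B", "NO-TIC"): 11.0,
        }
        tbl = self._table(means, n_per_cell=3, sd=0.8, seed=2)
        res = area_state_anova(tbl)
        f_oracle = _two_way_f_oracle(tbl)
        inter = res["anova"].loc["C(area):C(state)"]
        assert inter["F"] == pytest.approx(f_oracle, rel=1e-9)

    def test_selective_effect_detected(self):
        means = {
            ("A", "TIC"): 10.0, ("A", "NO-TIC"): 10.0,
            ("B", "TIC"): 25.0, ("B", "NO-TIC"): 10.0,
        }
        tbl = self._table(means, n_per_cell=20, sd=1.0, seed=3)
        res = area_state_anova(tbl)
        pw = res["pairwise"]
        assert bool(pw.loc["B", "significant"])
        assert not bool(pw.loc["A", "significant"])

    def test_sparse_cells_rejected(self):
        tbl = pd.DataFrame(
            {
                "subject": [0],
                "area": ["A"],
                "state": ["TIC"],
                "peak_amplitude": [1.0],
            }
        )
        with pytest.raises(ValueError):
            area_state_anova(tbl)


class TestLatencyAnova:
    def _table(self, delays_by_area, n=40, sd=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for subj in range(n):
            for area, mu in delays_by_area.items():
                rows.append(
                    {"subject": subj, "area": area,
                     "delay_s": mu + rng.normal(0, sd)}
                )
        return pd.DataFrame(rows)

    def test_equal_delays_not_significant(self):
        tbl = self._table({"A": 0.1, "B": 0.1, "M1": 0.1}, sd=0.01, seed=4)
        res = latency_anova(tbl)
        assert res["p"] > 0.01

    def test_two_cluster_separation(self):
        tbl = self._table(
            {"Putamen": 0.12, "GPe": 0.12, "STN": 0.0, "M1": 0.0},
            n=40, sd=0.01, seed=5,
        )
        res = latency_anova(tbl)
        assert res["p"] < 0.001
        assert bool(res["vs_m1"].loc["Putamen", "significant"])
        assert not bool(res["vs_m1"].loc["STN", "significant"])

    def test_single_subject_rejected(self):
        tbl = self._table({"A": 0.1, "M1": 0.0}, n=1)
        with pytest.raises(ValueError):
            latency_anova(tbl)


class TestDoseResponseAnova:
    def test_identical_counts_not_significant(self):
        counts = np.full((10, 5), 3.0) + np.random.default_rng(0).normal(
            0, 0.01, (10, 5)
        )
        res = dose_response_anova(counts)
        assert res["p"] > 0.05

    def test_linear_trend_detected(self):
        rng = np.random.default_rng(1)
        levels = np.linspace(0, 100, 17)
        counts = levels / 10 + rng.normal(0, 0.5, (10, 17))
        res = dose_response_anova(counts, levels=levels)
        assert res["p"] < 0.001
        assert res["spearman_rho"] > 0.9

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            dose_response_anova(np.zeros((5, 1)))
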