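"""Circuit assembly: unit counts, connectivity signs, dopamine modulation,
the dopamine-unit trajectory, cortical pulses and the granule-Purkinje
selection scheme."""

import numpy as np
import pytest

from ticscircuit import DEFAULT_PARAMS, PulseSpec, build_network
from ticscircuit.circuit import (
    COMPONENTS,
    CONNECTIONS,
    N_UNITS,
    SLICES,
    connection_table,
    d1_factor,
    d2_factor,
    da_trajectory,
    set_gc_pc_weights,
)
from ticscircuit.inputs import cortical_pulse
from ticscircuit.params import DA_MAX, DA_MIN


class TestBuild:
    def test_unit_counts(self, circuit):
        assert circuit.n == N_UNITS == 132
        counts = dict(COMPONENTS)
        for name in ("StrD1", "StrD2", "STN", "GPe", "GPiSNr",
                     "ThBC", "ThC", "M1", "PC", "DN"):
            assert counts[name] == 3
        assert counts["GC"] == 100
        assert counts["GO"] == 1
        assert counts["DA"] == 1

    def test_missing_parameter_rejected(self, params):
        incomplete = dict(params)
        del incomplete["w_STN_MF"]
        with pytest.raises(KeyError, match="w_STN_MF"):
            build_network(incomplete)

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(KeyError, match="w_made_up"):
            build_network({**params, "w_made_up": 1.0})

    def test_pallidal_output_inhibits_thalamus(self, circuit):
        block = circuit.W[SLICES["ThBC"], SLICES["GPiSNr"]]
        assert np.all(np.diag(block) < 0)

    def test_sign_discipline(self, circuit, params):
        """GABAergic arrows contribute negatively, glutamatergic positively."""
        for pre, post, topology, sign, wname in CONNECTIONS:
            if pre == "MF":
                block = circuit.W_from_mf[SLICES[post]]
            elif post == "MF":
                continue
            else:
                block = circuit.W[SLICES[post], SLICES[pre]]
            if params[wname] == 0:
                continue
            nz = block[block != 0]
            if sign < 0:
                assert np.all(nz < 0), f"{pre}->{post} should be inhibitory"
            else:
                assert np.all(nz > 0), f"{pre}->{post} should be excitatory"

    def test_stn_diffuse_striatum_selective(self, circuit):
        """STN reaches every pallidal unit (all-to-all); StrD1 reaches only
        its own channel (one-to-one)."""
        stn_to_gpi = circuit.W[SLICES["GPiSNr"], SLICES["STN"]]
        assert np.all(stn_to_gpi > 0)  # full 3x3 block
        str_to_gpi = circuit.W[SLICES["GPiSNr"], SLICES["StrD1"]]
        assert np.all(np.diag(str_to_gpi) < 0)
        off = str_to_gpi[~np.eye(3, dtype=bool)]
        assert np.all(off == 0)

    def test_absent_arrows_are_absent(self, circuit):
        # no M1 -> GPe or GPe -> M1 coupling exists in the architecture
        assert np.all(circuit.W[SLICES["GPe"], SLICES["M1"]] == 0)
        assert np.all(circuit.W[SLICES["M1"], SLICES["GPe"]] == 0)

    def test_connection_table_matches_spec_arrows(self):
        rows = connection_table()
        assert len(rows) == len(CONNECTIONS)
        assert {"pre", "post", "topology", "sign", "weight_param"} <= set(rows[0])


class TestDopamineFactors:
    def test_d1_examples(self):
        p = {"b_StrD1": 1.0, "d_StrD1": 2.0, "b_StrD2": 1.0, "d_StrD2": 1.0}
        assert d1_factor(0.0, p) == pytest.approx(1.0)
        assert d1_factor(0.5, p) == pytest.approx(2.0)
        p0 = {**p, "d_StrD1": 0.0}
        assert d1_factor(0.7, p0) == pytest.approx(p0["b_StrD1"])

    def test_d2_examples(self):
        p = {"b_StrD1": 1.0, "d_StrD1": 0.0, "b_StrD2": 1.0, "d_StrD2": 1.0}
        assert d2_factor(0.0, p) == pytest.approx(1.0)
        assert d2_factor(1.0, p) == pytest.approx(0.5)

    def test_d2_monotone_inhibitory(self):
        p = {"b_StrD1": 1.0, "d_StrD1": 0.0, "b_StrD2": 1.0, "d_StrD2": 5.0}
        grid = np.linspace(0.0, 1.0, 50)
        vals = d2_factor(grid, p)
        assert np.all(np.diff(vals) < 0)

    def test_d2_denominator_guard(self):
        p = {"b_StrD1": 1.0, "d_StrD1": 0.0, "b_StrD2": 0.5, "d_StrD2": -1.0}
        with pytest.raises(ValueError, match="denominator"):
            d2_factor(1.0, p)


class TestDopamineUnit:
    def test_no_drive_rests_at_minimum(self, params):
        trace = da_trajectory(PulseSpec(0.0, 1.0, 1.0), 0.001, 2.0, params)
        assert np.allclose(trace, DA_MIN, atol=1e-6)

    def test_tic_burst_reaches_max_near_one_second(self, params):
        trace = da_trajectory(PulseSpec(50.0, 0.020, 1.0), 0.001, 2.0, params)
        assert trace.max() == pytest.approx(DA_MAX, abs=1e-12)
        assert abs(trace.argmax() * 0.001 - 1.0) < 0.1
        assert trace[-1] < 0.05  # decays toward DA_MIN

    def test_clamped_to_operating_range(self, params):
        trace = da_trajectory(PulseSpec(100.0, 0.020, 1.0), 0.001, 2.0, params)
        assert trace.min() >= DA_MIN - 1e-12
        assert trace.max() <= DA_MAX + 1e-12

    def test_post_peak_decay_monotone(self, params):
        trace = da_trajectory(PulseSpec(50.0, 0.020, 1.0), 0.001, 2.0, params)
        k = trace.argmax()
        tail = trace[k + 100 :]  # past the clamped plateau
        assert np.all(np.diff(tail) <= 1e-12)

    def test_burst_outside_horizon_rejected(self, params):
        with pytest.raises(ValueError, match="horizon"):
            da_trajectory(PulseSpec(50.0, 0.02, 5.0), 0.001, 2.0, params)


class TestCorticalPulse:
    def test_zero_height_gives_zero_traces(self):
        out = cortical_pulse(PulseSpec(0.0, 1.0, 1.0, True),
                             np.random.default_rng(0), 100, 0.001)
        assert out.shape == (100, 3)
        assert np.all(out == 0)

    def test_deterministic_scalings(self):
        spec = PulseSpec(30.0, 0.040, 1.0, True)
        a = cortical_pulse(spec, np.random.default_rng(5), 2000, 0.001)
        b = cortical_pulse(spec, np.random.default_rng(5), 2000, 0.001)
        np.testing.assert_array_equal(a, b)

    def test_channel_scalings_differ_and_bounded(self):
        spec = PulseSpec(30.0, 0.040, 1.0, True)
        out = cortical_pulse(spec, np.random.default_rng(1), 2000, 0.001)
        peaks = out.max(axis=0)
        assert np.all(peaks <= 30.0 + 1e-9)
        integrals = out.sum(axis=0)
        assert len(np.unique(np.round(integrals, 6))) == 3


class TestGranulePurkinjeScheme:
    def test_selectable_channels_get_zero_columns(self, params):
        w = set_gc_pc_weights({0, 2}, params)
        assert np.all(w[0] == 0) and np.all(w[2] == 0)
        assert w[1].sum() > 0

    def test_invalid_channels_rejected(self, params):
        with pytest.raises(ValueError):
            set_gc_pc_weights({3}, params)

    def test_silent_mossy_fibres_purkinje_spontaneous_dentate_silent(
        self, params, rng
    ):
        """With no input the Purkinje cells fire spontaneously and their
        inhibition keeps the dentate nuclei silent."""
        circuit = build_network(params)
        _state, traces = circuit.simulate(
            800, 0.001, rng, record=["PC", "DN", "MF"]
        )
        assert np.all(traces["PC"][-100:] > 10)
        assert np.all(traces["DN"][-100:] < 1e-6)

    def test_nonselectable_channels_brake_dentate_via_purkinje(
        self, params, rng
    ):
        """Granule input to a non-selectable channel's Purkinje cell keeps it
        more active than in the selectable wiring, so the dentate is held at
        or below the selectable channel's level under the same drive."""
        drive = np.full((1500, 3), 350.0)
        non_sel = build_network(params, selectable_channels=())
        _s1, tr_non = non_sel.simulate(
            1500, 0.001, rng, m1_drive=drive, record=["PC", "DN"]
        )
        sel = build_network(params, selectable_channels=(0, 1, 2))
        _s2, tr_sel = sel.simulate(
            1500, 0.001, np.random.default_rng(12345), m1_drive=drive,
            record=["PC", "DN"],
        )
        # positive granule->Purkinje weights raise PC in the non-selectable
        # wiring; the extra Purkinje inhibition can only lower the dentate
        assert tr_non["PC"][-1].mean() > tr_sel["PC"][-1].mean() + 0.5
        assert tr_non["DN"].max() <= tr_sel["DN"].max() + 1e-9


class TestDisinhibitionChain:
    def test_striatal_drive_opens_thalamic_gate(self, circuit):
        """Raising StrD1 activity on one channel lowers that channel's
        GPi/SNr activity and raises its ThBC activity (double
        disinhibition), holding all other inputs frozen."""
        W = circuit.W
        gpi, thbc = SLICES["GPiSNr"], SLICES["ThBC"]

        def equilibrium(a_str):
            a = np.zeros(circuit.n)
            a[SLICES["StrD1"].start] = a_str
            u_g = u_t = 0.0
            for _ in range(400):
                a[gpi.start] = max(
                    0.0,
                    400 * np.tanh(u_g / 400) - circuit.thr[gpi.start],
                )
                I_g = circuit.r[gpi.start] + W[gpi.start] @ a
                u_g += 0.5 * (I_g - u_g)
                a[thbc.start] = max(
                    0.0,
                    400 * np.tanh(u_t / 400) - circuit.thr[thbc.start],
                )
                I_t = circuit.r[thbc.start] + W[thbc.start] @ a + 10.0
                u_t += 0.5 * (I_t - u_t)
            return a[gpi.start], a[thbc.start]

        gpi_low, thbc_low = equilibrium(10.0)
        gpi_high, thbc_high = equilibrium(150.0)
        assert gpi_high < gpi_low
        assert thbc_high > thbc_low
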