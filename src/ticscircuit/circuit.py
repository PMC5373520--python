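"""The basal ganglia-cerebellar-thalamo-cortical circuit.

Assembles the full architecture: three parallel basal-ganglia channels
(StrD1, StrD2, STN, GPe, GPi/SNr), a two-region thalamus (ThBC receiving
both basal-ganglia and cerebellar input, ThC receiving cerebellar input
only), a three-unit primary motor cortex (M1), a Marr-Albus cerebellar
microcircuit (mossy fibres MF, 100 granule cells GC, one Golgi cell GO,
three Purkinje cells PC, three dentate-nucleus units DN) and a dopamine
unit whose clamped potential multiplicatively modulates the two striatal
populations (excitatory on the D1 pathway, inhibitory on the D2 pathway).

The mossy-fibre layer is an instantaneous relay (weighted M1 + STN input
passed through the activation function); all other populations are leaky
integrator state units - 132 in total.
"""

from __future__ import annotations



import numpy as np

from .dynamics import ACTIVITY_CEILING, NetworkState, activate
from .inputs import PulseSpec
from .params import DA_MAX, DA_MIN, validate_params

__all__ = [
    "COMPONENTS",
    "CONNECTIONS",
    "TicCircuit",
    "build_network",
    "d1_factor",
    "d2_factor",
    "da_trajectory",
    "set_gc_pc_weights",
    "connection_table",
]

#: Leaky-integrator populations and their unit counts (132 state units).
COMPONENTS = [
    ("StrD1", 3),
    ("StrD2", 3),
    ("STN", 3),
    ("GPe", 3),
    ("GPiSNr", 3),
    ("ThBC", 3),
    ("ThC", 3),
    ("M1", 3),
    ("GC", 100),
    ("GO", 1),
    ("PC", 3),
    ("DN", 3),
    ("DA", 1),
]

N_UNITS = sum(n for _, n in COMPONENTS)  # 132
N_MF = 3  # mossy-fibre relay channels (not state units)

def _slices():
    out, k = {}, 0
    for name, n in COMPONENTS:
        out[name] = slice(k, k + n)
        k += n
    return out

SLICES = _slices()
DA_IDX = SLICES["DA"].start

#: Every arrow of the architecture: (pre, post, topology, sign, weight name).
#: Inhibitory (GABAergic) links enter the input sum with negative sign.
CONNECTIONS = [
    ("M1", "StrD1", "one-to-one", +1, "w_M1_StrD1"),
    ("M1", "StrD2", "one-to-one", +1, "w_M1_StrD2"),
    ("M1", "STN", "one-to-one", +1, "w_M1_STN"),
    ("M1", "MF", "one-to-one", +1, "w_M1_MF"),
    ("M1", "PC", "one-to-one", +1, "w_M1_PC"),
    ("M1", "ThBC", "one-to-one", +1, "w_M1_ThBC"),
    ("M1", "ThC", "one-to-one", +1, "w_M1_ThC"),
    ("ThBC", "M1", "one-to-one", +1, "w_ThBC_M1"),
    ("ThBC", "StrD1", "one-to-one", +1, "w_ThBC_StrD1"),
    ("ThBC", "StrD2", "one-to-one", +1, "w_ThBC_StrD2"),
    ("ThBC", "STN", "one-to-one", +1, "w_ThBC_STN"),
    ("ThC", "M1", "one-to-one", +1, "w_ThC_M1"),
    ("ThC", "StrD1", "one-to-one", +1, "w_ThC_StrD1"),
    ("ThC", "StrD2", "one-to-one", +1, "w_ThC_StrD2"),
    ("StrD1", "GPiSNr", "one-to-one", -1, "w_StrD1_GPiSNr"),
    ("StrD2", "GPe", "one-to-one", -1, "w_StrD2_GPe"),
    ("STN", "GPe", "all-to-all", +1, "w_STN_GPe"),
    ("STN", "GPiSNr", "all-to-all", +1, "w_STN_GPiSNr"),
    ("STN", "MF", "one-to-one", +1, "w_STN_MF"),
    ("GPe", "GPiSNr", "one-to-one", -1, "w_GPe_GPiSNr"),
    ("GPe", "STN", "one-to-one", -1, "w_GPe_STN"),
    ("GPiSNr", "ThBC", "one-to-one", -1, "w_GPiSNr_ThBC"),
    ("MF", "GC", "fixed-matrix", +1, "w_MF_GC"),
    ("MF", "GO", "all-to-all", +1, "w_MF_GO"),
    ("MF", "DN", "one-to-one", +1, "w_MF_DN"),
    ("GC", "GO", "all-to-all", +1, "w_GC_GO"),
    ("GC", "PC", "fixed-matrix", +1, "w_GC_PC"),
    ("GO", "GC", "all-to-all", -1, "w_GO_GC"),
    ("PC", "DN", "one-to-one", -1, "w_PC_DN"),
    ("DN", "ThBC", "one-to-one", +1, "w_DN_ThBC"),
    ("DN", "ThC", "one-to-one", +1, "w_DN_ThC"),
]

# per-component noise parameter names (GC, GO, PC, DN, DA are noise-free)
_NOISE_OF = {
    "StrD1": ("mean_BG", "sd_BG1"),
    "StrD2": ("mean_BG", "sd_BG1"),
    "STN": ("mean_BG", "sd_BG1"),
    "GPe": ("mean_BG", "sd_BG2"),
    "GPiSNr": ("mean_BG", "sd_BG2"),
    "ThBC": ("mean_Th", "sd_Th"),
    "ThC": ("mean_Th", "sd_Th"),
    "M1": ("mean_M1", "sd_M1"),
}


def d1_factor(a_da, params):
    """Multiplicative D1-pathway dopamine factor: ``b_StrD1 + d_StrD1 * a_DA``."""
    return params["b_StrD1"] + params["d_StrD1"] * np.asarray(a_da, dtype=float)


def d2_factor(a_da, params):
    """Multiplicative-inhibitory D2-pathway factor.

    ``d1_factor(a_DA) / (b_StrD2 + d_StrD2 * a_DA)``; the numerator carries
    the combined D1/D2 receptor effect, the denominator makes the factor
    decrease with dopamine.
    """
    a_da = np.asarray(a_da, dtype=float)
    den = params["b_StrD2"] + params["d_StrD2"] * a_da
    if np.any(den <= 0):
        raise ValueError("non-positive StrD2 dopamine denominator")
    return d1_factor(a_da, params) / den


def _gc_wiring(params):
    """Fixed random mossy-fibre -> granule wiring and heterogeneous GC thresholds.

    Each granule cell listens to one mossy-fibre channel (channel identity
    ``g % 3``) with a random weight, and carries a random threshold, so that
    an active mossy-fibre channel recruits only its most sensitive granule
    cells: a sparse, channel-specific code.
    """
    rng = np.random.default_rng(int(params["gc_seed"]))
    n_gc = SLICES["GC"].stop - SLICES["GC"].start
    channels = np.arange(n_gc) % N_MF
    w = np.zeros((n_gc, N_MF))
    w[np.arange(n_gc), channels] = params["w_MF_GC"] * rng.uniform(0.3, 1.5, n_gc)
    thr = params["thr_GC"] * rng.uniform(1.0, 4.0, n_gc)
    return w, thr, channels


def set_gc_pc_weights(selectable_channels, params, gc_channels=None):
    """Hand-set granule -> Purkinje weight matrix (100 x 3).

    For a *selectable* channel the column is zero (granule input cannot keep
    the Purkinje cell active, so incoming mossy-fibre drive disinhibits the
    dentate unit); for non-selectable channels the channel's granule cells
    excite the Purkinje unit, keeping it active and the dentate unit silent.
    """
    selectable = set(int(c) for c in selectable_channels)
    if not selectable <= {0, 1, 2}:
        raise ValueError("selectable channels must be a subset of {0, 1, 2}")
    if gc_channels is None:
        _, _, gc_channels = _gc_wiring(params)
    n_gc = len(gc_channels)
    w = np.zeros((3, n_gc))
    for ch in range(3):
        if ch not in selectable:
            w[ch, gc_channels == ch] = params["w_GC_PC"]
    return w


class TicCircuit:
    """Executable instance of the circuit for a given parameter vector."""

    def __init__(self, params, selectable_channels=(0, 1, 2)):
        self.params = validate_params(params)
        p = self.params

        self.n = N_UNITS
        self.tau = np.empty(N_UNITS)
        self.r = np.empty(N_UNITS)
        self.thr = np.zeros(N_UNITS)
        self.noise_mean = np.zeros(N_UNITS)
        self.noise_sd = np.zeros(N_UNITS)
        for name, _cnt in COMPONENTS:
            s = SLICES[name]
            if name == "DA":
                self.tau[s] = p["tau_DA"]
                self.r[s] = DA_MIN
                continue
            self.tau[s] = p[f"tau_{name}"]
            self.r[s] = p[f"r_{name}"]
            self.thr[s] = p[f"thr_{name}"]
            if name in _NOISE_OF:
                mkey, skey = _NOISE_OF[name]
                self.noise_mean[s] = p[mkey]
                self.noise_sd[s] = p[skey]

        # granule-layer wiring (fixed structural randomness)
        w_mf_gc, thr_gc, self.gc_channels = _gc_wiring(p)
        self.thr[SLICES["GC"]] = thr_gc

        # state-unit weight matrix
        W = np.zeros((N_UNITS, N_UNITS))
        # mossy-fibre relay: input weights (from state activities) and
        # output weights (into state units)
        self.W_from_mf = np.zeros((N_UNITS, N_MF))
        self.mf_in_m1 = p["w_M1_MF"]
        self.mf_in_stn = p["w_STN_MF"]
        self.mf_r = p["r_MF"]
        self.mf_thr = p["thr_MF"]
        self.mf_noise_mean = p["mean_MF"]
        self.mf_noise_sd = p["sd_MF"]

        for pre, post, topology, sign, wname in CONNECTIONS:
            w = sign * p[wname]
            if pre == "MF":
                tgt = SLICES[post]
                if topology == "fixed-matrix":  # MF -> GC
                    self.W_from_mf[tgt] = sign * w_mf_gc
                elif topology == "all-to-all":  # MF -> GO
                    self.W_from_mf[tgt] = w
                else:  # one-to-one: MF -> DN
                    self.W_from_mf[tgt, :] = w * np.eye(N_MF)
                continue
            if post == "MF":
                continue  # handled by mf_in_* above
            ps, qs = SLICES[pre], SLICES[post]
            npre, npost = ps.stop - ps.start, qs.stop - qs.start
            if topology == "one-to-one":
                if npre != npost:
                    raise ValueError(
                        f"one-to-one connection {pre}->{post} requires equal "
                        f"unit counts, got {npre} and {npost}"
                    )
                W[qs, ps] = w * np.eye(npre)
            elif topology == "all-to-all":
                W[qs, ps] = w
            elif topology == "fixed-matrix":  # GC -> PC
                W[qs, ps] = sign * set_gc_pc_weights(
                    selectable_channels, p, self.gc_channels
                )
            else:
                raise ValueError(f"unknown topology {topology!r}")
        self.W = W

        self.selectable_channels = tuple(sorted(set(int(c) for c in selectable_channels)))
        self._strd1 = SLICES["StrD1"]
        self._strd2 = SLICES["StrD2"]
        self._m1 = SLICES["M1"]
        self._stn = SLICES["STN"]
        self._noisy = np.flatnonzero(self.noise_sd > 0)

    # ------------------------------------------------------------------
    def initial_state(self) -> NetworkState:
        u = np.zeros(N_UNITS)
        u[DA_IDX] = DA_MIN
        a = activate(u, self.thr)
        a[DA_IDX] = u[DA_IDX]
        return NetworkState(u=u, a=a, t=0.0)

    def mf_activity(self, a, noise=0.0):
        """Instantaneous mossy-fibre relay activity from state activities."""
        drive = (
            self.mf_r
            + self.mf_in_m1 * a[self._m1]
            + self.mf_in_stn * a[self._stn]
            + noise
        )
        return activate(drive, self.mf_thr)

    def simulate(self, n_steps, dt, rng, da_drive=None, m1_drive=None,
                 state=None, record=None, check_every=100):
        """Integrate the circuit for ``n_steps`` synchronous Euler steps.

        Parameters
        ----------
        da_drive : (n_steps,) array or None
            External drive to the dopamine unit (already on the DA scale,
            i.e. burst height times the DA input gain).
        m1_drive : (n_steps, 3) array or None
            External per-channel drive to M1.
        record : sequence of component names or None
            Components whose activities are recorded. ``"GC"`` records the
            mean granule activity and the active fraction instead of all
            100 traces; ``"MF"`` records the three relay traces.
            None records every component.

        Returns
        -------
        (state, traces) where ``traces`` maps component name to an
        ``(n_steps, n_units)`` activity array (GC: ``(n_steps, 2)`` holding
        mean activity and active fraction; DA holds the clamped potential).
        """
        p = self.params
        if np.any(dt >= self.tau):
            raise ValueError("dt must be smaller than every unit time constant")
        if state is None:
            state = self.initial_state()
        if record is None:
            record = [name for name, _ in COMPONENTS] + ["MF"]
        rec_names = list(record)

        # recorded state units gathered through one index array per step
        gather_idx = []
        gather_cols = {}
        col = 0
        want_gc = want_mf = False
        for name in rec_names:
            if name == "GC":
                want_gc = True
            elif name == "MF":
                want_mf = True
            else:
                s = SLICES[name]
                idx = list(range(s.start, s.stop))
                gather_cols[name] = (col, col + len(idx))
                gather_idx.extend(idx)
                col += len(idx)
        gather_idx = np.asarray(gather_idx, dtype=np.intp)
        rec_units = np.empty((n_steps, len(gather_idx)))
        rec_gc = np.empty((n_steps, 2)) if want_gc else None
        rec_mf = np.empty((n_steps, N_MF)) if want_mf else None

        u = state.u.copy()
        a = state.a.copy()
        t = state.t
        W = self.W
        W_mf = self.W_from_mf
        r = self.r
        tau_ratio = dt / self.tau
        thr = self.thr
        noisy = self._noisy
        nm, nsd = self.noise_mean[noisy], self.noise_sd[noisy]
        b1, d1 = p["b_StrD1"], p["d_StrD1"]
        b2, d2 = p["b_StrD2"], p["d_StrD2"]
        m1_sl, stn_sl = self._m1, self._stn
        strd1, strd2 = self._strd1, self._strd2
        gc_sl = SLICES["GC"]
        mf_r, mf_thr = self.mf_r, self.mf_thr
        mf_w_m1, mf_w_stn = self.mf_in_m1, self.mf_in_stn
        ceil = ACTIVITY_CEILING

        chunk = 2000
        noise_block = mf_noise_block = None
        for k in range(n_steps):
            j = k % chunk
            if j == 0:
                m = min(chunk, n_steps - k)
                noise_block = rng.normal(nm, nsd, size=(m, len(noisy)))
                if self.mf_noise_sd > 0 or self.mf_noise_mean != 0:
                    mf_noise_block = rng.normal(
                        self.mf_noise_mean, self.mf_noise_sd, size=(m, N_MF)
                    )
                else:
                    mf_noise_block = np.zeros((m, N_MF))

            mf_drive = (
                mf_r + mf_w_m1 * a[m1_sl] + mf_w_stn * a[stn_sl] + mf_noise_block[j]
            )
            a_mf = np.maximum(0.0, ceil * np.tanh(mf_drive / ceil) - mf_thr)
            I = r + W @ a + W_mf @ a_mf
            I[noisy] += noise_block[j]
            if m1_drive is not None:
                I[m1_sl] += m1_drive[k]
            a_da = a[DA_IDX]
            f1 = b1 + d1 * a_da
            I[strd1] *= f1
            I[strd2] *= f1 / (b2 + d2 * a_da)
            # dopamine unit: driven only by its burst input, resting at DA_MIN
            I[DA_IDX] = DA_MIN + (da_drive[k] if da_drive is not None else 0.0)

            u += tau_ratio * (I - u)
            u[DA_IDX] = min(max(u[DA_IDX], DA_MIN), DA_MAX)
            if k % check_every == 0 and not np.all(np.isfinite(u)):
                raise FloatingPointError(f"non-finite state at step {k}")
            a = np.maximum(0.0, ceil * np.tanh(u / ceil) - thr)
            a[DA_IDX] = u[DA_IDX]
            t += dt

            rec_units[k] = a[gather_idx]
            if want_gc:
                g = a[gc_sl]
                rec_gc[k, 0] = g.mean()
                rec_gc[k, 1] = np.mean(g > 0)
            if want_mf:
                rec_mf[k] = a_mf
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(f"non-finite state at step {n_steps - 1}")

        traces = {}
        for name in rec_names:
            if name == "GC":
                traces[name] = rec_gc
            elif name == "MF":
                traces[name] = rec_mf
            else:
                lo, hi = gather_cols[name]
                traces[name] = rec_units[:, lo:hi]
        return NetworkState(u=u, a=a, t=t), traces


def build_network(params, selectable_channels=(0, 1, 2)) -> TicCircuit:
    """Assemble the executable circuit; validates completeness and bounds."""
    return TicCircuit(params, selectable_channels)


def da_trajectory(burst: PulseSpec, dt, horizon, params):
    """Potential trace of the dopamine unit under a Gaussian burst.

    The unit rests at ``DA_MIN`` = 0.01, is driven by the burst (height on
    the 0-100 burst scale, converted by ``da_gain``) and is hard-clamped
    to ``[DA_MIN, DA_MAX]`` = [0.01, 0.5].
    """
    n_steps = int(round(horizon / dt))
    if burst.height > 0 and not (0 <= burst.center <= horizon):
        raise ValueError("burst centre must lie within the horizon")
    drive = params["da_gain"] * burst.profile(n_steps, dt)
    tau = params["tau_DA"]
    u = DA_MIN
    out = np.empty(n_steps)
    for k in range(n_steps):
        u += (dt / tau) * (-u + DA_MIN + drive[k])
        u = min(max(u, DA_MIN), DA_MAX)
        out[k] = u
    return out


def connection_table():
    """The architecture's edge list as a list of dict rows (for CSV export)."""
    rows = []
    for pre, post, topology, sign, wname in CONNECTIONS:
        rows.append(
            {
                "pre": pre,
                "post": post,
                "topology": topology,
                "sign": "inhibitory" if sign < 0 else "excitatory",
                "weight_param": wname,
            }
        )
    return rows
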