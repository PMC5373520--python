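"""Model parameters: default values, bounds, and the GA-fitted subset.

The full parameter vector is a flat ``name -> value`` mapping covering
per-component unit constants (``tau_X``, ``r_X``, ``thr_X``), noise
specifications (``mean_*`` / ``sd_*``), connection-weight magnitudes
(``w_pre_post``; signs are fixed by the anatomy and applied when the
network is assembled) and the striatal dopamine-modulation coefficients
(``b_StrD1``, ``d_StrD1``, ``b_StrD2``, ``d_StrD2``).

The defaults shipped here are the package's own calibrated set: structural
constants follow classic basal-ganglia action-selection and Marr-Albus
cerebellar rate models, and the remaining weights were tuned (by hand and
with the package's genetic algorithm against its fixture curves, see
``docs/methods.md``) so that the circuit reproduces the target phenomena:
tic generation requires the conjunction of a dopamine burst and cortical
input, selection is winner-take-all, striatal/pallidal-output activity is
tic-insensitive while downstream areas are not, and basal-ganglia activity
leads primary motor cortex by roughly 0.12 s.
"""

from __future__ import annotations


__all__ = ["DEFAULT_PARAMS", "PARAM_BOUNDS", "STARRED", "validate_params"]

DA_MIN = 0.01
DA_MAX = 0.5

DEFAULT_PARAMS = {
    # --- unit time constants (seconds) ---
    "tau_StrD1": 0.05,
    "tau_StrD2": 0.05,
    "tau_STN": 0.01,
    "tau_GPe": 0.08,
    "tau_GPiSNr": 0.005,
    "tau_ThBC": 0.02,
    "tau_ThC": 0.02,
    "tau_M1": 0.3,
    "tau_GC": 0.01,
    "tau_GO": 0.01,
    "tau_PC": 0.02,
    "tau_DN": 0.02,
    "tau_DA": 0.15,
    # --- resting potentials ---
    "r_StrD1": 60.0,
    "r_StrD2": 60.0,
    "r_STN": 8.0,
    "r_GPe": 150.0,
    "r_GPiSNr": 192.0,
    "r_ThBC": 0.0,
    "r_ThC": 0.0,
    "r_M1": 0.0,
    "r_MF": 0.0,
    "r_GC": 0.0,
    "r_GO": 0.0,
    "r_PC": 35.0,
    "r_DN": 0.0,
    # --- activation thresholds (activity scale) ---
    "thr_StrD1": 0.0,
    "thr_StrD2": 0.0,
    "thr_STN": 0.0,
    "thr_GPe": 0.0,
    "thr_GPiSNr": 0.0,
    "thr_ThBC": 0.65,
    "thr_ThC": 0.0,
    "thr_M1": 0.0,
    "thr_MF": 0.0,
    "thr_GC": 10.0,
    "thr_GO": 0.0,
    "thr_PC": 0.0,
    "thr_DN": 0.0,
    # --- noise (GC, GO, PC, DN and DA are noise-free) ---
    "mean_BG": 0.0,
    "sd_BG1": 5.0,   # StrD1, StrD2, STN
    "sd_BG2": 1.0,   # GPe, GPi/SNr
    "mean_Th": 0.0,
    "sd_Th": 1.0,
    "mean_M1": 0.0,
    "sd_M1": 1.0,
    "mean_MF": 0.0,
    "sd_MF": 2.0,
    # --- connection-weight magnitudes (signs fixed by anatomy) ---
    "w_M1_StrD1": 0.2,
    "w_M1_StrD2": 0.05,
    "w_M1_STN": 0.5,
    "w_M1_MF": 0.4,
    "w_M1_PC": 0.25,
    "w_M1_ThBC": 1.1,
    "w_M1_ThC": 0.8,
    "w_ThBC_M1": 36.0,
    "w_ThBC_StrD1": 0.02,
    "w_ThBC_StrD2": 0.02,
    "w_ThBC_STN": 0.2,
    "w_ThC_M1": 0.2,
    "w_ThC_StrD1": 0.02,
    "w_ThC_StrD2": 0.02,
    "w_StrD1_GPiSNr": 1.5,
    "w_StrD2_GPe": 2.0,
    "w_STN_GPe": 0.35,
    "w_STN_GPiSNr": 1.6,
    "w_STN_MF": 0.3,
    "w_GPe_GPiSNr": 0.55,
    "w_GPe_STN": 0.05,
    "w_GPiSNr_ThBC": 2.8,
    "w_MF_GC": 2.2,
    "w_MF_GO": 0.2,
    "w_MF_DN": 0.4,
    "w_GC_GO": 0.02,
    "w_GC_PC": 0.05,
    "w_GO_GC": 1.5,
    "w_PC_DN": 0.6,
    "w_DN_ThBC": 0.5,
    "w_DN_ThC": 0.6,
    # --- striatal dopamine modulation ---
    "b_StrD1": 1.0,
    "d_StrD1": 3.2,
    "b_StrD2": 1.0,
    "d_StrD2": 12.0,
    # --- input coupling gains ---
    "da_gain": 0.05,    # burst height (0-100 burst scale) -> DA-unit drive
    "w_ext_M1": 0.36,   # external cortical pulse -> M1 drive
    # --- cerebellar granule-layer wiring seed (fixed structural randomness) ---
    "gc_seed": 20170330,
}

def _bounds():
    b = {}
    for name, v in DEFAULT_PARAMS.items():
        if name.startswith("tau_"):
            b[name] = (0.002, 0.5)
        elif name == "w_ext_M1":
            b[name] = (0.0, 2.0)
        elif name.startswith("w_"):
            b[name] = (0.0, max(5.0, 3.0 * v))
        elif name.startswith("r_"):
            b[name] = (-50.0, max(50.0, 3.0 * v))
        elif name.startswith("thr_"):
            b[name] = (0.0, 60.0)
        elif name.startswith("sd_"):
            b[name] = (0.0, 20.0)
        elif name.startswith("mean_"):
            b[name] = (-10.0, 10.0)
        elif name in ("b_StrD1", "b_StrD2"):
            b[name] = (0.1, 4.0)
        elif name in ("d_StrD1", "d_StrD2"):
            b[name] = (0.0, 20.0)
        elif name == "da_gain":
            b[name] = (0.001, 0.2)
        else:  # structural integers (gc_seed)
            b[name] = (v, v)
    return b

#: Finite bounds for every parameter, used by the genetic algorithm.
PARAM_BOUNDS = _bounds()

#: Parameters searched by the genetic algorithm (the fitted subset); the
#: remaining values are structural constants of the circuit.
STARRED = [
    "w_ThBC_M1",
    "w_ThC_M1",
    "w_M1_ThBC",
    "w_M1_ThC",
    "w_M1_STN",
    "w_STN_GPiSNr",
    "w_GPe_GPiSNr",
    "w_StrD1_GPiSNr",
    "w_GPiSNr_ThBC",
    "w_STN_MF",
    "w_DN_ThBC",
    "w_DN_ThC",
    "r_GPiSNr",
    "r_GPe",
    "d_StrD1",
    "d_StrD2",
]


def validate_params(params: dict) -> dict:
    """Check completeness and bounds; returns the validated dict.

    Raises
    ------
    KeyError   if a required parameter is missing.
    ValueError if a value violates its bounds or a structural invariant.
    """
    missing = sorted(set(DEFAULT_PARAMS) - set(params))
    if missing:
        raise KeyError(f"missing model parameters: {', '.join(missing)}")
    unknown = sorted(set(params) - set(DEFAULT_PARAMS))
    if unknown:
        raise KeyError(f"unknown model parameters: {', '.join(unknown)}")
    for name, v in params.items():
        lo, hi = PARAM_BOUNDS[name]
        if not (lo - 1e-12 <= v <= hi + 1e-12):
            raise ValueError(f"parameter {name}={v} outside bounds [{lo}, {hi}]")
    # Eq-5 denominator must stay positive over the whole DA operating range.
    for a_da in (DA_MIN, DA_MAX):
        den = params["b_StrD2"] + params["d_StrD2"] * a_da
        if den <= 0:
            raise ValueError(
                f"b_StrD2 + d_StrD2*a_DA = {den} <= 0 at a_DA={a_da}; "
                "the StrD2 dopamine factor would blow up"
            )
    return dict(params)
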