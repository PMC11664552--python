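"""Derivation of photosynthetic variables from gas exchange and fluorescence.

One light-saturated measurement per leaf yields, in order:

* ``phi_psii``     PSII operating efficiency from (Fm' - Fs)/Fm'
* ``j_f``          fluorescence-based electron transport, alpha*beta_PSII * phi_PSII * PPFD
* ``g_m``          mesophyll conductance via the variable-J method
* ``c_c``          chloroplastic CO2 from Fick's law, Ci - A/gm
* ``v_cmax``       one-point Rubisco capacity, A(Cc + Km)/(Cc - Gamma*)
* ``g_1``          stomatal slope from the unified stomatal optimality (USO)
                   model inverted at the measured Ci/Cs and sqrt(VPD)

with Vcmax and gm additionally normalized to 25 degC.  The product
alpha*beta_PSII is calibrated beforehand from a light-response ladder under
1% O2 (non-photorespiratory), as 4x the intercept-free slope of phi_CO2
against phi_PSII.

Quality rules applied during batch derivation: records with Asat <= 0 are
excluded; fluorescence pairs with Fs > Fm' are flagged invalid; gm (and the
Vcmax that depends on it) is only retained when Ci lies within
[150, 350] umol mol-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .kinetics import PhotosyntheticKinetics, kinetics_at, normalize_to_25

logger = logging.getLogger(__name__)

GSW_TO_GSC = 1.6  # ratio of H2O to CO2 diffusivity through stomata
CI_FILTER = (150.0, 350.0)  # umol mol-1, inclusive bounds for gm validity

GAS_EXCHANGE_COLUMNS = [
    "dae", "treatment", "leaf_id", "t_leaf", "c_s", "c_i",
    "a_sat", "g_sw", "vpd_leaf", "ppfd", "f_s", "f_m_prime",
]


class FluorescenceError(ValueError):
    """Fs exceeds Fm' or other fluorescence-validity violation."""


class CalibrationError(RuntimeError):
    """Not enough usable points to calibrate alpha*beta_PSII."""


class DerivationError(ValueError):
    """A per-record derivation left its mathematical domain."""


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated alpha*beta_PSII = 4k with k the phi_CO2 ~ phi_PSII slope."""

    k_slope: float
    alpha_beta: float
    sd: float
    n_points: int

    def __post_init__(self):
        if not (0.0 < self.alpha_beta <= 1.0):
            logger.warning("alpha*beta_PSII = %.3f outside the expected (0, 1]", self.alpha_beta)


@dataclass
class DerivedLeafState:
    """Per-record derived variables with validity flags."""

    dae: int
    treatment: str
    leaf_id: str
    g_s: float  # stomatal conductance to CO2, mol m-2 s-1
    ci_over_cs: float
    phi_psii: float
    j_f: float
    g_1: Optional[float]  # kPa^0.5
    g_m: Optional[float]
    g_m_25: Optional[float]
    v_cmax: Optional[float]
    v_cmax_25: Optional[float]
    c_c: Optional[float]
    gm_valid: bool
    a_sat: float
    flags: tuple = ()


def phi_psii(f_s, f_m_prime):
    """PSII operating efficiency (Fm' - Fs)/Fm'."""
    if np.any(np.asarray(f_m_prime) <= 0):
        raise FluorescenceError("f_m_prime must be positive")
    if np.any(np.asarray(f_s) > np.asarray(f_m_prime)):
        raise FluorescenceError("f_s exceeds f_m_prime")
    out = (np.asarray(f_m_prime, dtype=float) - np.asarray(f_s, dtype=float)) / np.asarray(
        f_m_prime, dtype=float
    )
    return out if np.ndim(out) else float(out)


def fit_alpha_beta_psii(points: pd.DataFrame) -> CalibrationResult:
    """Calibrate alpha*beta_PSII from a low-O2 light-response table.

    ``points`` needs columns (ppfd, a_net, f_s, f_m_prime) and optionally
    o2_fraction (points above 2% O2 are rejected as photorespiratory).
    phi_CO2 = a_net/ppfd is regressed on phi_PSII through the origin; the
    factor 4 converts the CO2 quantum yield to the electron yield.
    """
    df = points.copy()
    df.columns = [c.strip().lower() for c in df.columns]
    if "o2_fraction" in df.columns:
        df = df[df["o2_fraction"] <= 0.02]
    df = df[df["ppfd"] > 0]
    if len(df) < 5:
        raise CalibrationError(f"need >= 5 usable low-O2 points, got {len(df)}")
    phi = phi_psii(df["f_s"].to_numpy(), df["f_m_prime"].to_numpy())
    phi_co2 = df["a_net"].to_numpy() / df["ppfd"].to_numpy()
    sxx = float(phi @ phi)
    if sxx == 0.0:
        raise CalibrationError("phi_PSII identically zero")
    k = float(phi @ phi_co2) / sxx
    resid = phi_co2 - k * phi
    n = len(df)
    sd_k = math.sqrt(float(resid @ resid) / max(n - 1, 1) / sxx)
    if k == 0.0:
        logger.warning("calibration slope k = 0 (no CO2 uptake response)")
    return CalibrationResult(k_slope=k, alpha_beta=4.0 * k, sd=4.0 * sd_k, n_points=n)


def electron_transport(ppfd, phi, alpha_beta):
    """Fluorescence-based electron transport J_F = alpha*beta_PSII * phi_PSII * PPFD."""
    return alpha_beta * phi * ppfd


def gm_variable_j(a_sat, c_i, gamma_star, j_f):
    """Mesophyll conductance by the variable-J method.

    gm = Asat / (Ci - Gamma* (J_F + 8 Asat) / (J_F - 4 Asat)); requires
    J_F > 4 Asat (some electron transport beyond carboxylation demand).
    """
    if j_f <= 4.0 * a_sat:
        raise DerivationError("variable-J denominator degenerate: j_f <= 4*a_sat")
    if a_sat <= 0:
        raise DerivationError("variable-J requires a_sat > 0")
    bracket = c_i - gamma_star * (j_f + 8.0 * a_sat) / (j_f - 4.0 * a_sat)
    if bracket <= 0:
        return float("nan")  # flagged invalid by the caller
    return a_sat / bracket


def chloroplast_co2(c_i, a_sat, g_m):
    """Chloroplastic CO2 via Fick's law: Cc = Ci - Asat/gm."""
    if g_m <= 0:
        raise DerivationError("g_m must be positive")
    return c_i - a_sat / g_m


def vcmax_one_point(a_sat, c_c, k_m, gamma_star, r_d=0.0):
    """One-point Vcmax from a light-saturated measurement.

    Vcmax = (Asat + Rd)(Cc + Km)/(Cc - Gamma*).
    """
    if c_c <= gamma_star:
        raise DerivationError("Cc at or below the compensation point")
    return (a_sat + r_d) * (c_c + k_m) / (c_c - gamma_star)


def g1_from_gas_exchange(c_i, c_s, vpd_leaf):
    """Stomatal slope g1 from the USO model inverted at measured Ci/Cs.

    g1 = (Ci/Cs) sqrt(VPD) / (1 - Ci/Cs), in kPa^0.5.  The square root of
    VPD follows from the optimality derivation (g1 carries kPa^0.5 units).
    """
    if vpd_leaf <= 0:
        raise DerivationError("vpd_leaf must be positive")
    ratio = c_i / c_s
    if not 0.0 < ratio < 1.0:
        raise DerivationError(f"Ci/Cs = {ratio:.3f} outside (0, 1)")
    return ratio * math.sqrt(vpd_leaf) / (1.0 - ratio)


def uso_stomatal_conductance(a_sat, c_s, vpd_leaf, g_1):
    """Forward USO model: gs = (1 + g1/sqrt(VPD)) * Asat / Cs (CO2 basis)."""
    return (1.0 + g_1 / math.sqrt(vpd_leaf)) * a_sat / c_s


def gs_co2(g_sw):
    """Stomatal conductance to CO2 from the water-vapor value (divide by 1.6)."""
    g_sw = np.asarray(g_sw, dtype=float)
    if np.any(g_sw < 0):
        raise DerivationError("g_sw must be non-negative")
    out = g_sw / GSW_TO_GSC
    return out if out.ndim else float(out)


def derive_leaf_state(
    rec, cal: CalibrationResult, kin: PhotosyntheticKinetics, ci_filter=CI_FILTER
) -> DerivedLeafState:
    """Derive all leaf variables from one gas-exchange record.

    ``rec`` is any mapping (e.g. a DataFrame row) with the gas-exchange
    columns.  Failures in individual derivations are recorded per-field via
    NaN + flags rather than aborting.
    """
    flags = []
    a_sat = float(rec["a_sat"])
    if a_sat <= 0:
        raise DerivationError("record with a_sat <= 0 must be excluded upstream")
    c_i, c_s = float(rec["c_i"]), float(rec["c_s"])
    t_leaf = float(rec["t_leaf"])
    vpd = float(rec["vpd_leaf"])

    phi = phi_psii(float(rec["f_s"]), float(rec["f_m_prime"]))
    j_f = electron_transport(float(rec["ppfd"]), phi, cal.alpha_beta)
    g_s = gs_co2(float(rec["g_sw"]))
    ratio = c_i / c_s

    try:
        g_1 = g1_from_gas_exchange(c_i, c_s, vpd)
    except DerivationError as err:
        g_1 = None
        flags.append(f"g1: {err}")

    km, gamma_star = kinetics_at(t_leaf, kin)
    gm_valid = ci_filter[0] <= c_i <= ci_filter[1]
    g_m = g_m_25 = v_cmax = v_cmax_25 = c_c = None
    if not gm_valid:
        flags.append(f"ci {c_i:.0f} outside [{ci_filter[0]:.0f}, {ci_filter[1]:.0f}]")
    else:
        try:
            g_m = gm_variable_j(a_sat, c_i, gamma_star, j_f)
            if not np.isfinite(g_m) or g_m <= 0:
                raise DerivationError("non-positive variable-J gm")
            c_c = chloroplast_co2(c_i, a_sat, g_m)
            v_cmax = vcmax_one_point(a_sat, c_c, km, gamma_star, kin.r_d)
            g_m_25 = normalize_to_25(g_m, t_leaf, kin.ea_gm)
            v_cmax_25 = normalize_to_25(v_cmax, t_leaf, kin.ea_vcmax)
        except DerivationError as err:
            gm_valid = False
            g_m = g_m_25 = v_cmax = v_cmax_25 = c_c = None
            flags.append(f"gm/vcmax: {err}")

    return DerivedLeafState(
        dae=int(rec["dae"]),
        treatment=str(rec["treatment"]),
        leaf_id=str(rec["leaf_id"]),
        g_s=g_s,
        ci_over_cs=ratio,
        phi_psii=phi,
        j_f=j_f,
        g_1=g_1,
        g_m=g_m,
        g_m_25=g_m_25,
        v_cmax=v_cmax,
        v_cmax_25=v_cmax_25,
        c_c=c_c,
        gm_valid=gm_valid,
        a_sat=a_sat,
        flags=tuple(flags),
    )


DERIVED_NUMERIC = ["a_sat", "g_s", "g_m_25", "v_cmax_25", "g_1", "ci_over_cs"]


def derive_states(
    records: pd.DataFrame, cal: CalibrationResult, kin: PhotosyntheticKinetics, ci_filter=CI_FILTER
) -> pd.DataFrame:
    """Batch derivation with the quality rules applied; one row per usable record."""
    df = records.copy()
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in GAS_EXCHANGE_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"gas-exchange table is missing columns: {missing}")

    n_asat = int((df["a_sat"] <= 0).sum())
    if n_asat:
        logger.info("excluding %d records with a_sat <= 0", n_asat)
    df = df[df["a_sat"] > 0]
    bad_fluo = df["f_s"] > df["f_m_prime"]
    if bad_fluo.any():
        logger.info("excluding %d records with f_s > f_m_prime", int(bad_fluo.sum()))
    df = df[~bad_fluo]

    rows = []
    for _, rec in df.iterrows():
        st = derive_leaf_state(rec, cal, kin, ci_filter)
        rows.append(
            {
                "dae": st.dae,
                "treatment": st.treatment,
                "leaf_id": st.leaf_id,
                "a_sat": st.a_sat,
                "g_s": st.g_s,
                "g_m": st.g_m,
                "g_m_25": st.g_m_25,
                "v_cmax": st.v_cmax,
                "v_cmax_25": st.v_cmax_25,
                "g_1": st.g_1,
                "ci_over_cs": st.ci_over_cs,
                "c_c": st.c_c,
                "phi_psii": st.phi_psii,
                "j_f": st.j_f,
                "gm_valid": st.gm_valid,
                "flags": ";".join(st.flags),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        for col in ("g_m", "g_m_25", "v_cmax", "v_cmax_25", "g_1", "c_c"):
            out[col] = out[col].astype(float)
    return out


def aggregate_daily_means(states: pd.DataFrame) -> pd.DataFrame:
    """Per-(day, treatment) means and SDs, missing values excluded per variable.

    Measurements of one day and treatment share meteorological and soil
    conditions, so they are pooled before any response fitting.
    """
    if states.empty:
        return pd.DataFrame()
    grouped = states.groupby(["dae", "treatment"])
    out = []
    for (dae, trt), grp in grouped:
        row = {"dae": dae, "treatment": trt, "n_records": len(grp)}
        for col in DERIVED_NUMERIC:
            vals = grp[col].dropna().to_numpy(dtype=float)
            row[col] = vals.mean() if len(vals) else np.nan
            row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{col}_n"] = len(vals)
        out.append(row)
    return pd.DataFrame(out).sort_values(["treatment", "dae"]).reset_index(drop=True)
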