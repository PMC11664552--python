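"""Partitioning of drought limitations to light-saturated photosynthesis.

Two complementary schemes are evaluated along a REW grid from the fitted
response curves.

Grassi-Magnani scheme: the relative decline of assimilation is split into
stomatal, mesophyll and biochemical parts,

    dA/A = (dgs/gs) l_gs + (dgm/gm) l_gm + (dVcmax/Vcmax) l_vcmax
         = L_gs + L_gm + L_vcmax,

with weights built from the total conductance gt (1/gt = 1/gs + 1/gm) and
the FvCB slope dA/dCc; the weights sum to one by construction.

USO-coupled scheme: gs is not an independent driver -- it follows the
unified stomatal optimality model gs = (1 + g1/sqrt(VPD)) A/Cs.  Taking the
total derivative of that closure turns the stomatal term into explicit
g1 and VPD terms and inflates the remaining weights by 1/(1 - l_gs):

    dA/A = (dg1/g1) (l_gs/(1-l_gs)) (Ci/Cs)
         + (dgm/gm)  l_gm/(1-l_gs)
         + (dVcmax/Vcmax) l_vcmax/(1-l_gs)
         - 1/2 (l_gs/(1-l_gs)) (Ci/Cs) (dVPD/VPD).

The difference between the two schemes decomposes the stomatal-closure
contribution L_gs into its physiological origins (mesophyll and biochemical
feedbacks on gs, plus direct VPD and g1 effects).

Relative variations use the convention dy/y = (y_max - y(REW)) /
(y_max - y(REW_min)): zero on the plateau and magnitude one at the driest
observed REW, for declining and rising variables alike.  dVPD/VPD follows
the same convention on the (decreasing) linear VPD-REW relation, the
negative sign being carried explicitly by the VPD term.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .drought_response import LinearPlateauFit
from .kinetics import PhotosyntheticKinetics, TOBACCO_CC
from .presets import CS_CHAMBER, MIN_OBSERVED_REW

logger = logging.getLogger(__name__)

REQUIRED_FITS = ("a_sat", "g_s", "g_m_25", "v_cmax_25", "ci_over_cs", "g_1")


@dataclass(frozen=True)
class VpdRewRelation:
    """Linear VPD(REW) relation; slope must be negative (drier soil, drier air)."""

    slope: float  # kPa per REW unit
    intercept: float  # kPa
    r2: float = float("nan")
    sd_slope: float = float("nan")

    def __post_init__(self):
        if self.slope >= 0:
            logger.warning(
                "VPD-REW slope %.3f is non-negative; the drought convention assumes "
                "VPD rises as soil dries",
                self.slope,
            )

    def predict(self, rew):
        return self.slope * np.asarray(rew, dtype=float) + self.intercept


#: Default greenhouse relation: ~1 kPa at field capacity rising to ~3.3 kPa
#: at the driest observed soil.  Only the convention-normalized dVPD/VPD
#: enters the contributions, which is slope/intercept invariant for a line.
DEFAULT_VPD_REW = VpdRewRelation(slope=-3.0, intercept=4.0)


@dataclass
class LimitationState:
    """All limitation terms of both schemes at one REW value."""

    rew: float
    a_sat: float
    g_s: float
    g_m: float
    v_cmax: float
    ci_over_cs: float
    g_1: float
    vpd: float
    c_c: float
    g_t: float
    dA_dCc: float
    rel: Dict[str, float]  # relative variations dy/y per driver
    l_gs: float
    l_gm: float
    l_vcmax: float
    l_g1_uso: float
    l_gm_uso: float
    l_vcmax_uso: float
    l_vpd_uso: float
    L_gs: float
    L_gm: float
    L_vcmax: float
    L_g1_uso: float
    L_gm_uso: float
    L_vcmax_uso: float
    L_vpd_uso: float
    dA_over_A: float


@dataclass
class LimitationCurves:
    """Limitation states along a REW grid plus derived summaries."""

    rew_grid: np.ndarray
    states: list
    table: pd.DataFrame
    crossover_rew: Optional[float]
    rew_min: float


def relative_variation(fit: LinearPlateauFit, rew, rew_min: float = MIN_OBSERVED_REW):
    """dy/y = (y_max - y(rew)) / (y_max - y(rew_min)); 0 on the plateau, 1 at rew_min."""
    y = fit.predict(rew)
    y_extreme = fit.predict(rew_min)
    denom = fit.y_max - y_extreme
    if abs(denom) <= 1e-9 * max(abs(fit.y_max), 1e-30):
        logger.warning("%s: unresponsive over the observed range, dy/y set to 0", fit.variable)
        return np.zeros_like(np.asarray(rew, dtype=float)) if np.ndim(rew) else 0.0
    out = (fit.y_max - y) / denom
    return out if np.ndim(out) else float(out)


def assimilation_slope(v_cmax, c_c, k_m, gamma_star):
    """FvCB slope dA/dCc = Vcmax (Km + Gamma*) / (Cc + Km)^2."""
    if c_c <= -k_m:
        raise ValueError("Cc must exceed -Km")
    return v_cmax * (k_m + gamma_star) / (c_c + k_m) ** 2


def grassi_fractions(g_s, g_m, dA_dCc):
    """Stomatal / mesophyll / biochemical weights; sum to one identically."""
    if g_s <= 0 or g_m <= 0:
        raise ValueError("conductances must be positive")
    g_t = 1.0 / (1.0 / g_s + 1.0 / g_m)
    denom = g_t + dA_dCc
    l_gs = (g_t / g_s) * dA_dCc / denom
    l_gm = (g_t / g_m) * dA_dCc / denom
    l_vcmax = g_t / denom
    return l_gs, l_gm, l_vcmax


def uso_fractions(l_gs, l_gm, l_vcmax, ci_over_cs):
    """USO-scheme coefficients obtained from the Grassi weights and Ci/Cs."""
    if l_gs >= 1.0:
        raise ValueError("l_gs must be below 1")
    amp = l_gs / (1.0 - l_gs)
    l_g1_uso = amp * ci_over_cs
    l_gm_uso = l_gm / (1.0 - l_gs)
    l_vcmax_uso = l_vcmax / (1.0 - l_gs)
    l_vpd_uso = -0.5 * amp * ci_over_cs
    return l_g1_uso, l_gm_uso, l_vcmax_uso, l_vpd_uso


def grassi_contributions(rel: Dict[str, float], l_gs, l_gm, l_vcmax):
    """Contributions L = (dy/y) * l of the Grassi scheme."""
    return rel["g_s"] * l_gs, rel["g_m_25"] * l_gm, rel["v_cmax_25"] * l_vcmax


def uso_contributions(rel, l_g1_uso, l_gm_uso, l_vcmax_uso, l_vpd_uso):
    """Contributions of the USO scheme; the VPD term carries its minus sign."""
    return (
        rel["g_1"] * l_g1_uso,
        rel["g_m_25"] * l_gm_uso,
        rel["v_cmax_25"] * l_vcmax_uso,
        rel["vpd"] * l_vpd_uso,  # l_vpd_uso < 0, rel['vpd'] >= 0
    )


def stomatal_closure_decomposition(state: LimitationState):
    """Split L_gs into mesophyll/biochemical feedbacks plus VPD and g1 effects.

    Returns the four addends and the consistency residual against L_gs,
    which vanishes when dA/A is taken as the Grassi-scheme sum.
    """
    nsol_gm = state.L_gm_uso - state.L_gm
    nsol_vcmax = state.L_vcmax_uso - state.L_vcmax
    vpd_term = state.L_vpd_uso
    g1_term = state.L_g1_uso
    residual = (nsol_gm + nsol_vcmax + vpd_term + g1_term) - state.L_gs
    return {
        "nsol_gm": nsol_gm,
        "nsol_vcmax": nsol_vcmax,
        "vpd": vpd_term,
        "g1": g1_term,
        "residual": residual,
    }


def fit_vpd_rew(vpd, rew) -> VpdRewRelation:
    """OLS line VPD ~ REW; warns when the slope is not negative."""
    vpd = np.asarray(vpd, dtype=float)
    rew = np.asarray(rew, dtype=float)
    if len(vpd) < 5:
        raise ValueError("need at least 5 paired VPD/REW observations")
    res = stats.linregress(rew, vpd)
    return VpdRewRelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        sd_slope=float(res.stderr),
    )


def vpd_relative_variation(rel: VpdRewRelation, rew, rew_min: float = MIN_OBSERVED_REW):
    """dVPD/VPD under the extreme-normalized convention (positive magnitude).

    For a linear relation this reduces to (VPD(rew) - VPD(1)) /
    (VPD(rew_min) - VPD(1)) = (1 - rew) / (1 - rew_min): zero at field
    capacity, one at the driest observed REW, independent of the fitted
    coefficients.
    """
    v_top = rel.predict(1.0)
    v_ext = rel.predict(rew_min)
    denom = v_ext - v_top
    if denom == 0.0:
        return np.zeros_like(np.asarray(rew, dtype=float)) if np.ndim(rew) else 0.0
    out = (rel.predict(rew) - v_top) / denom
    return out if np.ndim(out) else float(out)


def _state_at(
    rew: float,
    fits: Dict[str, LinearPlateauFit],
    vpd_rel: VpdRewRelation,
    kin: PhotosyntheticKinetics,
    rew_min: float,
    cs: float,
) -> LimitationState:
    a_sat = float(fits["a_sat"].predict(rew))
    g_s = float(fits["g_s"].predict(rew))
    g_m = float(fits["g_m_25"].predict(rew))
    v_cmax = float(fits["v_cmax_25"].predict(rew))
    cics = float(fits["ci_over_cs"].predict(rew))
    g_1 = float(fits["g_1"].predict(rew))
    vpd = float(vpd_rel.predict(rew))

    c_i = cics * cs
    c_c = c_i - a_sat / g_m
    k_m, gamma_star = kin.km_25, kin.gamma_star_25  # curves live at 25 degC
    dA_dCc = assimilation_slope(v_cmax, c_c, k_m, gamma_star)
    l_gs, l_gm, l_vcmax = grassi_fractions(g_s, g_m, dA_dCc)
    l_g1, l_gmu, l_vcu, l_vpdu = uso_fractions(l_gs, l_gm, l_vcmax, cics)

    rel = {
        name: relative_variation(fits[name], rew, rew_min)
        for name in ("a_sat", "g_s", "g_m_25", "v_cmax_25", "g_1", "ci_over_cs")
    }
    rel["vpd"] = vpd_relative_variation(vpd_rel, rew, rew_min)

    L_gs, L_gm, L_vc = grassi_contributions(rel, l_gs, l_gm, l_vcmax)
    L_g1u, L_gmu, L_vcu, L_vpdu = uso_contributions(rel, l_g1, l_gmu, l_vcu, l_vpdu)

    g_t = 1.0 / (1.0 / g_s + 1.0 / g_m)
    return LimitationState(
        rew=rew,
        a_sat=a_sat,
        g_s=g_s,
        g_m=g_m,
        v_cmax=v_cmax,
        ci_over_cs=cics,
        g_1=g_1,
        vpd=vpd,
        c_c=c_c,
        g_t=g_t,
        dA_dCc=dA_dCc,
        rel=rel,
        l_gs=l_gs,
        l_gm=l_gm,
        l_vcmax=l_vcmax,
        l_g1_uso=l_g1,
        l_gm_uso=l_gmu,
        l_vcmax_uso=l_vcu,
        l_vpd_uso=l_vpdu,
        L_gs=L_gs,
        L_gm=L_gm,
        L_vcmax=L_vc,
        L_g1_uso=L_g1u,
        L_gm_uso=L_gmu,
        L_vcmax_uso=L_vcu,
        L_vpd_uso=L_vpdu,
        dA_over_A=rel["a_sat"],
    )


def evaluate_curves(
    fits: Dict[str, LinearPlateauFit],
    vpd_rel: VpdRewRelation = DEFAULT_VPD_REW,
    kin: PhotosyntheticKinetics = TOBACCO_CC,
    rew_min: float = MIN_OBSERVED_REW,
    cs: float = CS_CHAMBER,
    n_grid: int = 200,
    rew_grid=None,
) -> LimitationCurves:
    """Evaluate both limitation schemes along a REW grid.

    The grid defaults to ``n_grid`` uniform points on [rew_min, 1]; a grid
    reaching below the minimum observed REW is refused (the response fits
    would be extrapolated).  Normalized contributions divide each L by
    dA/A; they are NaN on the plateau where dA/A = 0.
    """
    missing = [k for k in REQUIRED_FITS if k not in fits]
    if missing:
        raise KeyError(f"missing response fits: {missing}")
    if rew_grid is None:
        rew_grid = np.linspace(rew_min, 1.0, n_grid)
    else:
        rew_grid = np.asarray(rew_grid, dtype=float)
        if rew_grid.min() < rew_min - 1e-12:
            raise ValueError("grid extends below the minimum observed REW")
    # fitted response lines from noisy data may cross zero near the dry end,
    # or imply a chloroplast CO2 below the compensation point; the
    # partitioning is undefined there, so such grid points are dropped
    pred = np.column_stack([fits[k].predict(rew_grid) for k in REQUIRED_FITS])
    valid = (pred > 0.0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc_pred = (
            fits["ci_over_cs"].predict(rew_grid) * cs
            - fits["a_sat"].predict(rew_grid) / fits["g_m_25"].predict(rew_grid)
        )
    valid &= cc_pred > kin.gamma_star_25
    if not valid.all():
        logger.warning(
            "dropping %d grid points where a fitted response is non-positive",
            int((~valid).sum()),
        )
        rew_grid = rew_grid[valid]
    if len(rew_grid) == 0:
        raise ValueError("no grid point yields positive fitted responses")
    states = [_state_at(float(r), fits, vpd_rel, kin, rew_min, cs) for r in rew_grid]

    rows = []
    for st in states:
        row = {
            "rew": st.rew,
            "a_sat": st.a_sat,
            "g_s": st.g_s,
            "g_m_25": st.g_m,
            "v_cmax_25": st.v_cmax,
            "ci_over_cs": st.ci_over_cs,
            "g_1": st.g_1,
            "vpd": st.vpd,
            "c_c": st.c_c,
            "g_t": st.g_t,
            "dA_dCc": st.dA_dCc,
            "dA_over_A": st.dA_over_A,
            "l_gs": st.l_gs,
            "l_gm": st.l_gm,
            "l_vcmax": st.l_vcmax,
            "l_g1_uso": st.l_g1_uso,
            "l_gm_uso": st.l_gm_uso,
            "l_vcmax_uso": st.l_vcmax_uso,
            "l_vpd_uso": st.l_vpd_uso,
            "L_gs": st.L_gs,
            "L_gm": st.L_gm,
            "L_vcmax": st.L_vcmax,
            "L_g1_uso": st.L_g1_uso,
            "L_gm_uso": st.L_gm_uso,
            "L_vcmax_uso": st.L_vcmax_uso,
            "L_vpd_uso": st.L_vpd_uso,
        }
        dA = st.dA_over_A
        for name in ("L_gs", "L_gm", "L_vcmax", "L_g1_uso", "L_gm_uso", "L_vcmax_uso", "L_vpd_uso"):
            row[f"{name}_norm"] = row[name] / dA if dA != 0.0 else float("nan")
        # internal consistency diagnostic: FvCB-reconstructed assimilation
        # vs the independent a_sat fit
        a_fvcb = st.v_cmax * (st.c_c - kin.gamma_star_25) / (st.c_c + kin.km_25)
        row["a_fvcb"] = a_fvcb
        row["a_consistency"] = abs(a_fvcb - st.a_sat) / st.a_sat if st.a_sat > 0 else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)

    curves = LimitationCurves(
        rew_grid=rew_grid, states=states, table=table, crossover_rew=None, rew_min=rew_min
    )
    curves.crossover_rew = crossover_rew(curves, fits, vpd_rel, kin, cs)
    return curves


def crossover_rew(
    curves: LimitationCurves,
    fits: Optional[Dict[str, LinearPlateauFit]] = None,
    vpd_rel: VpdRewRelation = DEFAULT_VPD_REW,
    kin: PhotosyntheticKinetics = TOBACCO_CC,
    cs: float = CS_CHAMBER,
) -> Optional[float]:
    """REW where the mesophyll contribution overtakes the stomatal one.

    Locates sign changes of L_gm - L_gs between bracketing grid points and
    refines by bisection on the continuous curve; the smallest crossing REW
    is returned (with a warning if several exist), None if no crossing.
    """
    diff = (curves.table["L_gm"] - curves.table["L_gs"]).to_numpy()
    grid = curves.rew_grid
    idx = np.nonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)[0]
    if len(idx) == 0:
        return None
    if len(idx) > 1:
        logger.warning("multiple L_gm/L_gs crossings; returning the smallest REW")
    i = int(idx[0])
    if fits is None:
        # fall back to linear interpolation on the grid
        x0, x1, d0, d1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
        return float(x0 - d0 * (x1 - x0) / (d1 - d0))

    def f(r):
        st = _state_at(float(r), fits, vpd_rel, kin, curves.rew_min, cs)
        return st.L_gm - st.L_gs

    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-10))


def summarize(curves: LimitationCurves) -> dict:
    """Headline numbers: crossover and normalized contributions at the driest REW."""
    st0 = curves.states[0]
    dA = st0.dA_over_A if st0.dA_over_A != 0 else float("nan")
    return {
        "rew_min": curves.rew_min,
        "crossover_rew": curves.crossover_rew,
        "normalized_at_min_rew": {
            "L_gs": st0.L_gs / dA,
            "L_gm": st0.L_gm / dA,
            "L_vcmax": st0.L_vcmax / dA,
            "L_g1_uso": st0.L_g1_uso / dA,
            "L_gm_uso": st0.L_gm_uso / dA,
            "L_vcmax_uso": st0.L_vcmax_uso / dA,
            "L_vpd_uso": st0.L_vpd_uso / dA,
        },
    }
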