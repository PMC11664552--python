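"""Synthetic drought experiments from a coupled FvCB-USO-mesophyll leaf model.

The generator forward-solves, for each measurement day, the system

    A  = Vcmax (Cc - Gamma*) / (Cc + Km)        Rubisco-limited assimilation
    Cc = Ci - A/gm                              mesophyll Fick diffusion
    gs = (1 + g1/sqrt(VPD)) A / Cs              USO stomatal closure
    Ci = Cs - A/gs                              stomatal Fick diffusion

driven by ground-truth linear-plateau curves of Vcmax25, gm25 and g1
against REW, a linear VPD-REW relation and a linear leaf-temperature-REW
relation.  The USO closure fixes Ci/Cs = g1/(g1 + sqrt(VPD)) independently
of A, so the remaining scalar equation in A is solved by safeguarded
bracketing.  Observables (fluxes, concentrations, fluorescence pairs, soil
moisture at two depths) are then emitted in the exact CSV schemas the
analysis pipeline consumes, with optional multiplicative lognormal noise;
fluorescence pairs are built by inverting the variable-J chain so that a
noise-free dataset reproduces the generating parameters exactly.

The same solver provides the central-finite-difference oracle used to
validate the USO limitation coefficients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .drought_response import LinearPlateauFit
from .kinetics import PhotosyntheticKinetics, TOBACCO_CC, denormalize_from_25
from .limitation import VpdRewRelation, DEFAULT_VPD_REW
from .presets import (
    ALPHA_BETA_PSII,
    CS_CHAMBER,
    IRRIGATED_MIN_REW,
    MIN_OBSERVED_REW,
    POTATO_RESPONSE_FITS,
    PPFD_SATURATING,
)
from .soil_water import VanGenuchtenParams, derive_wp_fc, vg_water_content

logger = logging.getLogger(__name__)

F_M_PRIME_SYNTH = 2000.0  # arbitrary fluorescence scale; only Fs/Fm' matters


class InfeasibleStateError(RuntimeError):
    """The coupled system has no positive assimilation root."""


@dataclass(frozen=True)
class CoupledLeafSolution:
    a_sat: float
    g_s: float
    c_i: float
    c_c: float
    residual: float
    iterations: int


@dataclass
class TrueResponseSet:
    """Ground-truth parameter curves driving the synthetic experiment."""

    v_cmax_25: LinearPlateauFit
    g_m_25: LinearPlateauFit
    g_1: LinearPlateauFit
    vpd_relation: VpdRewRelation = DEFAULT_VPD_REW
    t_leaf_slope: float = -10.0  # degC per REW unit (hotter when drier)
    t_leaf_intercept: float = 38.0
    c_s: float = CS_CHAMBER
    alpha_beta_true: float = ALPHA_BETA_PSII
    kinetics: PhotosyntheticKinetics = TOBACCO_CC
    vg_params: VanGenuchtenParams = field(
        default_factory=lambda: VanGenuchtenParams(
            theta_r=0.10, theta_s=0.38, alpha_vg=0.006, n_vg=1.38
        )
    )

    def t_leaf(self, rew):
        return self.t_leaf_slope * np.asarray(rew, dtype=float) + self.t_leaf_intercept

    @classmethod
    def potato_defaults(cls) -> "TrueResponseSet":
        """Continuous versions of the potato response curves.

        A real leaf responds continuously, so the intercept of each segment
        is re-derived from the continuity constraint b = y_max - a*REW_th
        (the independently rounded published intercepts leave small jumps at
        the threshold that a continuity-constrained fit could never recover).
        """
        from dataclasses import replace

        def cont(f: LinearPlateauFit) -> LinearPlateauFit:
            return replace(f, intercept_b=f.y_max - f.slope_a * f.rew_th)

        f = POTATO_RESPONSE_FITS
        return cls(v_cmax_25=cont(f["v_cmax_25"]), g_m_25=cont(f["g_m_25"]), g_1=cont(f["g_1"]))


@dataclass
class ExperimentConfig:
    """Sampling layout and noise levels of a synthetic drought experiment."""

    n_days: int = 34
    measurement_days: int = 14
    leaves_per_day_per_treatment: int = 3
    rew_start: float = 1.0
    rew_end: float = MIN_OBSERVED_REW
    rew_irrigated_min: float = IRRIGATED_MIN_REW
    #: multiplicative lognormal sigma per scatter source.  Keys naming
    #: physiological parameters (v_cmax_25, g_m_25, g_1) model leaf-to-leaf
    #: biological variability, applied to the drivers before the coupled
    #: solve so all observables of one leaf co-vary coherently; the
    #: remaining keys are independent instrument noise on the observables.
    noise: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def sigma(self, name: str) -> float:
        return float(self.noise.get(name, 0.0))


#: Scatter levels calibrated so the fitted response R^2 values match the
#: pattern reported for the field experiment (biological scatter dominates;
#: instrument noise is a few percent).
DEFAULT_NOISE = {
    "v_cmax_25": 0.19,
    "g_m_25": 0.18,
    "g_1": 0.30,
    "a_sat": 0.05,
    "g_sw": 0.07,
    "c_i": 0.02,
    "f_s": 0.01,
    "vpd_leaf": 0.05,
    "phi_co2": 0.05,
    "swc": 0.005,
}


def coupled_leaf_solve(
    v_cmax, g_m, g_1, vpd, c_s=CS_CHAMBER, kin: PhotosyntheticKinetics = TOBACCO_CC
) -> CoupledLeafSolution:
    """Solve the coupled FvCB-USO-mesophyll system for one leaf state.

    All inputs at leaf temperature (use 25 degC values with 25 degC
    constants for temperature-free work).  The USO closure gives
    Ci = Cs * g1/(g1 + sqrt(VPD)); the scalar residual in A is strictly
    decreasing, so the bracketed root is unique.
    """
    if min(v_cmax, g_m, vpd, c_s) <= 0 or g_1 < 0:
        raise InfeasibleStateError("drivers must be positive (g_1 may be zero)")
    km, gamma_star = kin.km_25, kin.gamma_star_25
    c_i = c_s * g_1 / (g_1 + np.sqrt(vpd))
    if c_i <= gamma_star:
        raise InfeasibleStateError(
            f"Ci = {c_i:.1f} at or below the compensation point {gamma_star:.1f}"
        )

    def residual(a):
        c_c = c_i - a / g_m
        return a - v_cmax * (c_c - gamma_star) / (c_c + km)

    # upper bracket: assimilation at Cc = Ci, capped where Cc would reach the
    # compensation point (the FvCB ratio has a pole at Cc = -Km below that)
    a_hi = min(
        v_cmax * (c_i - gamma_star) / (c_i + km),
        g_m * (c_i - gamma_star) * (1.0 - 1e-12),
    )
    lo, hi = 1e-12, a_hi
    if residual(hi) < 0:
        raise InfeasibleStateError("no sign change in the assimilation bracket")
    a = brentq(residual, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200)
    c_c = c_i - a / g_m
    g_s = (1.0 + g_1 / np.sqrt(vpd)) * a / c_s
    return CoupledLeafSolution(
        a_sat=float(a),
        g_s=float(g_s),
        c_i=float(c_i),
        c_c=float(c_c),
        residual=float(residual(a)),
        iterations=-1,
    )


def fick_fvcb_solve(v_cmax, g_s, g_m, c_s=CS_CHAMBER, kin: PhotosyntheticKinetics = TOBACCO_CC):
    """Solve Fick + FvCB with stomatal conductance held as an independent input.

    Used by the Grassi-scheme perturbation oracle: Cc = Cs - A/gt with
    1/gt = 1/gs + 1/gm.
    """
    km, gamma_star = kin.km_25, kin.gamma_star_25
    g_t = 1.0 / (1.0 / g_s + 1.0 / g_m)
    # quadratic in A: A^2/gt - A(Cs + Km + Vcmax/gt) + Vcmax(Cs - Gamma*) = 0
    aa = 1.0 / g_t
    bb = -(c_s + km + v_cmax / g_t)
    cc = v_cmax * (c_s - gamma_star)
    disc = bb * bb - 4 * aa * cc
    if disc < 0:
        raise InfeasibleStateError("no real assimilation root")
    a = (-bb - np.sqrt(disc)) / (2 * aa)  # smaller root is the physical one
    return float(a)


def simulate_trajectory(cfg: ExperimentConfig, truth: TrueResponseSet) -> pd.DataFrame:
    """Daily REW, VPD and leaf temperature per treatment (deterministic given seed).

    Non-irrigated REW declines linearly from rew_start to rew_end; the
    irrigated control oscillates deterministically between
    rew_irrigated_min and saturation (hand watering between readings).
    Atmospheric drivers follow the (shared) greenhouse drying trend,
    indexed on the non-irrigated REW.
    """
    days = np.arange(cfg.n_days)
    rew_dry = np.linspace(cfg.rew_start, cfg.rew_end, cfg.n_days)
    span = 1.0 - cfg.rew_irrigated_min
    rew_irr = cfg.rew_irrigated_min + span * (0.5 + 0.5 * np.cos(2.0 * np.pi * days / 7.0))
    vpd = truth.vpd_relation.predict(rew_dry)
    t_leaf = truth.t_leaf(rew_dry)
    rows = []
    for trt, rew in (("non_irrigated", rew_dry), ("irrigated", rew_irr)):
        for d in days:
            rows.append(
                {
                    "dae": int(d),
                    "treatment": trt,
                    "rew": float(rew[d]),
                    "vpd_leaf": float(vpd[d]),
                    "t_leaf": float(t_leaf[d]),
                }
            )
    return pd.DataFrame(rows)


def _measurement_days(cfg: ExperimentConfig) -> np.ndarray:
    return np.unique(np.linspace(0, cfg.n_days - 1, cfg.measurement_days).round().astype(int))


def _lognormal(rng, sigma, size=None):
    if sigma <= 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, sigma, size=size))


def jf_for_gm(a_sat, c_c, gamma_star):
    """Electron transport consistent with a given chloroplast state (variable-J inverse)."""
    return 4.0 * a_sat * (c_c + 2.0 * gamma_star) / (c_c - gamma_star)


def generate_dataset(
    cfg: ExperimentConfig,
    truth: Optional[TrueResponseSet] = None,
    out_dir: Optional[Path] = None,
) -> Dict[str, object]:
    """Generate a full synthetic experiment.

    Returns a dict with DataFrames ``gas_exchange``, ``calibration``,
    ``soil_moisture``, ``retention``, ``trajectory`` and the ``truth``
    object; writes them as CSV (+ ground_truth.json) when ``out_dir`` is
    given.  Infeasible leaf states are skipped with a log entry.
    """
    truth = truth or TrueResponseSet.potato_defaults()
    rng = np.random.default_rng(cfg.seed)
    traj = simulate_trajectory(cfg, truth)
    mdays = set(_measurement_days(cfg).tolist())
    kin = truth.kinetics

    gas_rows, truth_states = [], []
    for _, day in traj.iterrows():
        if int(day["dae"]) not in mdays:
            continue
        rew, vpd0, t_leaf0 = day["rew"], day["vpd_leaf"], day["t_leaf"]
        v25 = float(truth.v_cmax_25.predict(rew))
        gm25 = float(truth.g_m_25.predict(rew))
        g1 = float(truth.g_1.predict(rew))
        for leaf in range(cfg.leaves_per_day_per_treatment):
            vpd = vpd0 * _lognormal(rng, cfg.sigma("vpd_leaf"))
            t_leaf = t_leaf0
            # leaf-to-leaf biological scatter around the day's true curve
            v25_leaf = v25 * _lognormal(rng, cfg.sigma("v_cmax_25"))
            gm25_leaf = gm25 * _lognormal(rng, cfg.sigma("g_m_25"))
            g1_leaf = g1 * _lognormal(rng, cfg.sigma("g_1"))
            v_cmax = denormalize_from_25(v25_leaf, t_leaf, kin.ea_vcmax)
            g_m = denormalize_from_25(gm25_leaf, t_leaf, kin.ea_gm)
            km_t, gs_t = kin.at_temperature(t_leaf)
            kin_t = kin.with_(
                kc_25=km_t / (1.0 + kin.o2_mixing / kin.ko_25),
                gamma_star_25=gs_t,
                ea_kc=0.0, ea_ko=0.0, ea_gamma_star=0.0,
            )  # constants pinned at leaf temperature for the solver
            try:
                sol = coupled_leaf_solve(v_cmax, g_m, g1_leaf, vpd, truth.c_s, kin_t)
            except InfeasibleStateError as err:
                logger.info("skipping infeasible state at REW %.3f: %s", rew, err)
                continue
            j_f = jf_for_gm(sol.a_sat, sol.c_c, gs_t)
            phi = j_f / (truth.alpha_beta_true * PPFD_SATURATING)
            if not 0.0 < phi < 1.0:
                logger.info("skipping state with phi_PSII = %.3f outside (0, 1)", phi)
                continue
            f_s = F_M_PRIME_SYNTH * (1.0 - phi) * _lognormal(rng, cfg.sigma("f_s"))
            a_obs = sol.a_sat * _lognormal(rng, cfg.sigma("a_sat"))
            gsw_obs = 1.6 * sol.g_s * _lognormal(rng, cfg.sigma("g_sw"))
            # the gas analyzer derives Ci from the measured fluxes (Fick),
            # so flux noise propagates into Ci coherently
            ci_obs = (truth.c_s - 1.6 * a_obs / gsw_obs) * _lognormal(rng, cfg.sigma("c_i"))
            gas_rows.append(
                {
                    "dae": int(day["dae"]),
                    "treatment": day["treatment"],
                    "leaf_id": f"{day['treatment'][:3]}-{int(day['dae']):02d}-{leaf}",
                    "t_leaf": t_leaf,
                    "c_s": truth.c_s,
                    "c_i": ci_obs,
                    "a_sat": a_obs,
                    "g_sw": gsw_obs,
                    "vpd_leaf": vpd,
                    "ppfd": PPFD_SATURATING,
                    "f_s": min(f_s, F_M_PRIME_SYNTH),
                    "f_m_prime": F_M_PRIME_SYNTH,
                }
            )
            truth_states.append(
                {
                    "dae": int(day["dae"]),
                    "treatment": day["treatment"],
                    "rew": float(rew),
                    "v_cmax_25": v25_leaf,
                    "g_m_25": gm25_leaf,
                    "g_1": g1_leaf,
                    "a_sat": sol.a_sat,
                    "g_s": sol.g_s,
                    "c_i": sol.c_i,
                    "c_c": sol.c_c,
                }
            )
    gas = pd.DataFrame(gas_rows)

    # light-response calibration ladder under 1% O2
    cal_rows = []
    ppfd_ladder = [2000, 1500, 1200, 1000, 800, 600, 400, 200, 100, 0]
    for rep in range(3):
        for ppfd in ppfd_ladder:
            phi = 0.78 / (1.0 + ppfd / 900.0)  # declining PSII yield with light
            phi_co2 = truth.alpha_beta_true / 4.0 * phi
            a_net = phi_co2 * ppfd * _lognormal(rng, cfg.sigma("phi_co2"))
            cal_rows.append(
                {
                    "ppfd": float(ppfd),
                    "a_net": float(a_net),
                    "f_s": F_M_PRIME_SYNTH * (1.0 - phi),
                    "f_m_prime": F_M_PRIME_SYNTH,
                    "o2_fraction": 0.01,
                }
            )
    calibration = pd.DataFrame(cal_rows)

    # soil moisture consistent with the REW trajectory through the retention curve
    consts = derive_wp_fc(truth.vg_params)
    wp, fc = consts.theta_wp, consts.theta_fc  # percent
    soil_rows = []
    for _, day in traj[traj["treatment"] == "non_irrigated"].iterrows():
        theta = wp + day["rew"] * (fc - wp)
        d = 0.5 * _lognormal(rng, cfg.sigma("swc"))  # small 10/30 cm contrast
        soil_rows.append(
            {
                "time": pd.Timestamp("2020-06-04") + pd.Timedelta(days=int(day["dae"])),
                "theta_10": (theta + d) / 100.0,
                "theta_30": (theta - 2.0 * d) / 100.0,
            }
        )
    soil = pd.DataFrame(soil_rows)

    # pressure-plate retention cores sampled from the true VG curve
    pf_levels = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.7, 4.2])
    ret_rows = []
    for core in range(3):
        swc = vg_water_content(pf_levels, truth.vg_params) * _lognormal(
            rng, cfg.sigma("swc"), size=len(pf_levels)
        )
        for pf, th in zip(pf_levels, swc):
            ret_rows.append({"core_id": f"core{core + 1}", "pf": pf, "swc": float(th)})
    retention = pd.DataFrame(ret_rows)

    out = {
        "gas_exchange": gas,
        "calibration": calibration,
        "soil_moisture": soil,
        "retention": retention,
        "trajectory": traj,
        "truth": truth,
        "truth_states": pd.DataFrame(truth_states),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gas.to_csv(out_dir / "gas_exchange.csv", index=False)
        calibration.to_csv(out_dir / "calibration.csv", index=False)
        soil.to_csv(out_dir / "soil_moisture.csv", index=False)
        retention.to_csv(out_dir / "retention.csv", index=False)
        traj.to_csv(out_dir / "trajectory.csv", index=False)
        out["truth_states"].to_csv(out_dir / "truth_states.csv", index=False)
        gt = {
            name: asdict(getattr(truth, name))
            for name in ("v_cmax_25", "g_m_25", "g_1", "vg_params")
        }
        gt["vpd_relation"] = {"slope": truth.vpd_relation.slope, "intercept": truth.vpd_relation.intercept}
        gt["alpha_beta_true"] = truth.alpha_beta_true
        gt["t_leaf"] = {"slope": truth.t_leaf_slope, "intercept": truth.t_leaf_intercept}
        (out_dir / "ground_truth.json").write_text(json.dumps(gt, indent=2, default=float))
    return out


def finite_difference_limitation_oracle(
    base: Dict[str, float],
    which_driver: str,
    epsilon: float = 1e-4,
    kin: PhotosyntheticKinetics = TOBACCO_CC,
    c_s: float = CS_CHAMBER,
) -> float:
    """Log-log sensitivity (dA/A)/(dX/X) of the coupled solver to one driver.

    ``base`` maps {'v_cmax', 'g_m', 'g_1', 'vpd'} to positive values;
    ``which_driver`` names the perturbed one.  Central differences of the
    full solve, second-order accurate in epsilon.
    """
    if not 1e-6 <= epsilon <= 1e-3:
        raise ValueError("epsilon must lie in [1e-6, 1e-3]")
    if which_driver not in base:
        raise KeyError(which_driver)

    def solve(**over):
        d = dict(base)
        d.update(over)
        return coupled_leaf_solve(d["v_cmax"], d["g_m"], d["g_1"], d["vpd"], c_s, kin).a_sat

    x0 = base[which_driver]
    a_plus = solve(**{which_driver: x0 * (1.0 + epsilon)})
    a_minus = solve(**{which_driver: x0 * (1.0 - epsilon)})
    a0 = solve()
    return float((a_plus - a_minus) / (2.0 * epsilon * a0))
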