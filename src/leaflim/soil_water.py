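"""Soil water retention and the relative extractable water (REW) drought index.

Pressure-plate retention samples (pF, volumetric water content) are fitted
with the van Genuchten model; the wilting point and field capacity of the
rooted horizon are read off the fitted curve at pF 4.2 and 2.0, and
two-depth soil-moisture records are reduced to a horizon mean and rescaled
to REW in [0, 1]::

    REW = (theta_H1 - theta_wp) / (theta_fc - theta_wp)

Water contents may be given either as fractions (0-1) or percent; they are
normalized to percent internally so that printed horizon constants such as
(15.6, 35.01) can be used directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

PF_FIELD_CAPACITY = 2.0
PF_WILTING_POINT = 4.2

#: Horizon constants of the experimental plot (percent volumetric SWC).
DEFAULT_THETA_WP = 15.6
DEFAULT_THETA_FC = 35.01
DEFAULT_DEPTH_WEIGHTS = (2.0 / 3.0, 1.0 / 3.0)


class ParameterDomainError(ValueError):
    """Raised when retention parameters violate their domain."""


class RetentionFitError(RuntimeError):
    """Raised when a retention-curve fit is underdetermined or fails."""


@dataclass(frozen=True)
class VanGenuchtenParams:
    """van Genuchten retention parameters (Mualem constraint m = 1 - 1/n)."""

    theta_r: float  # residual SWC, cm3 cm-3
    theta_s: float  # saturated SWC, cm3 cm-3
    alpha_vg: float  # inverse air-entry, cm-1
    n_vg: float  # shape, > 1

    def __post_init__(self):
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ParameterDomainError(
                f"require 0 <= theta_r < theta_s <= 1, got ({self.theta_r}, {self.theta_s})"
            )
        if self.alpha_vg <= 0:
            raise ParameterDomainError("alpha_vg must be positive")
        if self.n_vg <= 1:
            raise ParameterDomainError("n_vg must exceed 1")

    @property
    def m_vg(self) -> float:
        return 1.0 - 1.0 / self.n_vg


@dataclass
class RetentionSample:
    """One pressure-plate core: paired (pF, volumetric SWC) points."""

    core_id: str
    pf: np.ndarray
    swc: np.ndarray

    def __post_init__(self):
        self.pf = np.asarray(self.pf, dtype=float)
        self.swc = np.asarray(self.swc, dtype=float)
        if self.pf.shape != self.swc.shape:
            raise ValueError("pf and swc must have equal length")
        if np.any((self.pf < 0) | (self.pf > 7)):
            raise ValueError("pF values must lie within [0, 7]")
        if np.any((self.swc <= 0) | (self.swc >= 1)):
            raise ValueError("swc values must lie within (0, 1) as fractions")


@dataclass(frozen=True)
class SoilHorizonConstants:
    """Wilting point / field capacity of the rooted horizon plus sensor weights."""

    theta_wp: float
    theta_fc: float
    depth_weights: tuple = DEFAULT_DEPTH_WEIGHTS

    def __post_init__(self):
        if not self.theta_wp < self.theta_fc:
            raise ParameterDomainError("theta_wp must be below theta_fc")
        if abs(sum(self.depth_weights) - 1.0) > 1e-9:
            raise ParameterDomainError("depth_weights must sum to 1")


def _to_percent(x):
    """Normalize SWC to percent: values <= 1 are taken as fractions."""
    x = np.asarray(x, dtype=float)
    out = np.where(x <= 1.0, x * 100.0, x)
    return out if out.ndim else float(out)


def vg_water_content(pf, params: VanGenuchtenParams):
    """Volumetric water content at suction pF (log10 of head in cm).

    theta(h) = theta_r + (theta_s - theta_r) * [1 + (alpha*h)^n]^(-m),
    strictly decreasing in pF for n > 1.
    """
    pf = np.asarray(pf, dtype=float)
    if np.any(pf < 0):
        raise ParameterDomainError("pf must be non-negative")
    head = 10.0**pf
    s_eff = (1.0 + (params.alpha_vg * head) ** params.n_vg) ** (-params.m_vg)
    out = params.theta_r + (params.theta_s - params.theta_r) * s_eff
    return out if out.ndim else float(out)


def _conditional_linear(pf, swc, alpha, n):
    """Given (alpha, n), solve the linear (theta_r, theta_s) subproblem."""
    m = 1.0 - 1.0 / n
    s = (1.0 + (alpha * 10.0**pf) ** n) ** (-m)
    design = np.column_stack([1.0 - s, s])
    coef, *_ = np.linalg.lstsq(design, swc, rcond=None)
    resid = swc - design @ coef
    return coef, float(resid @ resid)


def fit_van_genuchten(sample: RetentionSample) -> VanGenuchtenParams:
    """Least-squares van Genuchten fit of a retention sample.

    Multi-start: a log-spaced grid over (alpha, n) with the water contents
    solved linearly per node, then local refinement of the best grid node.
    Retention fitting is multi-modal, hence the grid stage.
    """
    if len(np.unique(sample.pf)) < 4:
        raise RetentionFitError(
            f"core {sample.core_id}: need >= 4 distinct pF points for a 4-parameter fit"
        )
    pf, swc = sample.pf, sample.swc

    alphas = np.logspace(-4, 0.5, 24)
    ns = 1.0 + np.logspace(-2, 1, 20)
    best = None
    for alpha in alphas:
        for n in ns:
            (tr, ts), rss = _conditional_linear(pf, swc, alpha, n)
            if not (0.0 <= tr < ts <= 1.0):
                continue
            if best is None or rss < best[0]:
                best = (rss, tr, ts, alpha, n)
    if best is None:
        raise RetentionFitError(f"core {sample.core_id}: no admissible grid start found")

    _, tr0, ts0, a0, n0 = best

    def resid(p):
        tr, ts, la, ln_n1 = p
        alpha, n = np.exp(la), 1.0 + np.exp(ln_n1)
        m = 1.0 - 1.0 / n
        s = (1.0 + (alpha * 10.0**pf) ** n) ** (-m)
        return tr + (ts - tr) * s - swc

    sol = least_squares(
        resid,
        x0=[tr0, ts0, np.log(a0), np.log(n0 - 1.0)],
        bounds=([0.0, 0.0, np.log(1e-6), np.log(1e-4)], [1.0, 1.0, np.log(10.0), np.log(50.0)]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise RetentionFitError(f"core {sample.core_id}: fit did not converge: {sol.message}")
    tr, ts, la, ln_n1 = sol.x
    if not tr < ts:
        raise RetentionFitError(f"core {sample.core_id}: degenerate fit theta_r >= theta_s")
    return VanGenuchtenParams(
        theta_r=float(tr), theta_s=float(ts), alpha_vg=float(np.exp(la)), n_vg=float(1.0 + np.exp(ln_n1))
    )


def derive_wp_fc(
    params: VanGenuchtenParams,
    depth_weights: tuple = DEFAULT_DEPTH_WEIGHTS,
) -> SoilHorizonConstants:
    """Wilting point (pF 4.2) and field capacity (pF 2.0) off the fitted curve.

    Returned in percent volumetric SWC regardless of fit units.
    """
    wp = _to_percent(vg_water_content(PF_WILTING_POINT, params))
    fc = _to_percent(vg_water_content(PF_FIELD_CAPACITY, params))
    return SoilHorizonConstants(theta_wp=wp, theta_fc=fc, depth_weights=depth_weights)


def horizon_swc(theta_10, theta_30, consts: SoilHorizonConstants):
    """Depth-weighted horizon SWC, default weights (2/3, 1/3) for (10, 30) cm."""
    w1, w2 = consts.depth_weights
    t10 = np.asarray(theta_10, dtype=float)
    t30 = np.asarray(theta_30, dtype=float)
    out = w1 * t10 + w2 * t30
    return out if out.ndim else float(out)


def compute_rew(theta_h1, consts: SoilHorizonConstants):
    """Relative extractable water, clipped to [0, 1] with a logged warning.

    Accepts the horizon SWC in fraction or percent; normalized to percent to
    match the horizon constants.
    """
    wp = _to_percent(consts.theta_wp)
    fc = _to_percent(consts.theta_fc)
    if not fc > wp:
        raise ParameterDomainError("degenerate horizon constants: theta_fc <= theta_wp")
    theta = _to_percent(theta_h1)
    rew = (theta - wp) / (fc - wp)
    if np.any(np.asarray(rew) < 0) or np.any(np.asarray(rew) > 1):
        logger.warning("REW outside [0, 1] clipped (sensor noise near saturation or wilting)")
    out = np.clip(rew, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_retention_csv(path) -> list[RetentionSample]:
    """Read retention cores from CSV with columns (core_id, pF, swc)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    samples = []
    for core_id, grp in df.groupby("core_id"):
        samples.append(
            RetentionSample(core_id=str(core_id), pf=grp["pf"].to_numpy(), swc=grp["swc"].to_numpy())
        )
    return samples


def rew_timeseries(moisture_csv, consts: SoilHorizonConstants) -> pd.DataFrame:
    """REW time series from a soil-moisture CSV (time, theta_10, theta_30)."""
    df = pd.read_csv(moisture_csv)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("theta_10", "theta_30"):
        if col not in df.columns:
            raise KeyError(f"soil-moisture CSV is missing column '{col}'")
    theta = horizon_swc(df["theta_10"].to_numpy(), df["theta_30"].to_numpy(), consts)
    out = df.copy()
    out["theta_h1"] = theta
    out["rew"] = compute_rew(theta, consts)
    return out
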