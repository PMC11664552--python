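"""Linear-plateau responses to relative extractable water and model selection.

Each derived variable y is regressed on REW with a continuous segmented
model,

    y = y_max                for REW >  REW_th
    y = a * REW + b          for REW <= REW_th,      y_max = a * REW_th + b

against a plain linear alternative.  Models are compared with the
small-sample Akaike criterion (AICc); the segmented model is retained
unless the linear one wins by at least 7 AICc units.  Drought thresholds of
different variables are compared with a z-test built from the fitted
REW_th values and their standard deviations.

Fitting strategy: the threshold is profiled over midpoints of consecutive
observed REW values (the conditionally-linear subproblem in (a, b) is
solved exactly per candidate), and the best candidate is refined by bounded
one-dimensional minimization.  Parameter SDs come from the linearized
covariance at the optimum; the SD of the derived plateau y_max = a*REW_th + b
follows by the delta method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

AICC_RULE_DELTA = 7.0


class DegenerateDesignError(ValueError):
    """All observations on one side of every admissible threshold."""


@dataclass
class LinearPlateauFit:
    """Continuous linear-plateau response of one variable to REW."""

    variable: str
    y_max: float
    slope_a: float
    intercept_b: float
    rew_th: float
    sd_y_max: float = float("nan")
    sd_a: float = float("nan")
    sd_b: float = float("nan")
    sd_rew_th: float = float("nan")
    r2: float = float("nan")
    aicc: float = float("nan")
    n_obs: int = 0
    rss: float = float("nan")
    degenerate: bool = False

    def __post_init__(self):
        # fits produced by fit_linear_plateau are continuous by construction;
        # externally supplied (e.g. published, independently rounded) parameter
        # rows may not be, and are accepted with a warning
        cont = abs(self.y_max - (self.slope_a * self.rew_th + self.intercept_b))
        if cont > 1e-8 * max(abs(self.y_max), 1e-12):
            logger.warning(
                "%s: segment does not meet the plateau at the threshold "
                "(gap %.4g); using the parameters as given",
                self.variable or "linear-plateau", cont,
            )

    @property
    def continuity_gap(self) -> float:
        return self.y_max - (self.slope_a * self.rew_th + self.intercept_b)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x > self.rew_th, self.y_max, self.slope_a * x + self.intercept_b)
        return out if out.ndim else float(out)


@dataclass
class LinearFit:
    """Ordinary least-squares line with AICc attached."""

    variable: str
    slope: float
    intercept: float
    sd_slope: float
    sd_intercept: float
    r2: float
    aicc: float
    n_obs: int
    rss: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class ModelSelection:
    aicc_segmented: float
    aicc_linear: float
    delta: float
    chosen: str
    rule_applied: str


def aicc(rss, n, k_params):
    """Small-sample corrected AIC for a Gaussian least-squares model.

    ``k_params`` counts all estimated parameters including the error
    variance.  AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1).
    """
    if n <= k_params + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k_params + 1}")
    rss = max(float(rss), 1e-300)  # guard the log for interpolating fits
    return n * math.log(rss / n) + 2 * k_params + 2 * k_params * (k_params + 1) / (n - k_params - 1)


def fit_linear(x, y, variable: str = "") -> LinearFit:
    """OLS line y ~ x with AICc (k = 3: slope, intercept, error variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return LinearFit(
        variable=variable,
        slope=float(res.slope),
        intercept=float(res.intercept),
        sd_slope=float(res.stderr),
        sd_intercept=float(res.intercept_stderr),
        r2=1.0 - rss / tss if tss > 0 else float("nan"),
        aicc=aicc(rss, n, 3),
        n_obs=n,
        rss=rss,
    )


def _profile_rss(x, y, th):
    """Exact (a, b) and RSS for a fixed threshold."""
    z = np.minimum(x, th)
    design = np.column_stack([z, np.ones_like(z)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _profile_interval_sd(x, y, rss_min, n, xs, level=0.95, n_scan=240):
    """Threshold SD proxy from the profile-likelihood interval.

    Half-width of the set {th : n ln(RSS(th)/RSS_min) <= chi2_1(level)},
    rescaled by the matching normal quantile.  Scanned on a fine grid over
    the admissible threshold range.
    """
    crit = rss_min * math.exp(stats.chi2.ppf(level, 1) / n)
    span = xs[-1] - xs[0]
    grid = np.linspace(xs[0], xs[-1] - 1e-9 * span, n_scan)
    inside = [
        t
        for t in grid
        if (xs <= t).sum() >= 2 and (xs > t).sum() >= 1 and _profile_rss(x, y, t)[1] <= crit
    ]
    if not inside:
        return 0.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(inside) - min(inside)) / (2.0 * z)


def fit_linear_plateau(x, y, variable: str = "") -> LinearPlateauFit:
    """Continuous linear-plateau least-squares fit of y against REW."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 6:
        raise ValueError("need at least 6 observations for a 3-parameter segmented fit")
    xs = np.unique(x)
    # admissible thresholds leave >= 2 distinct x at or below (slope identifiable)
    # and >= 1 above (plateau populated)
    candidates = 0.5 * (xs[1:] + xs[:-1])
    candidates = np.array(
        [c for c in candidates if (xs <= c).sum() >= 2 and (xs > c).sum() >= 1]
    )
    if len(candidates) == 0:
        raise DegenerateDesignError("observations do not straddle any admissible threshold")

    rss_prof = np.array([_profile_rss(x, y, c)[1] for c in candidates])
    i_best = int(np.argmin(rss_prof))
    lo = candidates[i_best - 1] if i_best > 0 else candidates[0]
    # when the best candidate is the last one, let the refinement approach
    # the data maximum so a pure line (plateau shrinking to one point) stays
    # inside the search space and the linear model is properly nested
    span = xs[-1] - xs[0]
    hi = candidates[i_best + 1] if i_best + 1 < len(candidates) else xs[-1] - 1e-9 * span
    if hi <= lo:
        th_best = candidates[i_best]
    else:
        sol = minimize_scalar(
            lambda t: _profile_rss(x, y, t)[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        th_best = float(sol.x)
        if _profile_rss(x, y, candidates[i_best])[1] < _profile_rss(x, y, th_best)[1]:
            th_best = float(candidates[i_best])

    (a, b), rss = _profile_rss(x, y, th_best)
    y_max = a * th_best + b
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    degenerate = False
    if abs(a) < 1e-12 * max(1.0, float(np.abs(y).max())):
        degenerate = True  # flat response: threshold unidentifiable
        logger.warning("%s: near-zero segment slope, threshold unidentifiable", variable)

    # parameter SDs: linearized (Gaussian, homoscedastic) covariance with two
    # conservative corrections for the threshold, whose sampling distribution
    # is notoriously non-Gaussian -- a heteroscedasticity-robust (HC3)
    # sandwich, and the half-width of the 95% profile-likelihood interval
    # (which widens across sampling gaps in x where the kink position is
    # only interval-identified).  The largest of the three is reported.
    below = x <= th_best
    jac = np.column_stack(
        [np.minimum(x, th_best), np.ones_like(x), np.where(below, 0.0, a)]
    )
    dof = n - 3
    sd_a = sd_b = sd_th = sd_ymax = float("nan")
    if dof > 0 and not degenerate:
        try:
            bread = np.linalg.inv(jac.T @ jac)
            cov_lin = (rss / dof) * bread
            resid = y - np.where(below, a * x + b, y_max)
            lev = np.clip(np.einsum("ij,jk,ik->i", jac, bread, jac), 0.0, 0.99)
            w = (resid / (1.0 - lev)) ** 2
            cov_hc3 = bread @ (jac.T * w) @ jac @ bread
            sd_lin = np.sqrt(np.maximum(np.diag(cov_lin), 0.0))
            sd_hc3 = np.sqrt(np.maximum(np.diag(cov_hc3), 0.0))
            sd_a, sd_b, sd_th = np.maximum(sd_lin, sd_hc3)
            sd_th = max(sd_th, _profile_interval_sd(x, y, rss, n, xs))
            grad = np.array([th_best, 1.0, a])  # delta method for y_max
            sd_ymax = float(
                np.sqrt(max(grad @ cov_lin @ grad, grad @ cov_hc3 @ grad, 0.0))
            )
        except np.linalg.LinAlgError:
            logger.warning("%s: singular design, SDs unavailable", variable)

    return LinearPlateauFit(
        variable=variable,
        y_max=float(y_max),
        slope_a=float(a),
        intercept_b=float(b),
        rew_th=float(th_best),
        sd_y_max=float(sd_ymax),
        sd_a=float(sd_a),
        sd_b=float(sd_b),
        sd_rew_th=float(sd_th),
        r2=r2,
        aicc=aicc(rss, n, 4),
        n_obs=n,
        rss=rss,
        degenerate=degenerate,
    )


def select_response_model(seg: LinearPlateauFit, lin: LinearFit) -> ModelSelection:
    """AICc-based choice: segmented unless linear wins by >= 7 units."""
    delta = seg.aicc - lin.aicc  # positive when linear is better
    if delta >= AICC_RULE_DELTA:
        chosen, rule = "linear", f"linear AICc lower by {delta:.2f} >= {AICC_RULE_DELTA}"
    else:
        chosen, rule = "segmented", (
            f"AICc difference {delta:.2f} < {AICC_RULE_DELTA}; segmented retained"
        )
    return ModelSelection(
        aicc_segmented=seg.aicc, aicc_linear=lin.aicc, delta=delta, chosen=chosen, rule_applied=rule
    )


def compare_thresholds(f1: LinearPlateauFit, f2: LinearPlateauFit, method: str = "z") -> float:
    """Two-sided p-value for the difference between two drought thresholds.

    Default: z statistic |th1 - th2| / sqrt(sd1^2 + sd2^2) against the
    standard normal.  ``method='t'`` uses a Welch-Satterthwaite t instead
    (df from the fits' residual degrees of freedom).
    """
    s1, s2 = f1.sd_rew_th, f2.sd_rew_th
    if not (s1 > 0 and s2 > 0):
        raise ValueError("threshold SDs must be positive for comparison")
    se = math.hypot(s1, s2)
    z = abs(f1.rew_th - f2.rew_th) / se
    if method == "z":
        return float(2.0 * stats.norm.sf(z))
    if method == "t":
        v1, v2 = s1**2, s2**2
        df = (v1 + v2) ** 2 / (
            v1**2 / max(f1.n_obs - 3, 1) + v2**2 / max(f2.n_obs - 3, 1)
        )
        return float(2.0 * stats.t.sf(z, df))
    raise ValueError(f"unknown method {method!r}")
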