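"""Reference response parameters for field-grown potato under soil drying.

Linear-plateau parameters (plateau y_max, segment slope a, intercept b,
threshold REW_th, with SDs and R^2) describing how light-saturated
assimilation, stomatal and mesophyll conductance, Vcmax at 25 degC, the
stomatal slope g1 and the Ci/Cs ratio of potato (cv. Agria) respond to
relative extractable water.  They let the limitation analysis run directly
from published fits when raw leaf data are unavailable, and they drive the
synthetic experiment generator as ground truth.
"""

from __future__ import annotations

import logging

from .drought_response import LinearPlateauFit

#: Lowest REW reached by the non-irrigated treatment.
MIN_OBSERVED_REW = 0.24
#: Lower bound of REW for the irrigated control.
IRRIGATED_MIN_REW = 0.83
#: Chamber CO2 at the leaf surface (umol mol-1).
CS_CHAMBER = 400.0
#: Saturating light in the chamber (umol m-2 s-1).
PPFD_SATURATING = 1200.0
#: Calibrated leaf absorptance x PSII partitioning product.
ALPHA_BETA_PSII = 0.73


def _fit(variable, y_max, a, b, rew_th, sd_y_max, sd_a, sd_b, sd_th, r2):
    # the published (y_max, a, b, rew_th) tuples are independently rounded
    # estimates and are used exactly as printed: the plateau holds above the
    # threshold, the printed segment line below it.  The resulting small
    # continuity gaps are known, so the constructor's warning is muted here.
    log = logging.getLogger("leaflim.drought_response")
    prev = log.level
    log.setLevel(logging.ERROR)
    try:
        return LinearPlateauFit(
            variable=variable,
            y_max=y_max,
            slope_a=a,
            intercept_b=b,
            rew_th=rew_th,
            sd_y_max=sd_y_max,
            sd_a=sd_a,
            sd_b=sd_b,
            sd_rew_th=sd_th,
            r2=r2,
        )
    finally:
        log.setLevel(prev)


#: variable -> LinearPlateauFit with published parameters used as printed.
POTATO_RESPONSE_FITS = {
    "a_sat": _fit("a_sat", 18.74, 35.22, -6.73, 0.72, 1.00, 8.38, 3.86, 0.08, 0.70),
    "v_cmax_25": _fit("v_cmax_25", 264.02, 1125.2, -255.2, 0.43, 11.63, 387.6, 127.9, 0.04, 0.74),
    "g_s": _fit("g_s", 0.10, 0.18, -0.03, 0.73, 0.01, 0.06, 0.03, 0.12, 0.55),
    "g_m_25": _fit("g_m_25", 0.15, 0.29, -0.06, 0.72, 0.01, 0.11, 0.05, 0.13, 0.66),
    "g_1": _fit("g_1", 1.39, -52.67, 20.15, 0.36, 0.17, 9.83, 3.06, 0.01, 0.77),
    "ci_over_cs": _fit("ci_over_cs", 0.48, -2.59, 1.43, 0.37, 0.02, 1.12, 0.35, 0.03, 0.47),
}
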