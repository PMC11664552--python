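"""Rubisco kinetic constants and Arrhenius temperature responses.

At light saturation, C3 assimilation is Rubisco-limited and follows

    A = Vcmax * (Cc - gamma_star) / (Cc + Km),     Km = Kc * (1 + O / Ko)

where ``Cc`` is the chloroplastic CO2 mixing ratio, ``gamma_star`` the
photorespiratory compensation point and ``Km`` the effective
Michaelis-Menten constant of Rubisco in the presence of oxygen.

Two tobacco-calibrated constant sets are provided: a chloroplast-based
(``Cc``) set, the default, and an intercellular-based (``Ci``) set.  Both
carry activation energies for the Arrhenius scaling

    f(T) = exp[ Ea * (T - 298.15) / (298.15 * R * T) ]

which equals 1 at 25 degC.  Leaf respiration ``r_d`` defaults to zero
(negligible against light-saturated assimilation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

R_GAS = 8.314  # J mol-1 K-1
T_REF = 298.15  # K (25 degC)


def arrhenius_factor(t_leaf_c, activation_energy_kj):
    """Arrhenius scaling factor relative to 25 degC.

    Parameters
    ----------
    t_leaf_c : float or array
        Leaf temperature in degrees Celsius.
    activation_energy_kj : float
        Activation energy in kJ mol-1.
    """
    t_k = np.asarray(t_leaf_c, dtype=float) + 273.15
    ea = activation_energy_kj * 1000.0
    out = np.exp(ea * (t_k - T_REF) / (T_REF * R_GAS * t_k))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PhotosyntheticKinetics:
    """Rubisco kinetic constants at 25 degC with activation energies.

    Units: kc_25 umol mol-1; ko_25 and o2_mixing mmol mol-1;
    gamma_star_25 umol mol-1; activation energies kJ mol-1;
    r_d umol m-2 s-1.
    """

    kc_25: float
    ko_25: float
    gamma_star_25: float
    o2_mixing: float = 210.0
    ea_kc: float = 80.99
    ea_ko: float = 23.72
    ea_gamma_star: float = 24.46
    ea_vcmax: float = 65.33
    ea_gm: float = 49.6
    r_d: float = 0.0

    def __post_init__(self):
        for name in ("kc_25", "ko_25", "gamma_star_25", "o2_mixing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_d < 0:
            raise ValueError("r_d must be non-negative")

    @property
    def km_25(self) -> float:
        """Effective Michaelis-Menten constant at 25 degC (umol mol-1)."""
        return self.kc_25 * (1.0 + self.o2_mixing / self.ko_25)

    def at_temperature(self, t_leaf_c):
        """Return (km, gamma_star) at leaf temperature via Arrhenius scaling."""
        if np.any(np.asarray(t_leaf_c) < 0.0) or np.any(np.asarray(t_leaf_c) > 50.0):
            raise ValueError("t_leaf outside the supported 0-50 degC range")
        kc = self.kc_25 * arrhenius_factor(t_leaf_c, self.ea_kc)
        ko = self.ko_25 * arrhenius_factor(t_leaf_c, self.ea_ko)
        gamma_star = self.gamma_star_25 * arrhenius_factor(t_leaf_c, self.ea_gamma_star)
        km = kc * (1.0 + self.o2_mixing / ko)
        return km, gamma_star

    def with_(self, **kwargs) -> "PhotosyntheticKinetics":
        return replace(self, **kwargs)


#: Chloroplast-CO2-based tobacco constants (default basis).
TOBACCO_CC = PhotosyntheticKinetics(kc_25=272.38, ko_25=165.82, gamma_star_25=37.43)

#: Intercellular-CO2-based tobacco constants (alternative basis).
TOBACCO_CI = PhotosyntheticKinetics(
    kc_25=404.9,
    ko_25=278.4,
    gamma_star_25=42.75,
    ea_kc=79.43,
    ea_ko=36.38,
    ea_gamma_star=37.83,
)

KINETICS_PRESETS = {"cc": TOBACCO_CC, "ci": TOBACCO_CI}


def kinetics_at(t_leaf_c, kin: PhotosyntheticKinetics):
    """(Km, gamma_star) at leaf temperature; functional alias."""
    return kin.at_temperature(t_leaf_c)


def normalize_to_25(value, t_leaf_c, activation_energy_kj):
    """Rescale a rate measured at ``t_leaf_c`` to its 25 degC equivalent."""
    return value / arrhenius_factor(t_leaf_c, activation_energy_kj)


def denormalize_from_25(value_25, t_leaf_c, activation_energy_kj):
    """Inverse of :func:`normalize_to_25`."""
    return value_25 * arrhenius_factor(t_leaf_c, activation_energy_kj)
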