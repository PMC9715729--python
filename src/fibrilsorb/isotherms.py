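"""Vapour-sorption isotherm models and humidity-state arithmetic.

Two published composite isotherms for nanocellulose films are
implemented verbatim, as an explicit ``variant`` argument ("park" for
the Belbekhouche parameterization of the Park model, "hakalahti" for the
TEMPO-CNF variant).  Each sums up to three terms in the water activity
a = %RH/100:

    park:       F_L = A_L B_L a / (1 + B_L a)    (a < 0.1)
                F_H = K_H a                      (0.1 - 0.6)
                F_C = K_C n a^n                  (a > 0.6)
    hakalahti:  F_L = A_L a / (1 + B_L a)        (a < 0.05)
                ln a = ln F_FH + (1-F_FH) + chi (1-F_FH)^2   (0.3 - 0.7)
                F_C = K_C a^n                    (a > 0.7)

The two printed Langmuir/clustering forms differ between the sources and
both are kept as printed; no variant is a silent default.  Model outputs
are treated as dimensionless uptake values (the sources state no units).

Humidity states: partial pressure p = p_sat * RH/100 and absolute
humidity rho = p / (R_v T_K) with R_v = 461.5 J/(kg K); saturation
pressures are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import KELVIN_OFFSET, R_VAPOUR

__all__ = [
    "ParkParams",
    "HakalahtiParams",
    "HumidityState",
    "PARK_DEFAULTS",
    "HAKALAHTI_DEFAULTS",
    "STATE_A",
    "STATE_B",
    "langmuir_fraction",
    "henry_fraction",
    "clustering_fraction",
    "flory_huggins_fraction",
    "flory_huggins_residual",
    "composite_isotherm",
    "absolute_humidity",
]


def _check_activity(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError(f"water activity must lie in [0, 1], got {a}")
    return a


@dataclass(frozen=True)
class ParkParams:
    """Park-model parameters (Belbekhouche parameterization)."""

    A_L: float = 1.0  # Langmuir capacity constant
    B_L: float = 200.0  # Langmuir affinity constant
    K_H: float = 13.7  # Henry solubility coefficient
    K_C: float = 18.2  # water-clustering equilibrium constant
    n: int = 11  # water molecules per cluster

    def __post_init__(self) -> None:
        if min(self.A_L, self.B_L, self.K_H, self.K_C) < 0:
            raise ValueError("Park parameters must be non-negative")
        if self.n < 1:
            raise ValueError(f"cluster size n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class HakalahtiParams:
    """TEMPO-CNF variant: Langmuir + Flory-Huggins + clustering.

    K_C was not stated in the source and is therefore a required
    argument with no default.
    """

    K_C: float
    A_L: float = 1.41
    B_L: float = 223.0
    chi: float = 0.67  # Flory-Huggins interaction parameter
    n: int = 10

    def __post_init__(self) -> None:
        if self.B_L <= 0:
            raise ValueError(f"B_L must be > 0, got {self.B_L}")
        if self.n < 1:
            raise ValueError(f"cluster size n must be >= 1, got {self.n}")
        for v in (self.A_L, self.K_C, self.chi):
            if not np.isfinite(v):
                raise ValueError("Hakalahti parameters must be finite")


PARK_DEFAULTS = ParkParams()
#: regime bounds in %RH as printed: (langmuir_upper, mid_lo, mid_hi, clustering_lower)
PARK_REGIMES = (10.0, 10.0, 60.0, 60.0)
HAKALAHTI_REGIMES = (5.0, 30.0, 70.0, 70.0)


def HAKALAHTI_DEFAULTS(K_C: float) -> HakalahtiParams:
    return HakalahtiParams(K_C=K_C)


def langmuir_fraction(a, params, variant: str):
    """Monolayer fraction F_L; the two printed forms differ and both are kept."""
    a = _check_activity(a)
    if variant == "park":
        out = params.A_L * params.B_L * a / (1.0 + params.B_L * a)
    elif variant == "hakalahti":
        out = params.A_L * a / (1.0 + params.B_L * a)
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'park' or 'hakalahti'")
    return out if out.ndim else float(out)


def henry_fraction(a, K_H: float):
    """Henry's-law fraction F_H = K_H a."""
    a = _check_activity(a)
    out = K_H * a
    return out if out.ndim else float(out)


def clustering_fraction(a, params, variant: str):
    """Water-clustering fraction: K_C n a^n (park) or K_C a^n (hakalahti)."""
    a = _check_activity(a)
    if variant == "park":
        out = params.K_C * params.n * a**params.n
    elif variant == "hakalahti":
        out = params.K_C * a**params.n
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'park' or 'hakalahti'")
    return out if out.ndim else float(out)


_EPS = 1e-12


def flory_huggins_residual(F: float, a: float, chi: float) -> float:
    """Residual of ln a = ln F + (1-F) + chi (1-F)^2."""
    return np.log(a) - (np.log(F) + (1.0 - F) + chi * (1.0 - F) ** 2)


def flory_huggins_fraction(a: float, chi: float) -> float:
    """Solve the implicit Flory-Huggins activity equation for F in (0, 1).

    Bracketed root-finding on (eps, 1-eps) with eps = 1e-12; the root is
    located to 1e-10 in F.  For a = 1 the exact solution F = 1 is
    returned.  Raises if the bracket shows no sign change (reporting the
    endpoint residuals).
    """
    if not 0.0 < a <= 1.0:
        raise ValueError(f"water activity must lie in (0, 1], got {a}")
    if a == 1.0:
        return 1.0
    lo, hi = _EPS, 1.0 - _EPS
    r_lo = flory_huggins_residual(lo, a, chi)
    r_hi = flory_huggins_residual(hi, a, chi)
    if np.sign(r_lo) == np.sign(r_hi):
        raise ValueError(
            f"no sign change on bracket ({lo}, {hi}): residuals {r_lo:.3e} and {r_hi:.3e}"
        )
    # xtol well below the 1e-10 contract: near small roots the residual's
    # slope is ~1/F, so slack in F inflates the residual proportionally
    return float(
        brentq(flory_huggins_residual, lo, hi, args=(a, chi), xtol=1e-14, rtol=8.9e-16)
    )


def composite_isotherm(
    a_grid,
    params,
    variant: str,
    regime_bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Evaluate all terms of a composite isotherm over an activity grid.

    Returns a DataFrame with columns a, F_L, F_mid (F_H for park, F_FH
    for hakalahti), F_C and the dominant-regime tag from the printed %RH
    bounds; activities falling between printed regimes are tagged
    'unspecified'.
    """
    a_grid = np.atleast_1d(_check_activity(a_grid))
    if regime_bounds is None:
        regime_bounds = PARK_REGIMES if variant == "park" else HAKALAHTI_REGIMES
    lang_hi, mid_lo, mid_hi, clus_lo = (b / 100.0 for b in regime_bounds)

    f_l = np.atleast_1d(langmuir_fraction(a_grid, params, variant))
    f_c = np.atleast_1d(clustering_fraction(a_grid, params, variant))
    if variant == "park":
        f_mid = np.atleast_1d(henry_fraction(a_grid, params.K_H))
        mid_name = "henry"
    else:
        f_mid = np.array([flory_huggins_fraction(a, params.chi) if a > 0 else np.nan for a in a_grid])
        mid_name = "flory-huggins"

    regime = np.full(len(a_grid), "unspecified", dtype=object)
    regime[a_grid < lang_hi] = "langmuir"
    regime[(a_grid >= mid_lo) & (a_grid <= mid_hi)] = mid_name
    regime[a_grid > clus_lo] = "clustering"
    return pd.DataFrame(
        {"a": a_grid, "F_L": f_l, "F_mid": f_mid, "F_C": f_c, "regime": regime}
    )


@dataclass(frozen=True)
class HumidityState:
    """A conditioning environment: temperature, %RH and saturation pressure."""

    temperature: float  # deg C
    rh: float  # percent
    saturation_pressure: float  # kPa (input; no saturation correlation here)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 100.0:
            raise ValueError(f"relative humidity must be in [0, 100] %, got {self.rh}")
        if self.temperature <= -KELVIN_OFFSET:
            raise ValueError(f"temperature below absolute zero: {self.temperature} C")
        if self.saturation_pressure < 0:
            raise ValueError(f"negative saturation pressure: {self.saturation_pressure}")

    @property
    def partial_pressure(self) -> float:
        """Water vapour partial pressure, kPa."""
        return self.saturation_pressure * self.rh / 100.0


#: 25 C / 80 %RH and 39 C / 36 %RH conditioning states sharing ~0.018 kg/m^3
STATE_A = HumidityState(temperature=25.0, rh=80.0, saturation_pressure=3.169)
STATE_B = HumidityState(temperature=39.0, rh=36.0, saturation_pressure=6.9969)


def absolute_humidity(state: HumidityState) -> float:
    """Water vapour mass density rho = p / (R_v T_K), kg/m^3."""
    p_pa = state.partial_pressure * 1000.0
    return p_pa / (R_VAPOUR * (state.temperature + KELVIN_OFFSET))
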