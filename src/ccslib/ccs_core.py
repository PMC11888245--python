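"""Drift-tube IMS physics: Mason-Schamp conversion and single-field calibration.

A drift-tube ion mobility spectrometer separates ions in a uniform weak
electric field through a neutral buffer gas (nitrogen here); the arrival
time encodes the reduced mobility K0, which the Mason-Schamp equation maps
to a collision cross section (CCS, Angstrom^2):

    Omega = (3 z e) / (16 N0) * sqrt(2 pi / (mu kB T)) * 1 / K0

with N0 the buffer-gas number density at standard conditions and
mu = m M / (m + M) the ion/gas reduced mass.

The *single-field* calibration bypasses absolute physics: calibrant ions
with accepted reference CCS values give a linear relation

    t_A = beta * (gamma * Omega) + t_fix,     gamma = sqrt(mu) / z

whose slope ``beta`` (ms per Angstrom^2 sqrt(Da)) and dead-time intercept
``t_fix`` (ms) then convert unknown arrival times to CCS.  Because the
calibration transfers reference CCS values rather than absolute constants,
calibrated CCS does not depend directly on the (unstated) drift-gas
temperature; a configurable default of 298.15 K is kept for the direct
Mason-Schamp route.

Units throughout: time ms, CCS Angstrom^2, mass Da, mobility cm^2 V^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import (
    ATOMIC_MASS_UNIT,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    LOSCHMIDT,
    NITROGEN_GAS_MASS,
)

__all__ = [
    "DriftConditions",
    "CalibrantIon",
    "SingleFieldCalibration",
    "reduced_mass",
    "mobility_to_ccs",
    "fit_single_field",
    "drift_to_ccs",
    "ccs_to_drift",
]


@dataclass(frozen=True)
class DriftConditions:
    """Instrument drift-cell conditions (defaults: 78.24 cm tube, ~3.95 torr
    N2, 17 V/cm; temperature defaults to 298.15 K and is configurable)."""

    drift_length_cm: float = 78.24
    pressure_torr: float = 3.95
    temperature_k: float = 298.15
    field_v_per_cm: float = 17.0
    gas_mass_da: float = NITROGEN_GAS_MASS

    def __post_init__(self) -> None:
        for name in (
            "drift_length_cm",
            "pressure_torr",
            "temperature_k",
            "field_v_per_cm",
            "gas_mass_da",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CalibrantIon:
    """A tune-mix ion: m/z, charge, accepted reference CCS and measured
    arrival time."""

    mz: float
    z: int
    reference_ccs: float  # Angstrom^2
    t_a: float            # ms

    def __post_init__(self) -> None:
        if self.reference_ccs <= 0:
            raise ValueError("reference_ccs must be positive")
        if self.t_a <= 0:
            raise ValueError("arrival time must be positive")
        if self.z == 0:
            raise ValueError("charge must be nonzero")


@dataclass(frozen=True)
class SingleFieldCalibration:
    """Fitted single-field line t_A = beta * gamma * Omega + t_fix."""

    beta: float      # ms per (Angstrom^2 sqrt(Da))
    t_fix: float     # ms
    r_squared: float
    n_calibrants: int
    gas_mass_da: float = NITROGEN_GAS_MASS

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_calibrants < 2:
            raise ValueError("need at least 2 calibrants")


def reduced_mass(ion_mass: float, gas_mass: float = NITROGEN_GAS_MASS) -> float:
    """Two-body reduced mass mu = m M / (m + M), Da."""
    if ion_mass <= 0 or gas_mass <= 0:
        raise ValueError("masses must be strictly positive")
    return ion_mass * gas_mass / (ion_mass + gas_mass)


def mobility_to_ccs(k0: float, z: int, mu: float, temperature_k: float = 298.15) -> float:
    """Mason-Schamp conversion from reduced mobility to CCS.

    Parameters
    ----------
    k0
        Reduced mobility, cm^2 V^-1 s^-1 (normalised to 273.15 K, 760 torr).
    z
        Charge state (sign ignored).
    mu
        Ion/buffer-gas reduced mass, Da.
    temperature_k
        Drift-gas temperature, K.

    Returns
    -------
    float
        CCS in Angstrom^2.
    """
    if k0 <= 0 or mu <= 0 or temperature_k <= 0:
        raise ValueError("k0, mu and temperature must be strictly positive")
    mu_kg = mu * ATOMIC_MASS_UNIT
    k0_si = k0 * 1e-4  # cm^2/Vs -> m^2/Vs
    omega_m2 = (
        (3.0 * abs(z) * ELEMENTARY_CHARGE)
        / (16.0 * LOSCHMIDT)
        * math.sqrt(2.0 * math.pi / (mu_kg * BOLTZMANN * temperature_k))
        / k0_si
    )
    return omega_m2 * 1e20  # m^2 -> Angstrom^2


def _gamma(ion_mass: float, z: int, gas_mass: float) -> float:
    return math.sqrt(reduced_mass(ion_mass, gas_mass)) / abs(z)


def fit_single_field(
    calibrants: Sequence[CalibrantIon],
    gas_mass: float = NITROGEN_GAS_MASS,
) -> SingleFieldCalibration:
    """Ordinary least-squares fit of arrival time against gamma * reference CCS.

    Requires >= 2 calibrants with distinct gamma*Omega abscissae; the result
    is invariant to calibrant ordering.
    """
    if len(calibrants) < 2:
        raise ValueError("need at least 2 calibrants")
    x = np.array(
        [_gamma(c.mz * abs(c.z), c.z, gas_mass) * c.reference_ccs for c in calibrants]
    )
    y = np.array([c.t_a for c in calibrants])
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibrant design: all gamma*CCS equal")
    beta, t_fix = np.polyfit(x, y, 1)
    resid = y - (beta * x + t_fix)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return SingleFieldCalibration(
        beta=float(beta),
        t_fix=float(t_fix),
        r_squared=min(max(r2, 0.0), 1.0),
        n_calibrants=len(calibrants),
        gas_mass_da=gas_mass,
    )


def drift_to_ccs(
    t_a: float,
    ion_mass: float,
    z: int,
    cal: SingleFieldCalibration,
    gas_mass: float | None = None,
) -> float:
    """Convert an arrival time to CCS: Omega = (t_A - t_fix) / (beta gamma)."""
    gas = cal.gas_mass_da if gas_mass is None else gas_mass
    if t_a <= cal.t_fix:
        raise ValueError(
            f"arrival time {t_a} ms is not above the dead time {cal.t_fix} ms"
        )
    return (t_a - cal.t_fix) / (cal.beta * _gamma(ion_mass, z, gas))


def ccs_to_drift(
    ccs: float,
    ion_mass: float,
    z: int,
    cal: SingleFieldCalibration,
    gas_mass: float | None = None,
) -> float:
    """Forward single-field model: t_A = beta gamma Omega + t_fix."""
    gas = cal.gas_mass_da if gas_mass is None else gas_mass
    if ccs <= 0:
        raise ValueError("ccs must be strictly positive")
    return cal.beta * _gamma(ion_mass, z, gas) * ccs + cal.t_fix
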