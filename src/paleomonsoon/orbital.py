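"""Orbital elements and daily-mean top-of-atmosphere insolation.

Elements come from a truncated trigonometric (Berger-1978-class) solution
valid over the last million years; insolation follows the standard
daily-mean formula

    W = S0/pi * (a/r)^2 * (H0 sin(phi) sin(delta) + cos(phi) cos(delta) sin(H0))

with declination from sin(delta) = sin(obliquity) sin(solar_longitude) and
the Kepler distance factor from the true anomaly relative to perihelion.
"June 21" forcing series are computed at solar longitude 90 deg (the
angular definition of the northern summer solstice), which avoids the
calendar-drift ambiguity of fixed calendar days in deep time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _berger1978 as _b78
from .records import ForcingSeries

MAX_AGE_KA = 1000.0
DEFAULT_SOLAR_CONSTANT = 1365.0  # W/m2; not uniquely defined by observations


@dataclass
class OrbitalElements:
    """Orbital configuration at one age (ka before present)."""

    age: float
    eccentricity: float
    obliquity: float  # degrees
    longitude_of_perihelion: float  # degrees from moving vernal equinox

    @property
    def climatic_precession(self) -> float:
        """e * sin(longitude of perihelion) — the precession index."""
        return self.eccentricity * np.sin(np.deg2rad(self.longitude_of_perihelion))


@dataclass
class InsolationSpec:
    """Where and when (in the seasonal cycle) insolation is evaluated."""

    latitude: float  # degrees N, negative = S
    solar_longitude: float = 90.0  # 0 = NH spring equinox, 90 = NH summer solstice
    solar_constant: float = DEFAULT_SOLAR_CONSTANT

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not 0.0 <= self.solar_longitude < 360.0:
            raise ValueError(
                f"solar_longitude {self.solar_longitude} outside [0, 360)")


def _check_ages(ages: np.ndarray) -> np.ndarray:
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(ages < 0.0) or np.any(ages > MAX_AGE_KA):
        raise ValueError(
            f"age outside the orbital-solution validity window [0, {MAX_AGE_KA:g}] ka")
    return ages


def orbital_elements(age: float) -> OrbitalElements:
    """Orbital elements at ``age`` ka before present (valid 0-1000 ka)."""
    ages = _check_ages(age)
    t_years = -ages * 1000.0
    ecc, _ = _b78.eccentricity_and_fixed_perihelion(t_years)
    return OrbitalElements(
        age=float(ages[0]),
        eccentricity=float(ecc[0]),
        obliquity=float(_b78.obliquity_deg(t_years)[0]),
        longitude_of_perihelion=float(_b78.longitude_of_perihelion_deg(t_years)[0]),
    )


def orbital_element_series(ages) -> dict[str, np.ndarray]:
    """Vectorized elements over an age grid (ka). Returns arrays keyed by name."""
    ages = _check_ages(ages)
    t_years = -ages * 1000.0
    ecc, _ = _b78.eccentricity_and_fixed_perihelion(t_years)
    omega = _b78.longitude_of_perihelion_deg(t_years)
    return {
        "age": ages,
        "eccentricity": ecc,
        "obliquity": _b78.obliquity_deg(t_years),
        "longitude_of_perihelion": omega,
        "climatic_precession": ecc * np.sin(np.deg2rad(omega)),
    }


def _daily_mean(ecc, obliquity_deg, omega_deg, lat_deg, solar_long_deg, s0):
    """Vectorized daily-mean insolation (W/m2)."""
    phi = np.deg2rad(lat_deg)
    lam = np.deg2rad(solar_long_deg)
    eps = np.deg2rad(obliquity_deg)

    sin_delta = np.sin(eps) * np.sin(lam)
    delta = np.arcsin(np.clip(sin_delta, -1.0, 1.0))

    # hour angle of sunrise/sunset; clip handles polar day/night
    cos_h0 = -np.tan(phi) * np.tan(delta)
    h0 = np.arccos(np.clip(cos_h0, -1.0, 1.0))

    # Kepler distance factor: true anomaly measured from perihelion
    nu = lam - np.deg2rad(omega_deg)
    dist2 = ((1.0 + ecc * np.cos(nu)) / (1.0 - ecc**2)) ** 2

    w = (s0 / np.pi) * dist2 * (
        h0 * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(h0))
    return np.maximum(w, 0.0)


def daily_mean_insolation(elements: OrbitalElements, spec: InsolationSpec) -> float:
    """Daily-mean TOA insolation (W/m2) for one orbital configuration.

    Zero in polar night (sun never rises), and symmetric about the equator
    at the equinoxes.
    """
    return float(_daily_mean(
        elements.eccentricity, elements.obliquity,
        elements.longitude_of_perihelion,
        spec.latitude, spec.solar_longitude, spec.solar_constant))


def forcing_series(ages, spec: InsolationSpec,
                   label: str | None = None) -> ForcingSeries:
    """Insolation time series at ``spec`` over an age grid (ka)."""
    ages = _check_ages(ages)
    el = orbital_element_series(ages)
    values = _daily_mean(el["eccentricity"], el["obliquity"],
                         el["longitude_of_perihelion"],
                         spec.latitude, spec.solar_longitude, spec.solar_constant)
    if label is None:
        label = f"insolation_{spec.latitude:g}N_ls{spec.solar_longitude:g}"
    return ForcingSeries(ages, values, label=label)


def hemispheric_gradient(ages, lat_a: float, lat_b: float,
                         solar_longitude: float = 90.0,
                         solar_constant: float = DEFAULT_SOLAR_CONSTANT) -> ForcingSeries:
    """Insolation difference series lat_a minus lat_b (W/m2)."""
    if lat_a == lat_b:
        raise ValueError("gradient requires two distinct latitudes")
    a = forcing_series(ages, InsolationSpec(lat_a, solar_longitude, solar_constant))
    b = forcing_series(ages, InsolationSpec(lat_b, solar_longitude, solar_constant))
    return ForcingSeries(a.ages, a.values - b.values,
                         label=f"gradient_{lat_a:g}N_minus_{lat_b:g}N_ls{solar_longitude:g}")


def normalize_01(series: ForcingSeries) -> ForcingSeries:
    """Affine rescale of a series to [0, 1]; preserves all correlations."""
    lo, hi = series.values.min(), series.values.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant series")
    return ForcingSeries(series.ages, (series.values - lo) / (hi - lo),
                         label=f"{series.label}_norm01")
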