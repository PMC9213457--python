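"""Plant-wax isotope interpretation: C4 fraction, landscape fractionation,
ice-volume correction, and precipitation hydrogen isotopes.

The chain, in fixed order:

1. f_C4 = (d13C_meas - d13C_C3) / (d13C_C4 - d13C_C3)          (linear mixing)
2. eps_landscape = (1 - f_C4) * eps_C3 + f_C4 * eps_C4          (abundance-weighted)
3. dD_wax,IVC = (1 + dD_wax) / (1 + dD_sw) - 1                  (ice-volume correction)
4. dD_precip = (1 + dD_wax,IVC) / (1 + eps_landscape) - 1       (remove biosynthesis)

All per-mil quantities are converted to fractional units (x / 1000) before
the "+1" algebra, which is only valid in fractional form; inputs and
outputs stay in per mil.  dD_sw is the seawater deuterium anomaly obtained
by scaling a benthic d18O stack so the Last Glacial Maximum anomaly is
1 permil and multiplying by the global-meteoric-water-line slope (8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ProxyRecord


class FcFourClipWarning(UserWarning):
    """Raised when measured d13C falls outside the C3/C4 end members."""


@dataclass
class WaxSample:
    """One horizon's C31 n-alkane isotope measurements."""

    age: float           # ka
    d13C: float          # permil VPDB
    d13C_sigma: float    # permil, 1 sigma
    dD: float            # permil VSMOW
    dD_sigma: float      # permil, 1 sigma

    def __post_init__(self):
        if not -40.0 <= self.d13C <= -10.0:
            raise ValueError(f"d13C={self.d13C} outside plausible plant-wax band")
        if not -250.0 <= self.dD <= -80.0:
            raise ValueError(f"dD={self.dD} outside plausible plant-wax band")
        if self.d13C_sigma < 0 or self.dD_sigma < 0:
            raise ValueError("sigmas must be nonnegative")


@dataclass
class MixingEndMembers:
    """C31 n-alkane d13C end members for African C3 and C4 vegetation."""

    d13C_C3: float = -33.6
    d13C_C4: float = -19.9
    d13C_C3_sigma: float = 0.0
    d13C_C4_sigma: float = 0.0

    def __post_init__(self):
        if not self.d13C_C4 > self.d13C_C3:
            raise ValueError("C4 end member must be heavier (less negative) than C3")


@dataclass
class FractionationParams:
    """Apparent (precipitation -> wax) hydrogen fractionations, permil.

    No literature defaults are baked in: values for C3 angiosperm trees and
    C4 grasses must be supplied from a fractionation compilation.
    """

    eps_C3: float
    eps_C4: float
    eps_C3_sigma: float = 0.0
    eps_C4_sigma: float = 0.0

    def __post_init__(self):
        for name, v in (("eps_C3", self.eps_C3), ("eps_C4", self.eps_C4)):
            if v is None:
                raise ValueError(f"{name} must be configured explicitly")
            if v >= 0:
                raise ValueError(f"{name} must be negative (waxes are D-depleted)")
            if v <= -1000.0:
                raise ValueError(f"{name} <= -1000 permil is unphysical")


@dataclass
class SeawaterCorrection:
    """Scaled seawater d18O anomaly series for the ice-volume correction."""

    ages: np.ndarray          # ka
    d18O_sw: np.ndarray       # permil, LGM anomaly scaled to 1
    gmwl_slope: float = 8.0   # dD : d18O in modern precipitation

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.d18O_sw = np.asarray(self.d18O_sw, dtype=float)
        if self.ages.shape != self.d18O_sw.shape:
            raise ValueError("ages and d18O_sw must have equal length")
        if self.gmwl_slope <= 0:
            raise ValueError("GMWL slope must be positive")

    def d18O_at(self, age) -> np.ndarray:
        a = np.atleast_1d(np.asarray(age, dtype=float))
        if np.any(a < self.ages.min()) or np.any(a > self.ages.max()):
            raise ValueError("age outside the seawater-correction series span")
        return np.interp(a, self.ages, self.d18O_sw)

    def dD_sw_at(self, age) -> np.ndarray:
        """Seawater dD anomaly (permil) at age, via the GMWL slope."""
        return self.gmwl_slope * self.d18O_at(age)


# ---------------------------------------------------------------------------

def f_c4(d13C_meas, em: MixingEndMembers, clip: bool = True):
    """C4 fraction from the two-end-member d13C mixing model.

    Values outside [0, 1] (measurement noise can exceed the end members)
    are clipped with a warning when ``clip`` is true.
    """
    f = (np.asarray(d13C_meas, dtype=float) - em.d13C_C3) / (em.d13C_C4 - em.d13C_C3)
    if clip:
        out_of_range = (f < 0) | (f > 1)
        if np.any(out_of_range):
            warnings.warn(
                f"{int(np.sum(out_of_range))} f_C4 value(s) outside [0, 1] "
                "clipped to the end members", FcFourClipWarning, stacklevel=2)
        f = np.clip(f, 0.0, 1.0)
    return f if np.ndim(d13C_meas) else float(f)


def epsilon_landscape(f_c4_value, fp: FractionationParams):
    """Landscape apparent fractionation (permil), C3/C4 abundance-weighted."""
    f = np.asarray(f_c4_value, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f_c4 must lie in [0, 1]")
    out = (1.0 - f) * fp.eps_C3 + f * fp.eps_C4
    return out if np.ndim(f_c4_value) else float(out)


def ice_volume_correct(dD_wax, age, sw: SeawaterCorrection):
    """Remove the seawater (ice-volume) dD anomaly from measured wax dD."""
    dsw = sw.dD_sw_at(age) / 1000.0
    dw = np.asarray(dD_wax, dtype=float) / 1000.0
    out = 1000.0 * ((1.0 + dw) / (1.0 + dsw) - 1.0)
    return out if (np.ndim(dD_wax) or np.ndim(age)) else float(out[0])


def uncorrect_ice_volume(dD_wax_ivc, age, sw: SeawaterCorrection):
    """Inverse of :func:`ice_volume_correct` (used by the synthetic generator)."""
    dsw = sw.dD_sw_at(age) / 1000.0
    di = np.asarray(dD_wax_ivc, dtype=float) / 1000.0
    out = 1000.0 * ((1.0 + di) * (1.0 + dsw) - 1.0)
    return out if (np.ndim(dD_wax_ivc) or np.ndim(age)) else float(out[0])


def delta_d_precip(dD_wax_ivc, eps_landscape_permil):
    """Precipitation dD (permil) from ice-volume-corrected wax dD."""
    eps = np.asarray(eps_landscape_permil, dtype=float) / 1000.0
    if np.any(eps <= -1.0):
        raise ValueError("eps_landscape <= -1000 permil is unphysical")
    dw = np.asarray(dD_wax_ivc, dtype=float) / 1000.0
    out = 1000.0 * ((1.0 + dw) / (1.0 + eps) - 1.0)
    scalar = not (np.ndim(dD_wax_ivc) or np.ndim(eps_landscape_permil))
    return float(out) if scalar else out


def apply_fractionation(dD_precip_permil, eps_landscape_permil):
    """Inverse of :func:`delta_d_precip`: impose the biosynthetic offset."""
    eps = np.asarray(eps_landscape_permil, dtype=float) / 1000.0
    dp = np.asarray(dD_precip_permil, dtype=float) / 1000.0
    out = 1000.0 * ((1.0 + dp) * (1.0 + eps) - 1.0)
    scalar = not (np.ndim(dD_precip_permil) or np.ndim(eps_landscape_permil))
    return float(out) if scalar else out


# ---------------------------------------------------------------------------

@dataclass
class WaxChainConfig:
    """Everything needed to run the full d13C/dD interpretation chain."""

    endmembers: MixingEndMembers
    fractionation: FractionationParams
    seawater: SeawaterCorrection
    # optional pre-step: subtract an age-interpolated atmospheric d13C_CO2
    # anomaly from measured d13C before mixing (off by default; leaving the
    # record uncorrected is the conservative choice for glacial cycles).
    d13C_co2_anomaly: ProxyRecord | None = None


def propagate_wax_uncertainty(sample: WaxSample, config: WaxChainConfig,
                              n_draws: int = 10_000, seed: int | None = None):
    """Monte-Carlo propagation of measurement (and optional end-member /
    fractionation) uncertainty through the full chain.

    Returns ``(dD_precip, dD_precip_sigma, f_c4, f_c4_sigma)`` in permil /
    fraction.  f_C4 draws are clipped to [0, 1].
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for stable moments")
    rng = np.random.default_rng(seed)
    em, fp, sw = config.endmembers, config.fractionation, config.seawater

    d13c = sample.d13C + sample.d13C_sigma * rng.standard_normal(n_draws)
    dd = sample.dD + sample.dD_sigma * rng.standard_normal(n_draws)
    c3 = em.d13C_C3 + em.d13C_C3_sigma * rng.standard_normal(n_draws)
    c4 = em.d13C_C4 + em.d13C_C4_sigma * rng.standard_normal(n_draws)
    e3 = fp.eps_C3 + fp.eps_C3_sigma * rng.standard_normal(n_draws)
    e4 = fp.eps_C4 + fp.eps_C4_sigma * rng.standard_normal(n_draws)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FcFourClipWarning)
        f = np.clip((d13c - c3) / (c4 - c3), 0.0, 1.0)
    eps = (1.0 - f) * e3 + f * e4
    dd_ivc = ice_volume_correct(dd, np.full(n_draws, sample.age), sw)
    dp = delta_d_precip(dd_ivc, eps)
    return (float(dp.mean()), float(dp.std(ddof=1)) if n_draws > 1 else 0.0,
            float(f.mean()), float(f.std(ddof=1)) if n_draws > 1 else 0.0)


def apply_chain(samples: list[WaxSample], config: WaxChainConfig,
                n_draws: int = 10_000, seed: int | None = None,
                propagate: bool = True) -> tuple[ProxyRecord, ProxyRecord]:
    """Run the full chain over a sample series.

    Order of operations is fixed: f_C4 from raw d13C -> landscape epsilon ->
    ice-volume correction of dD -> dD_precip.  Returns a
    ``(dD_precip, f_C4)`` pair of :class:`ProxyRecord`.
    """
    samples = sorted(samples, key=lambda s: s.age)
    ages = np.array([s.age for s in samples])
    d13c = np.array([s.d13C for s in samples])
    dd = np.array([s.dD for s in samples])

    if config.d13C_co2_anomaly is not None:
        co2 = config.d13C_co2_anomaly
        d13c = d13c - np.interp(ages, co2.ages, co2.values)

    f = f_c4(d13c, config.endmembers)
    eps = epsilon_landscape(f, config.fractionation)
    dd_ivc = ice_volume_correct(dd, ages, config.seawater)
    dp = delta_d_precip(dd_ivc, eps)

    dp_sigma = f_sigma = None
    if propagate:
        ss = np.random.SeedSequence(seed).spawn(len(samples))
        stats = [propagate_wax_uncertainty(
            WaxSample(s.age, float(dc), s.d13C_sigma, s.dD, s.dD_sigma),
            config, n_draws=n_draws, seed=sub)
            for s, dc, sub in zip(samples, d13c, ss)]
        dp_sigma = np.array([t[1] for t in stats])
        f_sigma = np.array([t[3] for t in stats])

    return (ProxyRecord(ages, dp, sigma=dp_sigma, label="dD_precip_permil"),
            ProxyRecord(ages, f, sigma=f_sigma, label="f_c4"))


def read_wax_samples(path) -> list[WaxSample]:
    """Read samples from a CSV with columns
    age_ka, d13C_permil, d13C_sigma, dD_permil, dD_sigma."""
    df = pd.read_csv(path)
    return [WaxSample(r.age_ka, r.d13C_permil, r.d13C_sigma,
                      r.dD_permil, r.dD_sigma) for r in df.itertuples()]
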