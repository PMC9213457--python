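"""Extraterrestrial-3He constant-flux-proxy dust fluxes.

Interplanetary dust particles (IDPs) rain onto the sea floor at a known,
near-constant 3He flux.  Partitioning measured sedimentary 3He into its
terrestrial and extraterrestrial components by a two-end-member 3He/4He
mixing model turns the 3He_ET concentration into an instantaneous vertical
mass accumulation rate (MAR) that is immune to lateral sediment focusing
and winnowing:

    3He_ET = 3He_meas * (1 - R_terr/R_meas) / (1 - R_terr/R_IDP)
    MAR    = F_IDP / 3He_ET
    dust   = MAR * (1 - F_CaCO3 - F_Opal)

Concentrations are in pcc/g (1 pcc = 1e-12 cc STP); fluxes in g/cm2/kyr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PCC_PER_CC = 1.0e12


class NonPhysicalSampleWarning(UserWarning):
    """Measured ratio outside the terrestrial-IDP mixing interval."""


@dataclass
class HeliumMeasurement:
    """Helium isotope data for one sample (carbonate-free leached basis)."""

    age: float              # ka
    he3: float              # pcc/g
    he4: float              # pcc/g (note 4He is usually reported in ncc/g;
                            # converted upstream so both share a unit)
    ratio_meas: float       # 3He/4He, mol/mol
    he3_sigma_frac: float = 0.0
    he4_sigma_frac: float = 0.0
    f_caco3: float = 0.0    # weight fraction, bulk sediment
    f_opal: float = 0.0

    def __post_init__(self):
        if self.he3 <= 0 or self.he4 <= 0:
            raise ValueError("He concentrations must be positive")
        if not 0.0 <= self.f_caco3 + self.f_opal <= 1.0:
            raise ValueError("carbonate + opal weight fractions must be in [0, 1]")
        if self.he3_sigma_frac < 0 or self.he4_sigma_frac < 0:
            raise ValueError("sigma fractions must be nonnegative")
        # ratio must be consistent with the concentrations up to rounding
        implied = self.he3 / self.he4
        if not 0.5 < self.ratio_meas / implied < 2.0:
            raise ValueError(
                f"ratio_meas {self.ratio_meas:g} inconsistent with "
                f"he3/he4 = {implied:g}")

    @property
    def f_terr(self) -> float:
        """Terrestrial (non-carbonate, non-opal) weight fraction."""
        return 1.0 - self.f_caco3 - self.f_opal


@dataclass
class EndMemberConfig:
    """End members, IDP flux, and the uncertainty budget."""

    ratio_terr: float = 1.0e-8       # terrestrial 3He/4He (Monte-Carlo calibrated)
    ratio_idp: float = 2.4e-4        # IDP 3He/4He
    idp_flux: float = 8.0e-13        # cc/cm2/kyr
    idp_flux_sigma_frac: float = 0.40
    fterr_sigma_frac: float = 0.05
    analytical_sigma_frac: float = 0.01   # air-standard He concentration
    he3_rep_sigma_frac: float = 0.229     # replicate fractional difference
    he4_rep_sigma_frac: float = 0.166

    def __post_init__(self):
        if not self.ratio_terr < self.ratio_idp:
            raise ValueError("terrestrial end member must be below the IDP ratio")
        for name in ("idp_flux_sigma_frac", "fterr_sigma_frac",
                     "analytical_sigma_frac", "he3_rep_sigma_frac",
                     "he4_rep_sigma_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def idp_flux_pcc(self) -> float:
        return self.idp_flux * PCC_PER_CC

    @property
    def he3_sigma_frac(self) -> float:
        """Replicate and analytical 3He sigma combined in quadrature."""
        return float(np.hypot(self.he3_rep_sigma_frac, self.analytical_sigma_frac))

    @property
    def he4_sigma_frac(self) -> float:
        return float(np.hypot(self.he4_rep_sigma_frac, self.analytical_sigma_frac))


@dataclass
class DustFluxRecord:
    age: float
    he3_et: float            # pcc/g
    mar: float               # g/cm2/kyr
    dust_flux: float         # g/cm2/kyr
    dust_flux_sigma: float   # g/cm2/kyr
    valid: bool = True


# ---------------------------------------------------------------------------

def he3_et(m: HeliumMeasurement, em: EndMemberConfig, warn: bool = True) -> float:
    """Extraterrestrial 3He concentration (pcc/g) from the mixing model.

    Exact at both end members: returns 0 for a pure-terrestrial ratio and
    the full measured 3He for a pure-IDP ratio.  A measured ratio at or
    below the terrestrial end member (or above the IDP ratio) has no
    physical solution; the value is still returned but flagged.
    """
    value = m.he3 * (1.0 - em.ratio_terr / m.ratio_meas) / \
        (1.0 - em.ratio_terr / em.ratio_idp)
    if warn and not em.ratio_terr < m.ratio_meas <= em.ratio_idp:
        warnings.warn(
            f"sample at {m.age:g} ka: measured 3He/4He {m.ratio_meas:g} outside "
            f"({em.ratio_terr:g}, {em.ratio_idp:g}] — nonphysical mixing branch",
            NonPhysicalSampleWarning, stacklevel=2)
    return value


def mar_from_he3et(he3_et_pcc_g: float, em: EndMemberConfig) -> float:
    """Constant-flux-proxy mass accumulation rate, g/cm2/kyr."""
    if he3_et_pcc_g <= 0:
        raise ValueError("3He_ET must be positive to invert to a MAR")
    return em.idp_flux_pcc / he3_et_pcc_g


def dust_flux(mar: float, m: HeliumMeasurement) -> float:
    """Dust (terrigenous) flux: MAR times the terrestrial weight fraction."""
    return mar * m.f_terr


def _lognormal_unit_mean(cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal multipliers with mean 1 and sd/mean = cv (cv=0 -> ones)."""
    if cv == 0:
        return np.ones(n)
    sig2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sig2, sigma=np.sqrt(sig2), size=n)


def propagate_dust_uncertainty(m: HeliumMeasurement, em: EndMemberConfig,
                               n_draws: int = 100_000,
                               seed: int | None = None):
    """Monte-Carlo 1-sigma on the dust flux for one sample.

    Draws 3He and 4He (replicate + analytical sigma in quadrature, as
    independent error sources), the terrestrial weight fraction, and the
    IDP 3He flux; recomputes the measured ratio per draw from the drawn
    concentrations; pushes each draw through the mixing model, MAR, and
    dust-flux steps.  Draws landing on the nonphysical branch
    (ratio <= R_terr) are rejected and counted.

    Returns ``(sigma, mean, n_rejected)``; warns if over half the draws
    are rejected.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for a stable sigma")
    rng = np.random.default_rng(seed)
    # a sample's own sigma (total, when reported) overrides the configured
    # replicate-plus-analytical quadrature budget
    s3 = m.he3_sigma_frac if m.he3_sigma_frac > 0 else em.he3_sigma_frac
    s4 = m.he4_sigma_frac if m.he4_sigma_frac > 0 else em.he4_sigma_frac

    # concentrations are positive multiplicative quantities: lognormal
    # draws (mean-parametrized, sd/mean = the stated fraction) keep the
    # reciprocal step in the linear regime that the quadrature budget assumes
    he3 = m.he3 * _lognormal_unit_mean(s3, n_draws, rng)
    he4 = m.he4 * _lognormal_unit_mean(s4, n_draws, rng)
    fterr = m.f_terr * (1.0 + em.fterr_sigma_frac * rng.standard_normal(n_draws))
    fidp = em.idp_flux_pcc * _lognormal_unit_mean(em.idp_flux_sigma_frac,
                                                  n_draws, rng)

    ratio = m.ratio_meas * (he3 / m.he3) / (he4 / m.he4)
    ok = (he3 > 0) & (he4 > 0) & (ratio > em.ratio_terr) & (fidp > 0)
    n_rej = int(n_draws - ok.sum())
    if n_rej > n_draws // 2:
        warnings.warn(
            f"sample at {m.age:g} ka: {n_rej}/{n_draws} Monte-Carlo draws on the "
            "nonphysical branch", NonPhysicalSampleWarning, stacklevel=2)
    het = he3[ok] * (1.0 - em.ratio_terr / ratio[ok]) / \
        (1.0 - em.ratio_terr / em.ratio_idp)
    flux = fidp[ok] / het * fterr[ok]
    return float(flux.std(ddof=1)), float(flux.mean()), n_rej


def dust_flux_series(measurements: list[HeliumMeasurement],
                     em: EndMemberConfig | None = None,
                     n_draws: int = 10_000,
                     seed: int | None = None) -> list[DustFluxRecord]:
    """Full Eqs.-of-the-method pipeline over a sample list.

    Nonphysical samples are carried through with ``valid=False`` and NaN
    fluxes rather than dropped, so the caller sees what was excluded.
    """
    em = em or EndMemberConfig()
    out = []
    seeds = np.random.SeedSequence(seed).spawn(len(measurements))
    for m, ss in zip(measurements, seeds):
        if not em.ratio_terr < m.ratio_meas <= em.ratio_idp:
            warnings.warn(
                f"sample at {m.age:g} ka excluded: ratio {m.ratio_meas:g} outside "
                "the physical mixing branch", NonPhysicalSampleWarning, stacklevel=2)
            out.append(DustFluxRecord(m.age, np.nan, np.nan, np.nan, np.nan, False))
            continue
        het = he3_et(m, em, warn=False)
        mar = mar_from_he3et(het, em)
        fl = dust_flux(mar, m)
        sig, _, _ = propagate_dust_uncertainty(m, em, n_draws=max(n_draws, 1000),
                                               seed=ss)
        out.append(DustFluxRecord(m.age, het, mar, fl, sig, True))
    return out


def records_to_frame(records: list[DustFluxRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "age_ka": [r.age for r in records],
        "he3_et_pcc_g": [r.he3_et for r in records],
        "mar_g_cm2_kyr": [r.mar for r in records],
        "dust_flux_g_cm2_kyr": [r.dust_flux for r in records],
        "dust_flux_sigma": [r.dust_flux_sigma for r in records],
        "valid": [r.valid for r in records],
    })


def read_helium_measurements(path) -> list[HeliumMeasurement]:
    """Read a CSV with columns age_ka, he3_pcc_g, he4_pcc_g, ratio_meas,
    f_caco3, f_opal (and optionally he3_sigma_frac, he4_sigma_frac)."""
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        out.append(HeliumMeasurement(
            age=r.age_ka, he3=r.he3_pcc_g, he4=r.he4_pcc_g,
            ratio_meas=r.ratio_meas,
            he3_sigma_frac=getattr(r, "he3_sigma_frac", 0.0),
            he4_sigma_frac=getattr(r, "he4_sigma_frac", 0.0),
            f_caco3=r.f_caco3, f_opal=r.f_opal))
    return out
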