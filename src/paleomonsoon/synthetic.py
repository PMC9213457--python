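"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator stores its ground truth alongside the observables it
emits, so each pipeline stage has a parameter-recovery oracle:

- orbitally forced proxy series (local insolation + inter-hemispheric
  gradient mix) with AR(1) noise;
- plant-wax samples built by inverting the isotope chain from known
  f_C4(t) and dD_precip(t) plus measurement noise;
- a sediment column with prescribed vertical dust flux, carbonate
  dilution, a sediment focusing factor, and terrestrial + IDP helium
  carriers (the constant-flux-proxy oracle);
- latitudinal core-top d13C transects with ecotone shifts;
- a glacial-cycle benthic-stack stand-in (synthetic; scaled so the
  maximum seawater d18O anomaly is 1 permil) and a CO2-like series
  derived from it.

Noise defaults mirror the measurement uncertainty budget used throughout
the package (3He 22.9%, 4He 16.6%, terrestrial fraction 5%, IDP flux 40%,
wax replicate sigmas ~0.3 permil d13C / ~3 permil dD).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import sawtooth

from .agemodel import TiePoint
from .calibration import PairedSample
from .helium import HeliumMeasurement
from .orbital import InsolationSpec, forcing_series, hemispheric_gradient, normalize_01
from .records import ProxyRecord
from .stats import TransectPoint
from .wax import (SeawaterCorrection, WaxChainConfig, WaxSample,
                  apply_fractionation, uncorrect_ice_volume)


def _ar1_noise(n: int, alpha: float, sigma: float,
               rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise with stationary marginal standard deviation ``sigma``."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("ar1_alpha must be in [0, 1)")
    z = rng.standard_normal(n)
    e = np.empty(n)
    e[0] = z[0]
    innov = np.sqrt(1.0 - alpha**2)
    for i in range(1, n):
        e[i] = alpha * e[i - 1] + innov * z[i]
    return sigma * e


# ---------------------------------------------------------------------------
# forced proxy series

@dataclass
class ForcingMixSpec:
    """Weights of the two normalized orbital forcings plus AR(1) noise."""

    beta_local: float = -20.0      # per unit normalized 23.5N June-21 insolation
    beta_gradient: float = -15.0   # per unit normalized 23.5N-23.5S gradient
    intercept: float = -25.0       # permil, a dD_precip-like baseline
    ar1_alpha: float = 0.3
    noise_sigma: float = 2.0       # permil
    local_latitude: float = 23.5
    gradient_lats: tuple[float, float] = (23.5, -23.5)
    solar_longitude: float = 90.0
    seed: int | None = None


@dataclass
class ForcedSeries:
    record: ProxyRecord
    local_norm: ProxyRecord
    gradient_norm: ProxyRecord
    noise: np.ndarray
    spec: ForcingMixSpec


def gen_forced_series(spec: ForcingMixSpec, ages) -> ForcedSeries:
    """value(t) = intercept + beta_local*ins01 + beta_gradient*grad01 + AR(1)."""
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(spec.seed)
    ins = normalize_01(forcing_series(
        ages, InsolationSpec(spec.local_latitude, spec.solar_longitude)))
    grad = normalize_01(hemispheric_gradient(
        ages, *spec.gradient_lats, spec.solar_longitude))
    noise = _ar1_noise(len(ages), spec.ar1_alpha, spec.noise_sigma, rng)
    values = (spec.intercept + spec.beta_local * ins.values
              + spec.beta_gradient * grad.values + noise)
    return ForcedSeries(ProxyRecord(ages, values, label="synthetic_forced"),
                        ins, grad, noise, spec)


# ---------------------------------------------------------------------------
# wax samples

def gen_wax_samples(dD_precip_truth: ProxyRecord, f_c4_truth: ProxyRecord,
                    config: WaxChainConfig,
                    d13C_sigma: float = 0.3, dD_sigma: float = 3.0,
                    seed: int | None = None) -> list[WaxSample]:
    """Invert the isotope chain from known truths and add Gaussian noise."""
    if not np.array_equal(dD_precip_truth.ages, f_c4_truth.ages):
        raise ValueError("truth records must share common ages")
    f = f_c4_truth.values
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f_c4 truth outside [0, 1]")
    em, fp, sw = config.endmembers, config.fractionation, config.seawater
    rng = np.random.default_rng(seed)
    ages = dD_precip_truth.ages

    d13c = em.d13C_C3 + f * (em.d13C_C4 - em.d13C_C3)
    eps = (1.0 - f) * fp.eps_C3 + f * fp.eps_C4
    dd_ivc = apply_fractionation(dD_precip_truth.values, eps)
    dd_wax = uncorrect_ice_volume(dd_ivc, ages, sw)

    d13c_obs = d13c + d13C_sigma * rng.standard_normal(len(ages))
    dd_obs = dd_wax + dD_sigma * rng.standard_normal(len(ages))
    return [WaxSample(a, c, d13C_sigma, d, dD_sigma)
            for a, c, d in zip(ages, d13c_obs, dd_obs)]


# ---------------------------------------------------------------------------
# helium column

@dataclass
class SyntheticColumn:
    """Ground-truth sediment column for the constant-flux-proxy oracle."""

    ages: np.ndarray                       # ka, strictly increasing
    true_dust_flux: np.ndarray             # g/cm2/kyr, vertical
    f_caco3: np.ndarray                    # weight fraction of bulk
    focusing_factor: np.ndarray            # psi(t) > 0
    f_opal: np.ndarray | float = 0.0
    r_terr_true: float = 1.0e-8
    he4_per_g_dust: float = 4.0e6          # pcc 4He per g dust (old cratonic
                                           # Saharan dust is U/Th-rich)
    idp_flux_true: float = 8.0e-13         # cc 3He /cm2/kyr
    ratio_idp_true: float = 2.4e-4         # 3He/4He of the IDP carrier
    he3_noise_frac: float = 0.229
    he4_noise_frac: float = 0.166
    th_noise_frac: float = 0.05
    dry_bulk_density: float = 1.0          # g/cm3, for the depth axis
    seed: int | None = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        n = len(self.ages)
        for name in ("true_dust_flux", "f_caco3", "focusing_factor", "f_opal"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float),
                                (n,)).copy()
            setattr(self, name, v)
        if np.any(self.true_dust_flux <= 0):
            raise ValueError("true dust flux must be positive")
        if np.any(self.focusing_factor <= 0):
            raise ValueError("focusing factor must be positive")
        frac = self.f_caco3 + self.f_opal
        if np.any((frac < 0) | (frac >= 1)):
            raise ValueError("carbonate+opal fraction must be in [0, 1)")

    @property
    def f_terr(self) -> np.ndarray:
        return 1.0 - self.f_caco3 - self.f_opal

    @property
    def vertical_mass_flux(self) -> np.ndarray:
        """Total vertical (rain) mass flux, g/cm2/kyr."""
        return self.true_dust_flux / self.f_terr

    @property
    def deposited_mass_flux(self) -> np.ndarray:
        """Mass flux actually accumulating at the site (focusing included)."""
        return self.focusing_factor * self.vertical_mass_flux


@dataclass
class ColumnRealization:
    column: SyntheticColumn
    measurements: list[HeliumMeasurement]
    paired: list[PairedSample]
    tie_points: list[TiePoint]
    depths: np.ndarray       # mbsf at each sample age


def gen_helium_column(col: SyntheticColumn,
                      n_pairs: int = 5) -> ColumnRealization:
    """Emit noisy helium observables (bulk basis) from a ground-truth column.

    The terrestrial He carrier is the dust itself; the IDP 3He
    concentration is set by the vertical (not focused) mass flux, because
    lateral redistribution moves IDP-bearing sediment together with
    everything else — this is exactly the premise that makes 3He a
    constant-flux proxy.
    """
    rng = np.random.default_rng(col.seed)
    fv = col.vertical_mass_flux
    dust_mass_fraction = col.f_terr  # of bulk deposited sediment

    he4_terr = dust_mass_fraction * col.he4_per_g_dust            # pcc/g bulk
    he3_terr = col.r_terr_true * he4_terr
    he3_idp = col.idp_flux_true * 1.0e12 / fv                     # pcc/g bulk
    # IDPs carry 4He too, at their own isotope ratio; negligible against
    # dust 4He except in the zero-dust limit, where it pins the measured
    # ratio at the IDP end member
    he4 = he4_terr + he3_idp / col.ratio_idp_true
    he3 = he3_terr + he3_idp

    z3 = 1.0 + col.he3_noise_frac * rng.standard_normal(len(col.ages))
    z4 = 1.0 + col.he4_noise_frac * rng.standard_normal(len(col.ages))
    he3_obs = he3 * np.clip(z3, 0.05, None)
    he4_obs = he4 * np.clip(z4, 0.05, None)

    measurements = [
        HeliumMeasurement(age=a, he3=h3, he4=h4, ratio_meas=h3 / h4,
                          he3_sigma_frac=col.he3_noise_frac,
                          he4_sigma_frac=col.he4_noise_frac,
                          f_caco3=fc, f_opal=fo)
        for a, h3, h4, fc, fo in zip(col.ages, he3_obs, he4_obs,
                                     col.f_caco3, col.f_opal)]

    # depth axis from the deposited (focused) mass flux
    dep = col.deposited_mass_flux
    dt = np.diff(col.ages)
    mid_flux = 0.5 * (dep[:-1] + dep[1:])
    thick_m = mid_flux * dt / col.dry_bulk_density / 100.0
    depths = np.concatenate([[0.0], np.cumsum(thick_m)])
    tie_points = [TiePoint(d, a) for d, a in zip(depths, col.ages)]

    # Th-normalized MAR pairs: vertical mass flux with lognormal noise.
    # Pairs are picked to span the flux dynamic range (as one would select
    # calibration samples across the glacial-interglacial contrast).
    order = np.argsort(fv)
    idx = np.unique(order[np.linspace(0, len(order) - 1, n_pairs).astype(int)])
    th = fv[idx] * np.exp(col.th_noise_frac * rng.standard_normal(len(idx)))
    paired = [PairedSample(measurements[i], t, col.th_noise_frac)
              for i, t in zip(idx, th)]

    return ColumnRealization(col, measurements, paired, tie_points, depths)


# ---------------------------------------------------------------------------
# latitudinal transects

@dataclass
class TransectSpec:
    """Logistic ecotone model of d13C along the West African margin."""

    ecotone_latitude: dict = field(default_factory=lambda: {
        "late_holocene": 14.0, "mid_holocene": 19.0, "lgm": 14.0})
    slice_offset: dict = field(default_factory=dict)  # uniform permil shift
    c4_plateau: float = -22.0     # permil, grassy south flank
    c3_plateau: float = -30.0     # permil, desert-edge / Med flank
    transition_width: float = 2.0  # degrees latitude
    noise_sigma: float = 0.4       # per-core permil
    core_latitudes: np.ndarray = field(
        default_factory=lambda: np.linspace(-5.0, 30.0, 15))
    seed: int | None = None


def transect_truth(spec: TransectSpec, latitude, time_slice: str) -> np.ndarray:
    """Noise-free d13C at latitude for a time slice."""
    lat = np.asarray(latitude, dtype=float)
    eco = spec.ecotone_latitude[time_slice]
    if spec.transition_width == 0:
        f = (lat < eco).astype(float)
    else:
        f = 1.0 / (1.0 + np.exp((lat - eco) / spec.transition_width))
    off = spec.slice_offset.get(time_slice, 0.0)
    return spec.c3_plateau + (spec.c4_plateau - spec.c3_plateau) * f + off


def gen_transect(spec: TransectSpec) -> list[TransectPoint]:
    rng = np.random.default_rng(spec.seed)
    points = []
    for s in spec.ecotone_latitude:
        truth = transect_truth(spec, spec.core_latitudes, s)
        noisy = truth + spec.noise_sigma * rng.standard_normal(len(truth))
        for i, (lat, v) in enumerate(zip(spec.core_latitudes, noisy)):
            points.append(TransectPoint(lat, float(v), f"core_{i:02d}", s))
    return points


# ---------------------------------------------------------------------------
# benthic stack stand-in and CO2 coupling

def gen_benthic_stack(ages, glacial_period: float = 100.0,
                      sawtooth_asymmetry: float = 0.9,
                      ar1_alpha: float = 0.5, noise_sigma: float = 0.0,
                      seed: int | None = None) -> ProxyRecord:
    """Synthetic seawater d18O anomaly series (stand-in for a benthic stack).

    Asymmetric sawtooth glacial cycles (slow ice growth, fast termination)
    plus optional AR(1) noise, normalized so the maximum anomaly is
    1 permil and the present-day (0 ka) anomaly is 0.
    """
    ages = np.asarray(ages, dtype=float)
    if glacial_period <= 0:
        raise ValueError("glacial period must be positive")
    s = 0.5 * (sawtooth(2.0 * np.pi * ages / glacial_period,
                        width=sawtooth_asymmetry) + 1.0)
    s = s - s[0]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = s + _ar1_noise(len(ages), ar1_alpha, noise_sigma, rng)
        s = s - s[0]
    s = np.clip(s, 0.0, None)
    mx = s.max()
    if mx > 0:
        s = s / mx
    return ProxyRecord(ages, s, label="d18O_sw_synthetic_permil")


def co2_from_stack(stack: ProxyRecord, co2_interglacial: float = 280.0,
                   co2_glacial: float = 190.0) -> ProxyRecord:
    """CO2-like inverse of the ice-volume series (glacials = low CO2)."""
    vals = co2_interglacial - (co2_interglacial - co2_glacial) * stack.values
    return ProxyRecord(stack.ages, vals, label="co2_ppm_synthetic")


def f_c4_from_co2(co2: ProxyRecord, f_mean: float = 0.6,
                  gamma: float = 0.002) -> ProxyRecord:
    """C4 fraction truth coupled to CO2 (lower CO2 favors C4 grasses).

    ``gamma`` is the fraction change per ppm below/above the series mean.
    """
    f = np.clip(f_mean - gamma * (co2.values - co2.values.mean()), 0.0, 1.0)
    return ProxyRecord(co2.ages, f, label="f_c4_truth")


# ---------------------------------------------------------------------------
# fixture set

def generate_fixture_set(outdir, seed: int = 0,
                         ages=None) -> dict:
    """Write the full synthetic fixture set (CSVs + truth.json).

    Fixed seed -> byte-identical files.  Returns the truth manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ages = np.arange(0.0, 511.0, 3.0) if ages is None else np.asarray(ages)
    ss = np.random.SeedSequence(seed)
    s_forced, s_wax, s_col, s_tr, s_stack = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]

    stack = gen_benthic_stack(ages, noise_sigma=0.03, seed=s_stack)
    stack.to_csv(outdir / "benthic_stack.csv")
    co2 = co2_from_stack(stack)
    co2.to_csv(outdir / "co2.csv")

    fspec = ForcingMixSpec(seed=s_forced)
    forced = gen_forced_series(fspec, ages)
    forced.record.to_csv(outdir / "dD_precip_truth.csv")

    from .wax import FractionationParams, MixingEndMembers
    config = WaxChainConfig(
        endmembers=MixingEndMembers(),
        fractionation=FractionationParams(eps_C3=-115.0, eps_C4=-132.0),
        seawater=SeawaterCorrection(ages, stack.values))
    dD_truth = ProxyRecord(ages, np.clip(forced.record.values, -80.0, 0.0),
                           label="dD_precip_truth")
    f_truth = f_c4_from_co2(co2)
    samples = gen_wax_samples(dD_truth, f_truth, config, seed=s_wax)
    pd.DataFrame({
        "age_ka": [s.age for s in samples],
        "d13C_permil": [s.d13C for s in samples],
        "d13C_sigma": [s.d13C_sigma for s in samples],
        "dD_permil": [s.dD for s in samples],
        "dD_sigma": [s.dD_sigma for s in samples],
    }).to_csv(outdir / "wax_samples.csv", index=False)

    dust_truth = 0.15 + 0.1 * (forced.record.values - forced.record.values.min()) \
        / np.ptp(forced.record.values)
    col = SyntheticColumn(ages=ages, true_dust_flux=dust_truth,
                          f_caco3=0.6, focusing_factor=1.5, seed=s_col)
    real = gen_helium_column(col)
    pd.DataFrame({
        "age_ka": [m.age for m in real.measurements],
        "he3_pcc_g": [m.he3 for m in real.measurements],
        "he4_pcc_g": [m.he4 for m in real.measurements],
        "ratio_meas": [m.ratio_meas for m in real.measurements],
        "f_caco3": [m.f_caco3 for m in real.measurements],
        "f_opal": [m.f_opal for m in real.measurements],
    }).to_csv(outdir / "helium.csv", index=False)
    pd.DataFrame({
        "age_ka": [p.measurement.age for p in real.paired],
        "he3_pcc_g": [p.measurement.he3 for p in real.paired],
        "he4_pcc_g": [p.measurement.he4 for p in real.paired],
        "ratio_meas": [p.measurement.ratio_meas for p in real.paired],
        "f_caco3": [p.measurement.f_caco3 for p in real.paired],
        "f_opal": [p.measurement.f_opal for p in real.paired],
        "th_mar": [p.th_mar for p in real.paired],
        "th_mar_sigma_frac": [p.th_mar_sigma_frac for p in real.paired],
    }).to_csv(outdir / "paired_samples.csv", index=False)
    pd.DataFrame({"depth_mbsf": [t.depth for t in real.tie_points],
                  "age_ka": [t.age for t in real.tie_points]}).to_csv(
        outdir / "tie_points.csv", index=False)

    tspec = TransectSpec(seed=s_tr)
    tpoints = gen_transect(tspec)
    pd.DataFrame({
        "core_id": [p.core_id for p in tpoints],
        "latitude": [p.latitude for p in tpoints],
        "d13C_permil": [p.d13C for p in tpoints],
        "time_slice": [p.time_slice for p in tpoints],
    }).to_csv(outdir / "transect.csv", index=False)

    truth = {
        "seed": seed,
        "forcing_mix": {k: v for k, v in asdict(fspec).items()
                        if not isinstance(v, np.ndarray)},
        "wax": {"eps_C3": -115.0, "eps_C4": -132.0,
                "d13C_C3": -33.6, "d13C_C4": -19.9},
        "column": {"r_terr_true": col.r_terr_true,
                   "idp_flux_true": col.idp_flux_true,
                   "focusing_factor": float(col.focusing_factor[0]),
                   "he4_per_g_dust": col.he4_per_g_dust},
        "transect": {"ecotone_latitude": tspec.ecotone_latitude,
                     "c4_plateau": tspec.c4_plateau,
                     "c3_plateau": tspec.c3_plateau},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return truth
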