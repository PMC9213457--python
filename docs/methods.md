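# Methods

`paleomonsoon` implements the proxy computations and statistical
machinery used to reconstruct orbital-scale West African monsoon
variability from marine sediment archives: insolation forcing, plant-wax
isotope interpretation, extraterrestrial-³He constant-flux-proxy dust
fluxes, Monte-Carlo end-member calibration, and the time-series methods
(autocorrelation-adjusted correlation, Morlet wavelets, LOESS transects)
used to attribute the resulting records. Every stage can be exercised on
synthetic data with stored ground truth, which is how the test suite
establishes parameter recovery.

## Orbital forcing

Orbital elements come from a truncated trigonometric solution of the
Berger-1978 class: the full 47-term obliquity development, the full
19-term development of e·sin Π / e·cos Π (fixed-frame perihelion), and
the 30 largest terms of the general precession in longitude. Omitted
precession terms contribute < 0.02° each; the solution reproduces the
known present-day values (obliquity 23.446°, perihelion at solar
longitude ~281°) and the canonical periodicities (41 kyr obliquity;
19–24 kyr climatic precession). The validity window is enforced at
0–1000 ka; the package's study window (0–520 ka) sits well inside it.

Daily-mean top-of-atmosphere insolation uses the standard closed form

    W = S0/π · (a/r)² · (H₀ sin φ sin δ + cos φ cos δ sin H₀)

with declination sin δ = sin ε sin λ, sunrise hour angle
H₀ = arccos(−tan φ tan δ) (clipped for polar day/night), and the Kepler
distance factor (a/r) = (1 + e cos ν)/(1 − e²) where the true anomaly is
ν = λ − ϖ. "June 21" is implemented as solar longitude λ = 90° — the
angular definition of the northern solstice — rather than a fixed
calendar day, avoiding paleo-calendar drift. The solar constant defaults
to 1365 W/m² and is configurable; nothing downstream depends on its
absolute value because forcing series are normalized to [0, 1] (an
affine map, so all correlations are preserved exactly).

## Age–depth model

Ages are piecewise-linear between externally supplied tie points
(tie-point construction, e.g. graphical matching to a benthic δ¹⁸O
stack, is out of scope — the points are inputs). Event layers of rapid
deposition are excised: the layer thickness is removed from the depth
axis and every depth inside maps to the age of the layer top. With tie
points bracketing a layer, its removal leaves all other ages unchanged.
Extrapolation beyond the tie-point span is off by default and, when
enabled, extends the end-interval sedimentation rates. Stratigraphic
mass accumulation rates are ρ·Δz/Δt per tie-point interval (dry bulk
density is a required user input); by construction they scale with any
sediment-focusing factor, which is exactly the bias the constant-flux
proxy removes.

## Plant-wax isotope chain

The fixed order of operations is: C₄ fraction from raw δ¹³C →
landscape apparent fractionation → ice-volume correction of δD →
precipitation δD:

    f_C4   = (δ¹³C_meas − δ¹³C_C3) / (δ¹³C_C4 − δ¹³C_C3)
    ε_l    = (1 − f_C4)·ε_C3 + f_C4·ε_C4
    δD_ivc = (1 + δD_wax) / (1 + δD_sw) − 1
    δD_p   = (1 + δD_ivc) / (1 + ε_l) − 1

All ‰ quantities are converted to fractional units before the "+1"
algebra (the identities only hold in fractional form); I/O stays in ‰.
The δ¹³C end members default to −33.6/−19.9‰ (African C₃ trees / C₄
grasses, C31 n-alkane). The apparent fractionations ε_C3, ε_C4 have *no*
defaults — they must be configured from a fractionation compilation,
because silently assuming them would fix the δD_precip scale. The
seawater term scales a benthic δ¹⁸O stack so the Last Glacial Maximum
anomaly is 1‰ and converts to δD with the global-meteoric-water-line
slope (8). f_C4 values pushed outside [0, 1] by measurement noise are
clipped with a warning rather than erroring. An optional pre-step
subtracts an age-interpolated atmospheric δ¹³C_CO2 anomaly; it is off by
default (the conservative choice across glacial transitions) and the
default path is bit-identical with the flag absent.

Uncertainties are propagated by Monte-Carlo resampling of the measured
values (and, if configured, end-member/fractionation σ) through the full
chain; the chain is nearly linear at the operating point, so the MC σ
agrees with linear propagation (verified in tests to 2%).

## Helium dust fluxes

The two-component ³He/⁴He mixing model partitions measured ³He:

    ³He_ET = ³He_meas · (1 − R_terr/R_meas) / (1 − R_terr/R_IDP)
    MAR    = F_IDP / ³He_ET
    dust   = MAR · (1 − F_CaCO3 − F_opal)

with defaults R_terr = 1×10⁻⁸ (see calibration below), R_IDP = 2.4×10⁻⁴,
F_IDP = 8×10⁻¹³ cc STP/cm²/kyr. Unit handling is centralized (1 pcc =
10⁻¹² cc STP). Samples whose measured ratio falls at or below the
terrestrial end member (or above the IDP ratio) have no physical mixing
solution; they are flagged and carried as NaN rather than dropped
silently. The uncertainty budget combines, per sample: analytical σ
(1%), replicate fractional differences (³He 22.9%, ⁴He 16.6%; combined
with analytical in quadrature as independent sources), terrestrial
weight fraction (5%), and IDP flux (40%). Concentration and IDP-flux
draws are lognormal with mean equal to the measured value and sd/mean
equal to the stated fraction: these are positive multiplicative
quantities, and the lognormal keeps the reciprocal step (MAR ∝ 1/³He)
exactly in the linear regime — with normal draws the reciprocal's
variance is formally divergent and the sample σ is dominated by rare
near-zero draws. In the regime R_meas ≫ R_terr the ⁴He term drops out
and the fractional σ reduces to the quadrature of the remaining four
components (≈ 0.464), which the MC reproduces.

The helium basis convention: concentrations are treated on a bulk-
sediment basis consistently from generator to flux (the terrestrial
weight fraction applies to bulk). Measured data reported carbonate-free
must be reconciled to bulk before entry; the data classes document this
so the conversion cannot be double-counted.

## Terrestrial end-member calibration

Paired samples with both He- and ²³⁰Th-derived MARs (Th-derived MARs are
consumed as inputs; their decay systematics are out of scope) constrain
R_terr: if the assumed end member is right, the total-least-squares
regression of He-MAR on Th-MAR has slope 1. For each candidate on a grid
(default 500 values over 1×10⁻⁹–1×10⁻⁷), n = 10,000 artificial
regressions resample the He and Th measurements from their stated σ, the
IDP flux from its normal prior (40%), and the IDP ratio from a uniform
prior on 1–4×10⁻⁴. The TLS slope uses the closed-form minor-eigenvector
solution on centered data (unweighted, unit error ratio, matching the
plain total-least-squares reading; a variance-weighted variant is not
provided because the draw distributions already encode the error
structure). Draws producing a nonphysical ³He_ET are rejected outright,
not resampled — resampling would bias the tails — and counted.

The per-candidate slope distribution is summarized by a Gaussian KDE
with Silverman bandwidth (recorded per candidate), evaluated at
slope 1. The resulting curve over candidates is a *plateau*, not a
peak: the data bound the end member from above but candidates far below
the truth are indistinguishable, because the extraterrestrial fraction
of ³He saturates. `choose_endmember` reports the plateau and a
configured preferred value inside it; it never auto-selects. In tests
the plateau is defined relative to the curve maximum (≥ 0.75·max)
because the absolute density level depends on the specific measurement
realization: the common 40% IDP-flux factor alone caps the achievable
density near 1.0, and the measurement errors frozen into any given five
pairs shift the slope center off 1 by a realization-dependent amount.
Flux-amplitude sensitivity to the end member is monotone (amplitude
grows with R_terr; timing of extrema is invariant), which
`flux_sensitivity` verifies by sweep.

Seeding: one seed stream with per-candidate substreams
(`numpy.random.SeedSequence.spawn`), so the full ensemble is
reproducible and candidates are independent; results are invariant to
the order the paired samples are supplied in.

## Series statistics

Correlations between proxy series use Pearson r after linear
interpolation of the higher-resolution series to the sample ages (no
extrapolation). Significance accounts for serial autocorrelation through
the effective sample size n_eff = n(1 − r₁ₓr₁ᵧ)/(1 + r₁ₓr₁ᵧ) with lag-1
autocorrelations estimated from the series, followed by a two-sided
t-test on n_eff − 2 degrees of freedom; n_eff is capped at n, and below
3 the p-value is reported as undefined. A phase-randomization surrogate
test is available as an alternative (`adjust="surrogate"`). Calibration:
for independent AR(1) pairs with lag-1 = 0.9 and n = 100 the adjusted
test's type-I error is ~0.04 (naive: ~0.50); for white noise it is
~0.045 — both verified by simulation in the suite.

LOESS transects use degree-2 local polynomials with tricube weights
over a span fraction of the points (default 0.5); the implementation is
a direct weighted-least-squares solve per grid point and is checked
against an independent normal-equations solve and against exact
reproduction of quadratic data. Time-slice anomalies (late Holocene
0–2 ka, mid-Holocene 6–8 ka, LGM 19–23 ka) are per-core means of one
slice minus another; cores missing a window are excluded with a log
entry.

## Wavelet analysis

The continuous wavelet transform uses a Morlet mother wavelet with
nondimensional frequency ω₀ = 5, implemented in the frequency domain
with zero-padding to the next power of two. Scales are s₀·2^(j·dj) with
dj = 0.1 and s₀ = 2Δt, spanning to half the series length; series are
first linearly resampled to uniform spacing (3 kyr for orbital-
resolution records) and demeaned. The Fourier period per unit scale is
4π/(ω₀ + √(2 + ω₀²)) ≈ 1.2325 for ω₀ = 5; the cone of influence is the
√2·s e-folding time of the Morlet envelope. The reconstruction constant
used in the Parseval-type variance check is computed numerically from
the transform of a delta function at ω₀ = 5 rather than taken from
tables published for ω₀ = 6; scalogram-reconstructed variance matches
the series variance within 5% for white noise at n = 1024.

Significance is a pointwise test of power against the theoretical AR(1)
(red-noise) spectrum scaled by the χ²(2 dof) quantile at the chosen
level; the AR(1) coefficient defaults to the series' own lag-1
autocorrelation. Monte-Carlo calibration over AR(1) nulls gives an
outside-COI exceedance of ~5% at the 95% level. The cross-wavelet
transform is Wₓ·conj(Wᵧ); its phase is positive where x leads y, and
`phase_lead_at_period` converts the cross-power-weighted circular mean
phase along the nearest scale row (outside the COI) to a lead in kyr. A
constructed 6-kyr lead at the 41-kyr band is recovered to ±0.15 kyr.
Wavelet coherence smoothing operators are deliberately out of scope —
the analyses here need scalograms, significance, and phase leads only.

## Synthetic data

The generators define the study conditions and store their ground truth:

- **Forced proxy series**: value(t) = intercept + β_local·ins₀₁(t) +
  β_gradient·grad₀₁(t) + AR(1) noise (stationary marginal sd =
  `noise_sigma`, default 2‰; α = 0.3). Defaults (β = −20, −15 on the
  normalized forcings, ~3 kyr sampling over 510 kyr) give the orbital-
  band signal-to-noise typical of well-resolved monsoon proxy records.
  The two normalized forcings are collinear (r ≈ 0.88), so recovery
  tests use HAC standard errors and pool replicates.
- **Wax samples**: exact inversion of the isotope chain from known
  f_C4(t) and δD_precip(t), plus Gaussian noise at typical replicate
  levels (0.3‰ δ¹³C, 3‰ δD).
- **Helium column**: prescribed vertical dust flux, carbonate dilution,
  and focusing factor ψ(t). The deposited mass flux is ψ·(vertical
  flux); terrestrial He rides on the dust (default 4×10⁶ pcc ⁴He/g,
  typical of old cratonic Saharan dust — this puts measured ³He/⁴He at
  ~3×10⁻⁷–2×10⁻⁶, where the end-member calibration has leverage); the
  IDP ³He concentration is set by the *vertical* (unfocused) mass flux,
  which is precisely the constant-flux-proxy premise (laterally focused
  sediment carries its IDPs with it); IDPs also carry ⁴He at the IDP
  ratio, so the zero-dust limit pins the measured ratio at R_IDP.
  Concentration noise is multiplicative at the stated budget (22.9%,
  16.6%); Th-MARs are the vertical flux with 5% lognormal noise, and
  paired samples are picked to span the flux dynamic range, as one
  would select calibration samples across a glacial–interglacial
  contrast. A depth axis built from the deposited flux feeds the
  age-model comparison (stratigraphic MAR ≈ ψ × vertical flux).
- **Transects**: logistic ecotone model per time slice with per-core
  noise; a slice-wide uniform offset emulates a CO₂-type effect.
- **Benthic stack stand-in** (synthetic): asymmetric sawtooth glacial
  cycles plus AR(1) noise, scaled so the maximum seawater δ¹⁸O anomaly
  is 1‰ and the present-day anomaly 0; a CO₂-like series is its inverse
  mapping onto 190–280 ppm, and a C₄-fraction truth can be coupled to
  it.

What the generators do *not* emulate: age-model error (sample ages are
exact), non-Gaussian and drift components of measurement error,
provenance mixing (distinct wax sheds), carbonate-dissolution cycles
correlated with climate, and non-stationary orbital response. Passing
recovery tests therefore demonstrate the correctness and calibration of
the *computations* under the stated error model, not robustness of the
scientific inferences to those real-world complications.

## Problem sizes and numerical choices

Test and acceptance runs use the method at reduced but representative
sizes, chosen as the scales at which each statistic stabilizes: the
end-member grid at 60–100 candidates with 800–2000 draws (module
defaults remain 500 × 10,000); wavelet null calibration at 200
replicates of n = 170; correlation calibration at 10,000 pairs of
n = 100; uncertainty budgets at 10⁵ draws. Ties and degenerate cases are
pinned by tests: coincident TLS points raise, vertical-line data return
an infinite-slope sentinel, constant series cannot be 0–1 normalized,
KDE of zero-spread slope draws reports a spike, and polar night returns
exactly zero insolation.
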