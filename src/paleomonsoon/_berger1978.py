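"""Trigonometric-series coefficients for the Berger (1978) orbital solution.

Obliquity, eccentricity and longitude-of-perihelion are expressed as
truncated sums of sinusoids in time; the coefficient triples below are the
published (amplitude, mean rate, phase) tables of that solution.  Amplitudes
of the obliquity and general-precession developments are in arcseconds,
rates in arcseconds per year, phases in degrees; time is measured in years
relative to 1950 CE (negative into the past).

Truncation level: the full 47-term obliquity and 19-term eccentricity
developments, and the 30 largest general-precession terms (omitted
precession terms each contribute < 0.02 degrees).  The solution is accurate
to a few hundredths of a degree over the last million years, far better
than the proxy chronologies it is paired with here.
"""

import numpy as np

# Mean obliquity (degrees) and the periodic development of obliquity.
EPSILON_STAR_DEG = 23.320556

# (amplitude arcsec, rate arcsec/yr, phase deg)
OBLIQUITY_TERMS = np.array([
    (-2462.2214466, 31.609974, 251.9025),
    (-857.3232075, 32.620504, 280.8325),
    (-629.3231835, 24.172203, 128.3057),
    (-414.2804924, 31.983787, 292.7252),
    (-311.7632587, 44.828336, 15.3747),
    (308.9408604, 30.973257, 263.7951),
    (-162.5533601, 43.668246, 308.4258),
    (-116.1077911, 32.246691, 240.0099),
    (101.1189923, 30.599444, 222.9725),
    (-67.6856209, 42.681324, 268.7809),
    (24.9079067, 43.836462, 316.7998),
    (22.5811241, 47.439436, 319.6024),
    (-21.1601414, 63.219948, 143.8050),
    (-15.6549876, 64.230478, 172.7351),
    (15.3936813, 1.010530, 28.9300),
    (14.6660938, 7.437771, 123.5968),
    (-11.7273029, 55.782177, 20.2082),
    (10.2742951, 0.373813, 40.8226),
    (6.4914588, 13.218362, 123.4722),
    (5.8539148, 62.583231, 155.6977),
    (-5.4872205, 63.593761, 184.6277),
    (-5.4290191, 76.438310, 267.2772),
    (5.1609570, 45.815258, 55.0196),
    (5.0786314, 8.448301, 152.5268),
    (-4.0735782, 56.792707, 49.1382),
    (3.7227167, 49.747842, 204.6609),
    (3.3971932, 12.058272, 56.5233),
    (-2.8347004, 75.278220, 200.3284),
    (-2.6550721, 65.241008, 201.6651),
    (-2.5717867, 64.604291, 213.5577),
    (-2.4712188, 1.647247, 17.0374),
    (2.4625410, 7.811584, 164.4194),
    (2.2464112, 12.207832, 94.5422),
    (-2.0755511, 63.856665, 131.9124),
    (-1.9713669, 56.155990, 61.0309),
    (-1.8813061, 77.448840, 296.2073),
    (-1.8468785, 6.801054, 135.4894),
    (1.8186742, 62.209418, 114.8750),
    (1.7601888, 20.656133, 247.0691),
    (-1.5428851, 48.344406, 256.6114),
    (1.4738838, 55.145460, 32.1008),
    (-1.4593669, 69.000539, 143.6804),
    (1.4192259, 11.071350, 16.8784),
    (-1.1818980, 74.291298, 160.6835),
    (1.1756474, 11.047742, 27.5932),
    (-1.1316126, 0.636717, 348.1074),
    (1.0896928, 12.844549, 82.6496),
])

# Development of e*sin(Pi), e*cos(Pi) with Pi the longitude of perihelion in
# the fixed frame of reference.  (amplitude, rate arcsec/yr, phase deg)
ECCENTRICITY_TERMS = np.array([
    (0.01860798, 4.207205, 28.620089),
    (0.01627522, 7.346091, 193.788772),
    (-0.01300660, 17.857263, 308.307024),
    (0.00988829, 17.220546, 320.199637),
    (-0.00336700, 16.846733, 279.376984),
    (0.00333077, 5.199079, 87.195000),
    (-0.00235400, 18.231076, 349.129677),
    (0.00140015, 26.216758, 128.443387),
    (0.00100700, 6.359169, 154.143880),
    (0.00085700, 16.210016, 221.739204),
    (0.00064990, 3.065181, 276.819503),
    (0.00059900, 16.583829, 200.402846),
    (0.00037800, 18.493980, 15.374687),
    (-0.00033700, 6.190953, 263.386961),
    (0.00027600, 18.867793, 58.574905),
    (0.00018200, 17.425567, 28.979533),
    (-0.00017400, 6.186001, 90.228695),
    (-0.00012400, 18.417441, 17.300034),
    (0.00001250, 0.667863, 285.163344),
])

# General precession in longitude: psi = PSI_DOT*t + ZETA + periodic terms.
PSI_DOT_ARCSEC_PER_YR = 50.439273
ZETA_DEG = -3.392506

# (amplitude arcsec, rate arcsec/yr, phase deg) — 30 largest terms
PRECESSION_TERMS = np.array([
    (7391.0225890, 31.609974, 251.9025),
    (2555.1526947, 32.620504, 280.8325),
    (2022.7629188, 24.172203, 128.3057),
    (-1973.6517951, 0.636717, 348.1074),
    (1240.2321818, 31.983787, 292.7252),
    (953.8679112, 3.138886, 165.1686),
    (-931.7537108, 30.973257, 263.7951),
    (872.3795383, 44.828336, 15.3747),
    (606.3544732, 0.991874, 58.5749),
    (-496.0274038, 0.373813, 40.8226),
    (456.9608039, 43.668246, 308.4258),
    (346.9462320, 32.246691, 240.0099),
    (-305.8412902, 30.599444, 222.9725),
    (249.6173246, 2.147012, 106.5937),
    (-199.1027200, 10.511172, 114.5182),
    (191.0560889, 42.681324, 268.7809),
    (-175.2936572, 13.650058, 279.6869),
    (165.9068833, 0.986922, 39.6448),
    (161.1285917, 9.874455, 126.4108),
    (139.7878093, 13.013341, 291.5795),
    (-133.5228399, 0.262904, 307.2848),
    (117.0673811, 0.004952, 18.9300),
    (104.6907281, 1.142024, 273.7596),
    (95.3227476, 63.219948, 143.8050),
    (86.7824524, 0.205021, 191.8927),
    (86.0857729, 2.151964, 125.5237),
    (70.5893698, 64.230478, 172.7351),
    (-69.9719343, 43.836462, 316.7998),
    (-62.5817473, 47.439436, 319.6024),
    (61.5450059, 1.384343, 69.7526),
])

ARCSEC_TO_DEG = 1.0 / 3600.0


def _series(terms: np.ndarray, t_years: np.ndarray, trig) -> np.ndarray:
    """Sum A_i * trig(f_i * t + phi_i) with rates in arcsec/yr, phases in deg."""
    amp = terms[:, 0]
    rate_deg = terms[:, 1] * ARCSEC_TO_DEG
    phase = terms[:, 2]
    ang = np.deg2rad(rate_deg[:, None] * t_years[None, :] + phase[:, None])
    return (amp[:, None] * trig(ang)).sum(axis=0)


def obliquity_deg(t_years: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t_years, dtype=float))
    out = EPSILON_STAR_DEG + ARCSEC_TO_DEG * _series(OBLIQUITY_TERMS, t, np.cos)
    return out


def eccentricity_and_fixed_perihelion(t_years):
    """Return (e, Pi_deg) with Pi the fixed-frame longitude of perihelion."""
    t = np.atleast_1d(np.asarray(t_years, dtype=float))
    esinpi = _series(ECCENTRICITY_TERMS, t, np.sin)
    ecospi = _series(ECCENTRICITY_TERMS, t, np.cos)
    ecc = np.hypot(esinpi, ecospi)
    pi_deg = np.rad2deg(np.arctan2(esinpi, ecospi)) % 360.0
    return ecc, pi_deg


def general_precession_deg(t_years) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t_years, dtype=float))
    psi = (PSI_DOT_ARCSEC_PER_YR * ARCSEC_TO_DEG * t + ZETA_DEG
           + ARCSEC_TO_DEG * _series(PRECESSION_TERMS, t, np.sin))
    return psi


def longitude_of_perihelion_deg(t_years) -> np.ndarray:
    """Longitude of perihelion from the moving vernal equinox (degrees).

    Returned in the geocentric-solar convention (the sun's ecliptic
    longitude when the Earth is at perihelion), i.e. the heliocentric
    Berger angle plus 180 degrees; at present this is ~283 degrees
    (perihelion in early January).
    """
    _, pi_deg = eccentricity_and_fixed_perihelion(t_years)
    psi = general_precession_deg(t_years)
    return (pi_deg + psi + 180.0) % 360.0
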