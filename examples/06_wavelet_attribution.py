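"""Wavelet attribution of orbital-band variability.

Generates a monsoon-proxy-like series forced by the inter-hemispheric
insolation gradient, shows that its scalogram carries both precession
(~23 kyr) and obliquity (~41 kyr) ridges, and recovers a constructed
6-kyr lead from the cross-wavelet phase.
"""

import numpy as np

from paleomonsoon import stats, synthetic, wavelet
from paleomonsoon.records import ProxyRecord

ages = np.arange(0.0, 511.0, 3.0)
spec = synthetic.ForcingMixSpec(beta_local=0.0, beta_gradient=20.0,
                                noise_sigma=1.0, seed=1)
forced = synthetic.gen_forced_series(spec, ages)

series = wavelet.resample_uniform(forced.record)
res = wavelet.cwt_morlet(series)  # Morlet, omega0 = 5
alpha = max(stats.lag1_autocorrelation(series.values), 0.0)
mask = wavelet.ar1_significance(res, alpha=alpha)

avg = res.power.mean(axis=1)
peaks = [res.periods[i] for i in range(1, len(avg) - 1)
         if avg[i] > avg[i - 1] and avg[i] > avg[i + 1]]
print("scale-averaged power maxima at periods (kyr):",
      [round(float(p), 1) for p in peaks])
print(f"fraction of scalogram significant at 95% (outside COI): "
      f"{mask[res.outside_coi()].mean():.2f}")

x = ProxyRecord(ages, np.sin(2 * np.pi * ages / 41.0))
y = ProxyRecord(ages, np.sin(2 * np.pi * (ages - 6.0) / 41.0))
lead = wavelet.phase_lead_at_period(wavelet.cross_wavelet(x, y), 41.0)
print(f"constructed 6-kyr lead recovered at the 41-kyr band: {lead:.2f} kyr")

# A gradient-forced series shows ridges in BOTH orbital bands — the
# diagnostic separating gradient forcing from purely local (precession-
# only) insolation forcing. Phase leads at the obliquity band measure
# timing offsets against, e.g., ice-volume records.
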