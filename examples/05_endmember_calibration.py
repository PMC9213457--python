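"""Monte-Carlo calibration of the terrestrial 3He/4He end member.

Five samples with both He- and 230Th-derived mass accumulation rates
constrain the terrestrial end member: for each candidate on a grid,
artificial total-least-squares regressions are drawn by resampling all
measured quantities and priors, and the kernel density of the slope
draws is evaluated at slope 1.
"""

import numpy as np

from paleomonsoon import calibration, synthetic

ages = np.linspace(0.0, 510.0, 37)
dust = 0.35 + 0.25 * np.sin(2 * np.pi * ages / 23.0)
col = synthetic.SyntheticColumn(ages=ages, true_dust_flux=dust, f_caco3=0.6,
                                focusing_factor=1.5, r_terr_true=1.0e-8,
                                seed=3)
pairs = synthetic.gen_helium_column(col, n_pairs=5).paired

cfg = calibration.CalibrationConfig(
    endmember_grid=np.linspace(1e-9, 1e-7, 100), n_mc=2000, seed=11)
res = calibration.calibrate(pairs, cfg)

print("candidate R_terr  density at slope 1")
for i in range(0, 100, 10):
    bar = "#" * int(40 * res.pdf_at_one[i] / np.nanmax(res.pdf_at_one))
    print(f"{res.endmembers[i]:.2e}   {res.pdf_at_one[i]:6.3f}  {bar}")

choice = calibration.choose_endmember(
    res, threshold=0.75 * np.nanmax(res.pdf_at_one), preferred=1e-8)
print(f"\n{choice['diagnostic']}")
print(f"generating value 1e-8 inside plateau: "
      f"{choice['plateau'][0] <= 1e-8 <= choice['plateau'][1]}")

# Candidates well below the truth are indistinguishable (the curve is a
# plateau, not a peak: the data only bound the end member from above);
# candidates several times larger inflate the He-derived MARs away from
# the Th constraint and the density at slope 1 collapses.
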