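"""Apical F-actin intensity profiles: junctional versus uniform patterns.

Simulates images for two conditions - signal concentrated at the cell-cell
junctions (0% and 100% of the apical path) versus spread uniformly over the
apical surface - samples width-3 line profiles through 3 embryos x 5 cells
per condition, normalizes each profile by its cell's nuclear mean, and fits
a LOWESS curve with a bootstrap 95% confidence band (resampling cells
within embryos).
"""

import pandas as pd

from epiquant import profiles as pr
from epiquant.synth import ProfileSimConfig, generate_profile_image

bands = {}
for mode in ("junctional", "uniform"):
    tidy = []
    for e in range(3):            # embryos
        for c in range(5):        # cells per embryo
            cfg = ProfileSimConfig(mode=mode, noise_sd=2.0,
                                   seed=100 * e + c)
            image, _ = generate_profile_image(cfg)
            prof = pr.profile_cell(image, cfg.path(), cfg.nucleus_polygon,
                                   width=3)
            prof["cell"] = f"e{e}c{c}"
            prof["embryo"] = f"e{e}"
            tidy.append(prof)
    tidy = pd.concat(tidy, ignore_index=True)
    bands[mode] = pr.fit_lowess_band(tidy, frac=0.3, n_boot=200, seed=0)
    fit = bands[mode]["fit"]
    print(f"{mode:>10}: fitted range {fit.min():.3f} - {fit.max():.3f} "
          f"(peak-to-trough {fit.max() - fit.min():.3f}, "
          f"n = {tidy['cell'].nunique()} cells)")

# junctional profiles peak at the junction positions (path ends)
jfit = bands["junctional"]
peak_pos = jfit.loc[jfit["fit"].idxmax(), "percent"]
print(f"\njunctional fit peaks at {peak_pos:.0f}% of the apical path "
      "(junctions sit at 0% and 100%)")
print("uniform-mode fit stays flat: the mutant-like phenotype spreads the "
      "same total signal evenly")
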