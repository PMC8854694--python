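"""Phasor-FLIM lifetime pipeline on a synthetic tension-probe stack.

Simulates a photon-decay stack with two tissue regions whose probe
lifetimes differ (high versus low membrane tension), then runs the standard
pipeline: 5x5 pixel binning, background thresholding, phasor transform,
median filtering, lifetime mapping and ROI means restricted to the
tension-sensitive 2.8-7 ns window. Writes a rainbow-coded lifetime image to
scratch/.
"""

from pathlib import Path

import numpy as np

from epiquant import flim as fl
from epiquant.synth import FlimSimConfig, generate_flim_stack


def rect(r0, c0, r1, c1):
    return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], float)


# --- simulate: left half 4.83 ns (high tension), right half 4.50 ns ------
h, w = 100, 100
cfg = FlimSimConfig(
    image_shape=(h, w),
    regions=[(rect(-0.5, -0.5, h - 0.5, w / 2 - 0.5), 4.83),
             (rect(-0.5, w / 2 - 0.5, h - 0.5, w - 0.5), 4.50)],
    photons_per_pixel_mean=400.0,  # 1e4 per pixel after 5x5 binning
    rep_rate=20e6, n_time_bins=256, pixel_size_nm=135.0, seed=0)
stack, truth = generate_flim_stack(cfg)
print(f"raw stack: {stack.decay.shape} (bins, rows, cols), "
      f"{stack.pixel_size_nm:.0f} nm pixels")

# --- the published pipeline ----------------------------------------------
stack = fl.bin_pixels(stack, 5)            # 675 nm pixels, 25x the photons
stack = fl.threshold_background(stack, 50)  # drop dim background pixels
ph = fl.phasor_transform(stack)
ph = fl.median_filter_phasor(ph, 5)
lt = fl.lifetime_map(ph)                   # exact finite-bin-width inversion
print(f"binned lifetime map: {lt.tau.shape}, "
      f"{lt.pixel_size_nm:.0f} nm pixels")

# --- ROI means inside the tension-sensitive window -----------------------
rois = fl.RoiSet(rois={"left": rect(2, 2, 17, 7),
                       "right": rect(2, 13, 17, 18)},
                 lifetime_window=fl.TENSION_WINDOW)
table = fl.roi_mean_lifetime(lt, rois)
print("\nROI mean lifetimes (ns):")
print(table.to_string(index=False))
means = table.set_index("roi")["mean_ns"]
print(f"\nleft - right difference: {means['left'] - means['right']:.3f} ns "
      f"(true 4.83 - 4.50 = 0.33 ns)")

# --- rendered map (binary output goes to scratch/) -----------------------
import matplotlib.pyplot as plt

rgb = fl.render_lifetime(lt, display_range=(3.75, 4.75))
out = Path("scratch")
out.mkdir(exist_ok=True)
plt.imsave(out / "lifetime_map.png", rgb)
print(f"wrote {out / 'lifetime_map.png'} (display range 3.75-4.75 ns)")
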