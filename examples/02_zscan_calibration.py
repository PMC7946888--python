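"""Self-calibrated axial localisation on a synthetic z-scan.

Renders a fixed 3 um bead stepped through +/-2 um in 50 nm increments
(with shot noise), runs the full pipeline — segmentation, sharpness profile,
centre of sharpness z_cs, sharpest-plane z_sp, in-situ linear rescaling —
and compares the rescaled estimate z_rcs with the known stage position.

The calibration gradient (>1) quantifies how strongly the nine-plane
sampling biases z_cs toward zero; the mean residual in the central +/-1 um
region is the axial tracking accuracy.
"""

import numpy as np

from mprheo import OpticalConfig, render_zscan, track

config = OpticalConfig()  # 0.88 um plane spacing, 3 um bead, Poisson noise
stage_z = np.arange(-2.0, 2.0 + 1e-9, 0.05)
frames = render_zscan(stage_z, config, seed=7)

result = track(frames, config, calibration="self")
central = np.abs(stage_z) <= 1.0
residual_nm = np.mean(np.abs(result.z_rcs[central] - stage_z[central])) * 1e3

print(f"rescaling gradient : {result.calibration.gradient:.2f}")
print(f"z_cs slope vs stage: {np.polyfit(stage_z[central], result.z_cs[central], 1)[0]:.2f}"
      "  (biased < 1 before rescaling)")
print(f"mean |z_rcs - z|   : {residual_nm:.1f} nm over the +/-1 um region")
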