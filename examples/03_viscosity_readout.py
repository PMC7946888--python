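"""Relative viscosity of water from the NPAF e^-1 crossing.

Simulates a water-like measurement (fluid viscosity equal to the solvent
viscosity), computes the per-axis NPAF, rescales the lag axis to the
dimensionless tau* = tau kappa / (6 pi r eta_s) using the equipartition
stiffness, and reads the relative viscosity off the e^-1 crossing.  For
water every axis should give eta_r ~ 1, and the three rescaled curves
collapse onto a single master curve.
"""

import numpy as np

from mprheo import TrapParameters, analyze_trajectory, simulate_trajectory

params = TrapParameters(
    kappa_x=1e-7, kappa_y=1e-7, kappa_z=4e-8,
    bead_radius=3e-6, solvent_viscosity=0.00095, fluid_viscosity=0.00095,
)
traj = simulate_trajectory(params, frame_rate=67.0, n_frames=100_000, seed=2)
result = analyze_trajectory(
    traj, bead_radius=params.bead_radius, solvent_viscosity=params.solvent_viscosity
)

print("axis  kappa [N/m]  FWHM [um]  eta_r")
for i, axis in enumerate("xyz"):
    print(f"{axis:>4}  {result.kappa[i]:11.3e}  {result.fwhm[i]:9.3f}  {result.eta_r[i]:5.3f}")
print(f"mean eta_r: {np.mean(result.eta_r):.3f}  (true value 1: pure solvent)")
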