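# Methods

This note records the physical models, estimators, parameter defaults and
numerical choices behind `mprheo`, and what the synthetic validation does
and does not demonstrate.

## Trapped-bead dynamics (`mprheo.trap_dynamics`)

The bead is modelled as an overdamped sphere in a 3D harmonic potential in a
Newtonian fluid. Each axis is an independent Ornstein–Uhlenbeck process with
relaxation time τ_c = 6πηr/κ and equilibrium variance k_BT/κ. The simulator
uses the **exact discrete transition**

x_{t+Δt} = x_t e^{−Δt/τ_c} + ξ √(k_BT/κ · (1 − e^{−2Δt/τ_c})),

initialised from the equilibrium distribution, so simulated statistics are
unbiased at any frame rate — important at 67 Hz, where Δt (15 ms) is not
small compared with τ_c (0.5–1.3 s for the default traps). An
Euler–Maruyama step would distort the variance and the lag-1 correlation at
coarse sampling; two tests pin the exact-transition behaviour at Δt ≫ τ_c
and Δt ≪ τ_c.

Deliberately excluded: inertia, hydrodynamic memory, Faxén wall
corrections, viscoelasticity. The analysis stage assumes a purely
exponential NPAF, and the simulator realises exactly that model. Camera
motion blur is off by default (`blur_window=1`) and available as a box
average for robustness experiments.

Defaults: T = 294 K (room temperature; configurable — the ambient
temperature of a given instrument must be supplied by the user), k_B fixed
at 1.380649e-23 J/K, solvent viscosity 0.00095 Pa·s (water near 22 °C).
Trap stiffnesses outside 1e-9–1e-5 N/m trigger a warning, not an error.

## Image formation (`mprheo.imaging`)

Each camera frame is a 3×3 grid of 64 px sub-images (0.1833 µm/px — an
11 µm camera pixel behind a 60× objective), one per object plane
z = nΔz, n = −4…+4, Δz = 0.88 µm by default. The tile→plane arrangement
depends on the grating orientation and is therefore configuration
(`tile_layout`), defaulting to row-major +4…−4.

The bead is a projected disk of its diameter convolved with an isotropic
Gaussian of width σ(n) = √(σ₀² + (s·|z − nΔz|)²). The convolution has the
closed form 1 − Q₁(ρ/σ, R/σ) (Marcum Q), evaluated through the non-central
χ² CDF on a radial grid and interpolated onto the pixel grid. The amplitude
is set by the in-focus peak contrast; because convolution conserves the
integral, the background-subtracted signal sum is identical in every plane
(verified to <1%) while the peak falls with defocus. Shot noise is Poisson
per pixel on background + signal; frames are integer-quantised either way.

Defaults chosen once on physical grounds: σ₀ = 0.15 µm (≈ diffraction-
limited Gaussian width at NA 1.2, 532 nm), defocus slope s = 0.35 µm of
blur width per µm of defocus (a geometric-blur growth rate moderated for a
high-NA transmission system), background 100 counts, peak contrast 400
counts.

**What this model is not.** Real transmission images of a micron bead show
concentric diffraction rings and contrast reversals through focus; this
renderer produces a monotone blur. That is sufficient — by construction —
for the one property the localisation method relies on: a unimodal,
symmetric sharpness-versus-defocus curve. Passing the synthetic acceptance
bounds therefore validates the *algorithmic chain* (segmentation →
sharpness → z_CS/z_SP → calibration → z_RCS) under realistic photon noise,
not the radiometric fidelity of any particular instrument; absolute
accuracies on real data depend on the real sharpness curve's shape and
stability.

## Localisation (`mprheo.localization`)

Per frame: the tiled image is split losslessly into nine sub-images; a
single Otsu threshold is computed on the pooled stack (pooling keeps a
strongly defocused plane from losing the bead); the lateral position is the
intensity centroid of the thresholded **sharpest plane's** sub-image (best
SNR; a sharpness-weighted multi-plane average is a documented alternative,
config-exposed); the sharpness metric S = Σ(I²−I)/(ΣI)² is evaluated on
each plane after subtracting the per-plane median and taking absolute
values (median: robust while the bead covers <25% of the tile; absolute
value: dark and bright beads score identically).

Axial estimates: z_CS (sharpness-weighted mean of plane depths) and z_SP
(sharpest-plane depth shifted Δz/4 toward the runner-up; exact sharpness
ties break toward the plane nearer the mid-plane, then the lower index — a
measure-zero case under noise). z_SP lives on the lattice {nΔz ± Δz/4}
and steps by exactly Δz/2.

**Calibration.** Because the nine planes undersample the sharpness curve,
z_CS compresses real motion (slope ≈ 0.2–0.6 versus truth, depending on
bead size and blur). The in-situ fit regresses the z_SP staircase on
median-centred z_CS by ordinary least squares, restricted to the linear
regime: |z_SP| ≤ 2Δz and frames whose sharpest plane is an edge plane
(|n| ≥ 3) are dropped. The median-centring makes the trap centre map to
z ≈ 0 and the fitted intercept near zero. At least 20 samples spanning ≥ 3
distinct staircase steps are required. This is a deliberately simple,
documented approximation of the de-biasing a production instrument would
tune; its adequacy is judged by the end-to-end residual bounds.

**Plane-spacing characterisation.** For each plane, the stage position
maximising its sharpness over a ±4 µm scan is located by fitting a
quadratic over the samples within ±0.4 µm of the discrete argmax; Δz is the
slope of peak position versus plane index. A 3-point parabolic vertex was
rejected: with Poisson noise at 50 nm steps its variance dominates the
estimate (errors ~3%), while the windowed fit is unbiased for a symmetric
peak and recovers the spacing to ~0.5%. Planes whose maximum falls on a
scan boundary are excluded with a warning; at least three usable planes are
required.

Conventions: pixel centres at integer indices, origin at the sub-image
centre; z increases with plane index; the trap centre defines z = 0 after
calibration centring.

## Microrheology (`mprheo.rheology`)

- κ = k_BT/⟨x²⟩ per axis (variance about the sample mean — the trap centre
  is not known a priori). At 67 Hz a 1e5-frame run carries only
  N_eff ≈ NΔt/2τ_c ≈ 1.4e3 independent samples, so a single-run κ estimate
  has ≈4% standard error; accuracy statements are made on means over
  repeated runs.
- NPAF/NMSD: all-pairs (overlapping) estimators at ~120 log-spaced integer
  lags, mean-subtracted, normalised by the sample variance; max lag
  defaults to duration/10 to bound estimator variance. NPAF(0) = 1 and
  NMSD(0) = 0 exactly; the stationarity identity NMSD + NPAF = 1 holds to
  <0.02 at 1e5 samples. The variance-normalised ACF is a ratio estimator
  with an O(1/N_eff) bias (~1e-3 at these sizes) — visible only when
  averaging many seeds, and immaterial for the viscosity read-out.
- τ* rescaling multiplies lags by κ/(6πrη_s) with the *estimated* κ, so the
  read-out needs no prior knowledge of the trap. The e⁻¹ crossing is
  located by linear interpolation of NPAF against log τ* between the
  bracketing samples (the curve is exponential-like, hence near-linear in
  log-lag there); a missing crossing raises an error naming the ≳10 τ_c
  duration requirement.
- FWHM = 2√(2 ln 2)·σ from the sample standard deviation (the equilibrium
  distribution is Gaussian by model); histogram peak-finding would be far
  noisier at realistic sample counts.
- Allan deviation: overlapping variant over octave-spaced cluster sizes up
  to N/4 — a decaying curve is the drift-free signature; linear drift makes
  it grow linearly with cluster time. Used as a qualitative diagnostic only.

## Problem sizes and reproducibility

Validation runs use the study-scale conditions throughout: 1e5 frames at
67 Hz for trajectory statistics; ±2 µm z-scans in 50 nm steps (81 frames)
for localisation accuracy; ±4 µm (161 frames) for plane-spacing
characterisation; the five-measurement viscosity protocol uses bead
diameters 6–8 µm. Every stochastic element (OU innovations, Poisson shot
noise) flows from a single integer seed through `numpy.random.Generator`,
and identical seeds give bit-identical trajectories, frames and CSV
outputs. The 6 µm-bead scans use 96 px tiles: a 6 µm bead plus defocus blur
does not fit the default 11.7 µm tile, and matching the field of view to
the bead is exactly what an experimenter would do.

## Known limitations

- The Newtonian assumption is structural: NPAF = exp(−τ/τ_c) is both
  simulated and assumed; no viscoelastic moduli are extracted.
- The image model omits diffraction rings, aberrations, read noise and
  pixel-response non-uniformity.
- The calibration's linear-regime restriction fails for very large beads or
  very weak traps, where the bead leaves the linear window of z_CS; the
  errors then are systematic underestimates of axial motion, not noise.
- Single-particle only: no detection/linking of multiple beads.
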