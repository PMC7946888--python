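"""Brownian dynamics of an optically trapped bead in a Newtonian fluid.

An overdamped bead in a harmonic trap performs, along each axis, a stationary
Ornstein-Uhlenbeck (OU) process with relaxation time

    tau_c = 6 * pi * eta * r / kappa

where ``eta`` is the fluid viscosity, ``r`` the bead radius and ``kappa`` the
trap stiffness along that axis.  The normalised position autocorrelation
function (NPAF) is then ``exp(-lag / tau_c)`` and the normalised mean squared
displacement (NMSD) is its complement; both closed forms are exposed here as
analytic oracles for the estimators in :mod:`mprheo.rheology`.

The simulator uses the exact OU transition density rather than an
Euler-Maruyama step, so simulated statistics are unbiased at any frame rate,
including rates where the frame interval is comparable to ``tau_c``.  Inertia,
hydrodynamic memory and wall corrections are deliberately absent: the analysis
this package implements assumes a purely exponential NPAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .constants import K_B
from .errors import InvalidParameterError

__all__ = [
    "TrapParameters",
    "Trajectory",
    "relaxation_time",
    "analytic_npaf",
    "analytic_nmsd",
    "simulate_trajectory",
]

_AXES = {"x": 0, "y": 1, "z": 2}

#: Trap stiffnesses outside this range are physically implausible for
#: optical tweezers and trigger a warning (not an error).
_PLAUSIBLE_KAPPA = (1e-9, 1e-5)


def _axis_index(axis: str | int) -> int:
    if isinstance(axis, str):
        try:
            return _AXES[axis.lower()]
        except KeyError:
            raise InvalidParameterError(f"unknown axis {axis!r}; expected one of x, y, z") from None
    if axis in (0, 1, 2):
        return int(axis)
    raise InvalidParameterError(f"unknown axis {axis!r}; expected one of x, y, z")


@dataclass(frozen=True)
class TrapParameters:
    """Physical parameters of the trap, bead and fluid (SI units).

    Parameters
    ----------
    kappa_x, kappa_y, kappa_z
        Trap stiffness along each axis [N/m].
    temperature_K
        Absolute temperature [K].  Default 294 K (room temperature).
    bead_radius
        Bead radius [m].
    solvent_viscosity
        Viscosity of the pure solvent [Pa s], used to non-dimensionalise
        lag-times.
    fluid_viscosity
        Viscosity of the (possibly bead-loaded or solute-bearing) fluid the
        bead actually moves in [Pa s]; equals ``solvent_viscosity`` for a
        pure-solvent measurement.
    """

    kappa_x: float
    kappa_y: float
    kappa_z: float
    temperature_K: float = 294.0
    bead_radius: float = 3e-6
    solvent_viscosity: float = 0.00095
    fluid_viscosity: float = 0.00095

    def __post_init__(self) -> None:
        for name in (
            "kappa_x",
            "kappa_y",
            "kappa_z",
            "temperature_K",
            "bead_radius",
            "solvent_viscosity",
            "fluid_viscosity",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
        for name in ("kappa_x", "kappa_y", "kappa_z"):
            value = getattr(self, name)
            if not (_PLAUSIBLE_KAPPA[0] <= value <= _PLAUSIBLE_KAPPA[1]):
                warnings.warn(
                    f"{name} = {value:g} N/m is outside the plausible optical-trap "
                    f"range [{_PLAUSIBLE_KAPPA[0]:g}, {_PLAUSIBLE_KAPPA[1]:g}] N/m",
                    stacklevel=3,
                )

    def kappa(self, axis: str | int) -> float:
        """Trap stiffness along ``axis`` [N/m]."""
        return (self.kappa_x, self.kappa_y, self.kappa_z)[_axis_index(axis)]

    def equilibrium_std(self, axis: str | int) -> float:
        """Equipartition standard deviation sqrt(k_B T / kappa) [m]."""
        return float(np.sqrt(K_B * self.temperature_K / self.kappa(axis)))


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled 3D bead positions relative to the trap centre.

    ``positions`` is a (3, N) array in micrometres, rows ordered x, y, z.
    """

    times: np.ndarray
    positions: np.ndarray
    frame_rate: float
    seed: int | None = None
    params: TrapParameters | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if times.ndim != 1 or times.size < 2:
            raise InvalidParameterError("times must be a 1D array with at least 2 samples")
        if positions.shape != (3, times.size):
            raise InvalidParameterError(
                f"positions must have shape (3, {times.size}), got {positions.shape}"
            )
        if not np.all(np.isfinite(positions)):
            raise InvalidParameterError("positions contain non-finite values")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=0):
            raise InvalidParameterError("times must be uniformly spaced (rtol 1e-9)")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def axis(self, axis: str | int) -> np.ndarray:
        """Position series along one axis [um]."""
        return self.positions[_axis_index(axis)]


def relaxation_time(params: TrapParameters, axis: str | int) -> float:
    """Trap relaxation time tau_c = 6 pi eta r / kappa [s].

    This is the decay constant of the exponential NPAF for a Newtonian fluid
    of viscosity ``params.fluid_viscosity``.
    """
    kappa = params.kappa(axis)
    return 6.0 * np.pi * params.fluid_viscosity * params.bead_radius / kappa


def analytic_npaf(
    params: TrapParameters, axis: str | int, lag: float | np.ndarray
) -> float | np.ndarray:
    """Closed-form NPAF(lag) = exp(-lag / tau_c) for a Newtonian fluid."""
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise InvalidParameterError("lag must be non-negative")
    out = np.exp(-lag / relaxation_time(params, axis))
    return float(out) if out.ndim == 0 else out


def analytic_nmsd(
    params: TrapParameters, axis: str | int, lag: float | np.ndarray
) -> float | np.ndarray:
    """Closed-form NMSD(lag) = 1 - exp(-lag / tau_c) for a Newtonian fluid."""
    return 1.0 - analytic_npaf(params, axis, lag)


def simulate_trajectory(
    params: TrapParameters,
    frame_rate: float,
    n_frames: int,
    seed: int | np.random.Generator,
    blur_window: int = 1,
) -> Trajectory:
    """Simulate a stationary OU trajectory of a trapped bead.

    Each axis follows the exact discrete OU update

        x[t+1] = x[t] * exp(-dt/tau_c) + xi * sqrt(var_eq * (1 - exp(-2 dt/tau_c)))

    with ``var_eq = k_B T / kappa`` and ``xi`` standard normal; the initial
    position is drawn from the equilibrium distribution, so the series is
    stationary from the first sample.  Axes are independent.

    Parameters
    ----------
    frame_rate
        Sampling rate [Hz].
    n_frames
        Number of samples (>= 2).
    seed
        Integer seed or a ``numpy.random.Generator``; the same seed always
        yields a bit-identical trajectory.
    blur_window
        Optional camera motion-blur emulation: a centred box average over
        this many consecutive samples (1 = off).  Intended for robustness
        tests only; the default analysis assumes instantaneous sampling.

    Returns
    -------
    Trajectory
        Positions in micrometres, rows x, y, z.
    """
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    if frame_rate <= 0:
        raise InvalidParameterError("frame_rate must be positive")
    if blur_window < 1:
        raise InvalidParameterError("blur_window must be >= 1")
    rng = np.random.default_rng(seed)
    seed_out = int(seed) if isinstance(seed, (int, np.integer)) else None

    dt = 1.0 / frame_rate
    positions = np.empty((3, n_frames))
    for i, axis in enumerate(("x", "y", "z")):
        tau_c = relaxation_time(params, axis)
        phi = np.exp(-dt / tau_c)
        sigma_eq_um = params.equilibrium_std(axis) * 1e6
        # Driving sequence: w[0] is the equilibrium draw, the rest are the
        # exact-transition innovations; the AR(1) filter realises the update.
        w = rng.standard_normal(n_frames)
        w[1:] *= sigma_eq_um * np.sqrt(1.0 - phi * phi)
        w[0] *= sigma_eq_um
        positions[i] = lfilter([1.0], [1.0, -phi], w)
    if blur_window > 1:
        kernel = np.full(blur_window, 1.0 / blur_window)
        positions = np.apply_along_axis(
            lambda x: np.convolve(x, kernel, mode="same"), 1, positions
        )
    times = np.arange(n_frames) * dt
    return Trajectory(
        times=times, positions=positions, frame_rate=frame_rate, seed=seed_out, params=params
    )
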