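"""Passive microrheology of a trapped bead from its 3D trajectory.

For an overdamped bead in a harmonic trap in a Newtonian fluid the normalised
position autocorrelation function and normalised mean squared displacement
satisfy

    NMSD(tau) = 1 - NPAF(tau) = 1 - exp(-kappa * tau / (6 pi eta r))

with the trap stiffness estimated by equipartition, kappa = k_B T / <x^2>.
Plotting NPAF against the dimensionless lag-time

    tau* = tau * kappa / (6 pi r eta_s)

(eta_s the solvent viscosity) collapses all axes onto one master curve, and
the tau* at which NPAF crosses e^-1 reads off the relative viscosity
eta_r = eta / eta_s directly — for water, tau* ~ 1 on every axis.

The module also provides the equilibrium trap-volume FWHM per axis and an
overlapping Allan deviation as a drift diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .constants import K_B
from .errors import (
    DegenerateImageError,
    InvalidParameterError,
    TrajectoryTooShortError,
)
from .trap_dynamics import Trajectory, _axis_index

__all__ = [
    "CorrelationCurve",
    "RheologyResult",
    "trap_stiffness",
    "compute_npaf",
    "compute_nmsd",
    "rescale_lags",
    "relative_viscosity",
    "fwhm",
    "allan_deviation",
    "analyze_trajectory",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548... for a Gaussian


@dataclass(frozen=True)
class CorrelationCurve:
    """NPAF/NMSD versus lag (seconds, or dimensionless tau* if rescaled)."""

    lags: np.ndarray
    npaf: np.ndarray
    nmsd: np.ndarray
    axis: str
    n_pairs: np.ndarray
    dimensionless: bool = False

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        if np.any(np.diff(lags) <= 0):
            raise InvalidParameterError("lags must be strictly increasing")
        for name in ("npaf", "nmsd"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise InvalidParameterError(f"{name} contains non-finite values")
        if self.npaf[0] > 1.0 + 1e-12:
            raise InvalidParameterError("npaf at the first lag exceeds 1")


@dataclass(frozen=True)
class RheologyResult:
    """Per-axis trap and fluid read-outs (arrays ordered x, y, z)."""

    kappa: np.ndarray  # [N/m]
    variance: np.ndarray  # [um^2]
    fwhm: np.ndarray  # [um]
    eta_r: np.ndarray  # relative viscosity, dimensionless
    temperature_K: float
    bead_radius_um: float
    solvent_viscosity: float


def _axis_series(traj: Trajectory, axis: str | int) -> np.ndarray:
    series = traj.axis(axis)
    if series.size < 1000:
        warnings.warn(
            f"only {series.size} samples on axis {axis}: estimates will be noisy "
            "(>= 1000 recommended)",
            stacklevel=3,
        )
    return series


def trap_stiffness(traj: Trajectory, axis: str | int, temperature_K: float = 294.0) -> float:
    """Equipartition trap stiffness kappa = k_B T / <x^2> [N/m].

    The variance is taken about the sample mean (the trap centre is not known
    a priori) and converted from um^2 to m^2.
    """
    if temperature_K <= 0:
        raise InvalidParameterError("temperature_K must be positive")
    series = _axis_series(traj, axis)
    var_um2 = float(np.var(series))
    if var_um2 <= 0:
        raise DegenerateImageError("zero position variance: degenerate trajectory")
    return K_B * temperature_K / (var_um2 * 1e-12)


def _log_lags(n: int, max_lag_frames: int, n_lags: int = 120) -> np.ndarray:
    max_lag_frames = min(max_lag_frames, n - 1)
    dense = np.unique(
        np.rint(np.logspace(0, np.log10(max_lag_frames), n_lags)).astype(int)
    )
    return np.concatenate(([0], dense[dense >= 1]))


def _correlations(traj: Trajectory, axis: str | int, max_lag: float | None):
    series = _axis_series(traj, axis)
    if max_lag is None:
        max_lag = traj.duration / 10.0
    max_lag_frames = int(np.floor(max_lag * traj.frame_rate))
    if max_lag_frames < 1:
        raise TrajectoryTooShortError(
            f"max_lag {max_lag:g} s is below one frame interval ({traj.dt:g} s)"
        )
    x = series - series.mean()
    var = float(np.mean(x * x))
    if var <= 0:
        raise DegenerateImageError("zero position variance: degenerate trajectory")
    lags = _log_lags(series.size, max_lag_frames)
    npaf = np.empty(lags.size)
    nmsd = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for i, k in enumerate(lags):
        if k == 0:
            npaf[i], nmsd[i], n_pairs[i] = 1.0, 0.0, series.size
            continue
        a, b = x[:-k], x[k:]
        npaf[i] = float(np.mean(a * b)) / var
        nmsd[i] = float(np.mean((b - a) ** 2)) / (2.0 * var)
        n_pairs[i] = a.size
    return lags * traj.dt, npaf, nmsd, n_pairs


def compute_npaf(traj: Trajectory, axis: str | int, max_lag: float | None = None) -> CorrelationCurve:
    """Empirical NPAF(tau) = <x(t) x(t+tau)> / <x^2> at log-spaced lags.

    All available (overlapping) pairs contribute at each lag; the series is
    mean-subtracted first.  ``max_lag`` defaults to a tenth of the duration
    to bound estimator variance.  The NMSD over the same lags rides along in
    the returned curve.
    """
    lags, npaf, nmsd, n_pairs = _correlations(traj, axis, max_lag)
    return CorrelationCurve(
        lags=lags, npaf=npaf, nmsd=nmsd, axis=str(axis), n_pairs=n_pairs
    )


def compute_nmsd(traj: Trajectory, axis: str | int, max_lag: float | None = None) -> CorrelationCurve:
    """Empirical NMSD(tau) = <(x(t+tau) - x(t))^2> / (2 <x^2>).

    For a stationary series NMSD = 1 - NPAF up to estimator noise; both are
    returned on the same lag grid.
    """
    return compute_npaf(traj, axis, max_lag)


def rescale_lags(
    curve: CorrelationCurve,
    kappa: float,
    bead_radius: float,
    solvent_viscosity: float,
) -> CorrelationCurve:
    """Re-express the lag axis as dimensionless tau* = tau kappa / (6 pi r eta_s).

    ``kappa`` in N/m, ``bead_radius`` in metres, ``solvent_viscosity`` in
    Pa s.  Curve values are unchanged.
    """
    if kappa <= 0 or bead_radius <= 0 or solvent_viscosity <= 0:
        raise InvalidParameterError("kappa, bead_radius and solvent_viscosity must be positive")
    factor = kappa / (6.0 * np.pi * bead_radius * solvent_viscosity)
    return replace(curve, lags=curve.lags * factor, dimensionless=True)


def relative_viscosity(curve: CorrelationCurve) -> float:
    """Relative viscosity: the tau* at which NPAF first crosses e^-1.

    The crossing is located by linear interpolation of NPAF against
    log(tau*) between the bracketing samples (NPAF is exponential-like, so it
    is near-linear in log-lag around the crossing).  Expects a curve already
    rescaled to dimensionless lag.
    """
    if not curve.dimensionless:
        raise InvalidParameterError("curve must be rescaled to dimensionless tau* first")
    target = np.exp(-1.0)
    lags, npaf = curve.lags, curve.npaf
    positive = lags > 0
    lags, npaf = lags[positive], npaf[positive]
    below = np.nonzero(npaf <= target)[0]
    crossing = None
    for j in below:
        if j > 0 and npaf[j - 1] > target:
            crossing = j
            break
    if crossing is None:
        raise TrajectoryTooShortError(
            "NPAF never crosses e^-1 within the lag range: the trajectory is too "
            "short (a duration of at least ~10 relaxation times is required)"
        )
    i = crossing - 1
    log_lo, log_hi = np.log(lags[i]), np.log(lags[crossing])
    frac = (npaf[i] - target) / (npaf[i] - npaf[crossing])
    return float(np.exp(log_lo + frac * (log_hi - log_lo)))


def fwhm(traj: Trajectory, axis: str | int) -> float:
    """FWHM of the equilibrium position distribution [um].

    The trap potential is harmonic, so the distribution is Gaussian and
    FWHM = 2 sqrt(2 ln 2) sigma; using the sample standard deviation is far
    more robust than histogram peak-finding at typical sample counts.
    """
    series = _axis_series(traj, axis)
    sigma = float(np.std(series))
    if sigma <= 0:
        raise DegenerateImageError("zero position variance: degenerate trajectory")
    return _FWHM_FACTOR * sigma


def allan_deviation(
    traj: Trajectory, axis: str | int, cluster_sizes: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping Allan deviation of the position series.

    sigma_A(tau) = sqrt(0.5 <(m_{i+1} - m_i)^2>) over consecutive (overlapping)
    cluster means of ``m`` samples, tau = m * dt.  A decaying curve indicates
    a drift-free measurement; linear instrumental drift makes it grow with
    cluster time.  Cluster sizes default to octaves up to a quarter of the
    series length.

    Returns ``(cluster_times_s, adev_um)``.
    """
    series = traj.axis(axis)
    n = series.size
    if cluster_sizes is None:
        max_m = n // 4
        if max_m < 1:
            raise TrajectoryTooShortError("trajectory too short for Allan deviation")
        cluster_sizes = 2 ** np.arange(int(np.log2(max_m)) + 1)
    cluster_sizes = np.asarray(cluster_sizes, dtype=int)
    if np.any(cluster_sizes < 1) or np.any(cluster_sizes > n // 4):
        raise InvalidParameterError("cluster sizes must be in [1, n_frames/4]")
    cumsum = np.concatenate(([0.0], np.cumsum(series)))
    adev = np.empty(cluster_sizes.size)
    for i, m in enumerate(cluster_sizes):
        means = (cumsum[m:] - cumsum[:-m]) / m  # overlapping cluster means
        diffs = means[m:] - means[:-m]
        adev[i] = np.sqrt(0.5 * np.mean(diffs * diffs))
    return cluster_sizes * traj.dt, adev


def analyze_trajectory(
    traj: Trajectory,
    temperature_K: float = 294.0,
    bead_radius: float = 3e-6,
    solvent_viscosity: float = 0.00095,
    max_lag: float | None = None,
) -> RheologyResult:
    """Full per-axis read-out: stiffness, FWHM and relative viscosity.

    ``bead_radius`` in metres, ``solvent_viscosity`` in Pa s.
    """
    kappa = np.empty(3)
    variance = np.empty(3)
    widths = np.empty(3)
    eta_r = np.empty(3)
    for i, axis in enumerate(("x", "y", "z")):
        kappa[i] = trap_stiffness(traj, axis, temperature_K)
        variance[i] = float(np.var(traj.axis(axis)))
        widths[i] = fwhm(traj, axis)
        curve = compute_npaf(traj, axis, max_lag=max_lag)
        curve = rescale_lags(curve, kappa[i], bead_radius, solvent_viscosity)
        eta_r[i] = relative_viscosity(curve)
    return RheologyResult(
        kappa=kappa,
        variance=variance,
        fwhm=widths,
        eta_r=eta_r,
        temperature_K=temperature_K,
        bead_radius_um=bead_radius * 1e6,
        solvent_viscosity=solvent_viscosity,
    )
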