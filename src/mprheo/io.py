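"""File formats: multi-page TIFF frames, CSV trajectories/logs, YAML configs.

Units are fixed in the schemas and encoded in the column names (um, seconds,
N/m, Pa s).  CSV floats are written with 9 significant digits; TIFF
round-trips are exact.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, InvalidParameterError
from .imaging import OpticalConfig, RawFrame
from .localization import CalibrationModel, TrackingResult
from .rheology import CorrelationCurve, RheologyResult
from .trap_dynamics import Trajectory, TrapParameters

__all__ = [
    "write_frames",
    "read_frames",
    "write_truth",
    "read_truth",
    "write_trajectory",
    "read_trajectory",
    "write_stage_log",
    "read_stage_log",
    "write_config",
    "read_config",
    "write_tracking_result",
    "write_curve",
    "write_rheology_result",
    "tracking_to_trajectory",
]

_FLOAT_FMT = "%.9g"

_TRAJ_COLUMNS = ("time_s", "x_um", "y_um", "z_um")


# ---------------------------------------------------------------- frames ----

def write_frames(path: str | Path, frames: Sequence[RawFrame]) -> None:
    """Write frames as a multi-page TIFF, one page per time point."""
    tifffile.imwrite(str(path), np.stack([f.image for f in frames]))


def read_frames(path: str | Path, frame_rate: float | None = None) -> list[RawFrame]:
    """Read a multi-page TIFF; timestamps are frame_index / frame_rate."""
    try:
        pages = tifffile.imread(str(path))
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise FormatError(f"{path}: cannot read TIFF stack: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    dt = 1.0 / frame_rate if frame_rate else 1.0
    return [RawFrame(image=page, timestamp=i * dt) for i, page in enumerate(pages)]


def write_truth(path: str | Path, frames: Sequence[RawFrame]) -> None:
    """Ground-truth sidecar CSV (frame, x_um, y_um, z_um) for rendered frames."""
    rows = []
    for i, frame in enumerate(frames):
        if frame.truth is None:
            raise FormatError(f"frame {i} carries no ground truth")
        rows.append((i, *frame.truth))
    pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "z_um"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_truth(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ("frame", "x_um", "y_um", "z_um"))


# ---------------------------------------------------------- trajectories ----

def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    pd.DataFrame(
        {
            "time_s": traj.times,
            "x_um": traj.positions[0],
            "y_um": traj.positions[1],
            "z_um": traj.positions[2],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    for column in required:
        if column not in df.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    return df


def read_trajectory(path: str | Path, frame_rate: float | None = None) -> Trajectory:
    """Read a trajectory CSV (time_s, x_um, y_um, z_um).

    Timestamps are validated as uniformly spaced (to within 1% of the frame
    interval, which tolerates decimal rounding in the file) and then snapped
    onto the exact uniform grid the schema implies.
    """
    df = _read_csv(path, _TRAJ_COLUMNS)
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise FormatError(f"{path}: trajectory needs at least 2 rows")
    dt = (times[-1] - times[0]) / (times.size - 1)
    if dt <= 0:
        raise FormatError(f"{path}: time_s must be strictly increasing")
    grid = times[0] + np.arange(times.size) * dt
    if np.abs(times - grid).max() > 0.01 * dt:
        raise FormatError(f"{path}: time_s is not uniformly sampled")
    if frame_rate is None:
        frame_rate = 1.0 / dt
    positions = np.vstack([df[c].to_numpy(dtype=float) for c in ("x_um", "y_um", "z_um")])
    return Trajectory(times=grid, positions=positions, frame_rate=frame_rate)


def write_stage_log(path: str | Path, stage_z: np.ndarray) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(stage_z)), "stage_z_um": np.asarray(stage_z, dtype=float)}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_stage_log(path: str | Path) -> np.ndarray:
    df = _read_csv(path, ("frame", "stage_z_um"))
    return df.sort_values("frame")["stage_z_um"].to_numpy(dtype=float)


# --------------------------------------------------------------- configs ----

_CONFIG_KINDS = {
    "optical_config": OpticalConfig,
    "trap_parameters": TrapParameters,
    "calibration_model": CalibrationModel,
}


def write_config(path: str | Path, obj) -> None:
    """Serialise a config dataclass to YAML with a ``kind`` tag."""
    for kind, cls in _CONFIG_KINDS.items():
        if isinstance(obj, cls):
            payload = {"kind": kind, **dataclasses.asdict(obj)}
            break
    else:
        raise FormatError(f"unsupported config object of type {type(obj).__name__}")
    for key, value in payload.items():
        if isinstance(value, tuple):
            payload[key] = list(value)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_config(path: str | Path):
    """Read a YAML config written by :func:`write_config` (validated on load)."""
    try:
        payload = yaml.safe_load(Path(path).read_text())
    except (yaml.YAMLError, FileNotFoundError) as exc:
        raise FormatError(f"{path}: cannot read config: {exc}") from exc
    if not isinstance(payload, dict) or "kind" not in payload:
        raise FormatError(f"{path}: config must be a mapping with a 'kind' key")
    kind = payload.pop("kind")
    try:
        cls = _CONFIG_KINDS[kind]
    except KeyError:
        raise FormatError(f"{path}: unknown config kind {kind!r}") from None
    for key, value in payload.items():
        if isinstance(value, list):
            payload[key] = tuple(value)
    try:
        return cls(**payload)
    except TypeError as exc:
        raise FormatError(f"{path}: invalid {kind} config: {exc}") from exc
    except InvalidParameterError as exc:
        raise FormatError(f"{path}: invalid {kind} config: {exc}") from exc


# --------------------------------------------------------------- results ----

def write_tracking_result(path: str | Path, result: TrackingResult) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(result.n_frames),
            "time_s": result.times,
            "x_um": result.x,
            "y_um": result.y,
            "z_cs_um": result.z_cs,
            "z_sp_um": result.z_sp,
            "z_rcs_um": result.z_rcs,
            "sharpest_plane": result.sharpest_plane,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def tracking_to_trajectory(result: TrackingResult) -> Trajectory:
    """Repackage tracked coordinates (x, y, z_rcs) as a Trajectory."""
    if result.frame_rate is None:
        raise FormatError("tracking result has no uniform frame rate")
    return Trajectory(
        times=result.times - result.times[0],
        positions=np.vstack([result.x, result.y, result.z_rcs]),
        frame_rate=result.frame_rate,
    )


def write_curve(path: str | Path, curve: CorrelationCurve) -> None:
    lag_column = "tau_star" if curve.dimensionless else "lag_s"
    pd.DataFrame(
        {
            lag_column: curve.lags,
            "nmsd": curve.nmsd,
            "npaf": curve.npaf,
            "n_pairs": curve.n_pairs,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_rheology_result(path: str | Path, result: RheologyResult) -> None:
    pd.DataFrame(
        {
            "axis": ["x", "y", "z"],
            "kappa_N_per_m": result.kappa,
            "variance_um2": result.variance,
            "fwhm_um": result.fwhm,
            "eta_r": result.eta_r,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
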