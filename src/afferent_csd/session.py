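"""Session data model and portable HDF5 container.

A :class:`RecordingSession` bundles everything one imaging session produces
after registration and ROI extraction: raw ROI and neuropil fluorescence
traces, ROI centroid positions, a spatially binned background-fluorescence
movie, the wheel-position series, per-frame affine registration parameters
and Z-shifts, and the CSD trigger frame (if a CSD was induced).

Conventions
-----------
* Frame ``k`` is timestamped ``t_k = k / frame_rate_hz`` (0-based, frame 0 at
  acquisition start); wheel samples analogously at ``wheel_rate_hz``.
* Image coordinates are in micrometres, 0-based, origin at the top-left
  corner of the field of view; ``x`` increases laterally and ``y`` increases
  posteriorly, so "anterior" maps to ``-y`` (recorded in metadata).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

__all__ = [
    "RecordingSession",
    "FiberMap",
    "SessionValidationError",
    "read_session",
    "write_session",
    "export_traces_csv",
    "SCHEMA_VERSION",
]


class SessionValidationError(ValueError):
    """Raised when a session violates a structural invariant."""


@dataclass
class RecordingSession:
    session_id: str
    frame_rate_hz: float
    roi_traces: np.ndarray          # [n_roi, n_frames] raw F_ROI
    neuropil_traces: np.ndarray     # [n_roi, n_frames] background-mask F_np
    roi_centroids_um: np.ndarray    # [n_roi, 2] (x, y), top-left origin
    background_grid: np.ndarray     # [n_bins_y, n_bins_x, n_frames]
    wheel_position: np.ndarray      # encoder units at wheel_rate_hz
    affine_linear: np.ndarray       # [n_frames, 2, 2]
    affine_translation: np.ndarray  # [n_frames, 2] pixels
    zshift_series: np.ndarray       # [n_frames] plane units, + toward skull
    wheel_rate_hz: float = 15.5
    fov_size_um: tuple[float, float] = (626.0, 423.0)
    pixel_size_um: float = 1.223
    bin_size_px: int = 40
    plane_spacing_um: float = 5.0
    csd_trigger_frame: int | None = None
    anterior_axis: str = "-y"
    meta: dict = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return int(self.roi_traces.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.roi_traces.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def wheel_times(self) -> np.ndarray:
        return np.arange(len(self.wheel_position)) / self.wheel_rate_hz

    def validate(self) -> "RecordingSession":
        """Check every structural invariant; raise on the first violation."""
        if self.frame_rate_hz <= 0 or self.wheel_rate_hz <= 0:
            raise SessionValidationError("sampling rates must be positive")
        if self.pixel_size_um <= 0 or self.bin_size_px <= 0:
            raise SessionValidationError("pixel/bin geometry must be positive")
        rt = np.asarray(self.roi_traces)
        npil = np.asarray(self.neuropil_traces)
        if rt.ndim != 2:
            raise SessionValidationError("roi_traces must be 2-D [n_roi, n_frames]")
        if npil.shape != rt.shape:
            raise SessionValidationError(
                f"neuropil_traces shape {npil.shape} does not match "
                f"roi_traces shape {rt.shape}"
            )
        n_frames = rt.shape[1]
        cents = np.asarray(self.roi_centroids_um)
        if cents.shape != (rt.shape[0], 2):
            raise SessionValidationError(
                f"roi_centroids_um shape {cents.shape} inconsistent with "
                f"{rt.shape[0]} ROIs"
            )
        bg = np.asarray(self.background_grid)
        if bg.ndim != 3 or bg.shape[2] != n_frames:
            raise SessionValidationError(
                "background_grid must be [n_bins_y, n_bins_x, n_frames]; got "
                f"{bg.shape} with n_frames={n_frames}"
            )
        # bin counts must tile the FOV at the declared pixel size
        npx_x = int(round(self.fov_size_um[0] / self.pixel_size_um))
        npx_y = int(round(self.fov_size_um[1] / self.pixel_size_um))
        exp_bins = (npx_y // self.bin_size_px, npx_x // self.bin_size_px)
        if bg.shape[:2] != exp_bins:
            raise SessionValidationError(
                f"background_grid bins {bg.shape[:2]} inconsistent with FOV "
                f"{self.fov_size_um} um at {self.pixel_size_um} um/px and "
                f"bin size {self.bin_size_px} px (expected {exp_bins})"
            )
        for name in ("affine_linear", "affine_translation", "zshift_series"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n_frames:
                raise SessionValidationError(
                    f"{name} has {arr.shape[0]} frames, traces have {n_frames}"
                )
        if np.asarray(self.affine_linear).shape[1:] != (2, 2):
            raise SessionValidationError("affine_linear must be [n_frames, 2, 2]")
        if np.asarray(self.affine_translation).shape[1:] != (2,):
            raise SessionValidationError("affine_translation must be [n_frames, 2]")
        # durations must agree across rates to within one sample period
        dur_frames = n_frames / self.frame_rate_hz
        dur_wheel = len(self.wheel_position) / self.wheel_rate_hz
        tol = 1.0 / self.frame_rate_hz + 1.0 / self.wheel_rate_hz
        if abs(dur_frames - dur_wheel) > tol:
            raise SessionValidationError(
                f"wheel series spans {dur_wheel:.2f} s but frames span "
                f"{dur_frames:.2f} s"
            )
        for name in (
            "roi_traces", "neuropil_traces", "roi_centroids_um",
            "background_grid", "wheel_position", "affine_linear",
            "affine_translation", "zshift_series",
        ):
            if not np.all(np.isfinite(np.asarray(getattr(self, name)))):
                raise SessionValidationError(f"{name} contains non-finite values")
        if self.csd_trigger_frame is not None:
            t = int(self.csd_trigger_frame)
            if not 0 <= t < n_frames:
                raise SessionValidationError(
                    f"csd_trigger_frame {t} outside [0, {n_frames})"
                )
        return self

    def copy(self) -> "RecordingSession":
        arrays = {
            k: np.array(getattr(self, k), copy=True)
            for k in (
                "roi_traces", "neuropil_traces", "roi_centroids_um",
                "background_grid", "wheel_position", "affine_linear",
                "affine_translation", "zshift_series",
            )
        }
        return replace(self, meta=dict(self.meta), **arrays)


@dataclass
class FiberMap:
    """Per-ROI fiber labels; -1 marks an unassigned ROI."""

    assignments: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.assignments, dtype=int)
        labels = np.unique(a[a >= 0])
        if len(labels) and not np.array_equal(labels, np.arange(len(labels))):
            raise SessionValidationError(
                "fiber labels must be contiguous from 0; got %s" % labels
            )
        self.assignments = a

    @property
    def n_fibers(self) -> int:
        a = self.assignments
        return int(a.max()) + 1 if np.any(a >= 0) else 0

    def members(self, fiber: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fiber)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi_id": np.arange(len(self.assignments)),
             "fiber_id": self.assignments}
        )


_ARRAY_LAYOUT = {
    "traces/roi": "roi_traces",
    "traces/neuropil": "neuropil_traces",
    "traces/centroids_um": "roi_centroids_um",
    "background/grid": "background_grid",
    "behavior/wheel_position": "wheel_position",
    "registration/affine_linear": "affine_linear",
    "registration/affine_translation": "affine_translation",
    "registration/zshift": "zshift_series",
}


def write_session(session: RecordingSession, path) -> Path:
    """Write a validated session to an HDF5 container.

    Two writes of the same session produce byte-identical array payloads
    (dataset timestamps are disabled).
    """
    session.validate()
    path = Path(path)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "session_id": session.session_id,
        "frame_rate_hz": session.frame_rate_hz,
        "wheel_rate_hz": session.wheel_rate_hz,
        "fov_size_um": list(session.fov_size_um),
        "pixel_size_um": session.pixel_size_um,
        "bin_size_px": session.bin_size_px,
        "plane_spacing_um": session.plane_spacing_um,
        "anterior_axis": session.anterior_axis,
        "extra": session.meta,
    }
    if session.csd_trigger_frame is not None:
        meta["csd_trigger_frame"] = int(session.csd_trigger_frame)
    with h5py.File(path, "w", track_order=True) as f:
        for group in ("traces", "background", "behavior", "registration", "meta"):
            f.create_group(group)
        for key, attr in _ARRAY_LAYOUT.items():
            f.create_dataset(
                key, data=np.asarray(getattr(session, attr), dtype=np.float64),
                track_times=False,
            )
        f["meta"].attrs["json"] = json.dumps(meta, sort_keys=True)
    return path


def read_session(path) -> RecordingSession:
    """Read and validate a session container written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            try:
                meta = json.loads(f["meta"].attrs["json"])
            except KeyError as exc:
                raise SessionValidationError(
                    f"{path} is missing the /meta JSON attribute block"
                ) from exc
            arrays = {}
            for key, attr in _ARRAY_LAYOUT.items():
                if key not in f:
                    raise SessionValidationError(f"{path} is missing /{key}")
                arrays[attr] = f[key][()]
    except OSError as exc:
        raise OSError(f"could not read session container {path}: {exc}") from exc
    session = RecordingSession(
        session_id=meta["session_id"],
        frame_rate_hz=float(meta["frame_rate_hz"]),
        wheel_rate_hz=float(meta["wheel_rate_hz"]),
        fov_size_um=tuple(meta["fov_size_um"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        bin_size_px=int(meta["bin_size_px"]),
        plane_spacing_um=float(meta.get("plane_spacing_um", 5.0)),
        csd_trigger_frame=meta.get("csd_trigger_frame"),
        anterior_axis=meta.get("anterior_axis", "-y"),
        meta=meta.get("extra", {}),
        **arrays,
    )
    return session.validate()


def export_traces_csv(session: RecordingSession, path) -> Path:
    """Export ROI and neuropil traces as a tidy CSV for inspection."""
    path = Path(path)
    t = session.frame_times()
    cols = {"time_s": t}
    for i in range(session.n_rois):
        cols[f"roi_{i}"] = session.roi_traces[i]
        cols[f"neuropil_{i}"] = session.neuropil_traces[i]
    pd.DataFrame(cols).to_csv(path, index=False)
    return path
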