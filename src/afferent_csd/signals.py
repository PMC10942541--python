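"""Fluorescence trace processing and event detection.

The chain mirrors standard GCaMP trace analysis: neuropil-corrected
fluorescence ``F = F_ROI - F_np + <F_np>``, a trailing 32-s 10th-percentile
baseline ``F0``, the fractional change ``dF/F0``, standardization to z-units
using the median of the full trace and the standard deviation during quiet
wakefulness, and event detection as supra-threshold runs.

A fluorescence event is a maximal run where z > 1 sustained for at least 1 s
whose peak dF/F0 reaches at least 0.05.  "Consistently exceeded" is read as
strict inequality with no gap tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StandardizedTrace",
    "EventTrain",
    "correct_neuropil",
    "rolling_baseline",
    "standardize",
    "detect_events",
    "standardize_session_traces",
]


@dataclass
class EventTrain:
    """Detected fluorescence events for one trace.

    events: array of records (onset_frame, offset_frame, peak_dff, peak_z);
    ``offset_frame`` is exclusive.  ``occupancy`` is the fraction of frames
    inside events.
    """

    onsets: np.ndarray
    offsets: np.ndarray
    peak_dff: np.ndarray
    peak_z: np.ndarray
    n_frames: int

    @property
    def n_events(self) -> int:
        return len(self.onsets)

    @property
    def occupancy(self) -> float:
        if self.n_frames == 0:
            return 0.0
        return float(np.sum(self.offsets - self.onsets)) / self.n_frames

    def indicator(self) -> np.ndarray:
        """Binary per-frame event indicator."""
        ind = np.zeros(self.n_frames, dtype=bool)
        for a, b in zip(self.onsets, self.offsets):
            ind[a:b] = True
        return ind


@dataclass
class StandardizedTrace:
    f_corrected: np.ndarray
    f0: np.ndarray
    dff: np.ndarray
    z: np.ndarray
    quiet_mask: np.ndarray
    events: EventTrain | None = field(default=None)


def correct_neuropil(f_roi: np.ndarray, f_np: np.ndarray) -> np.ndarray:
    """Neuropil-corrected fluorescence ``F = F_ROI - F_np + <F_np>``.

    The bracket is the mean of the neuropil trace over the entire recording,
    so the corrected trace keeps the mean of the raw ROI trace.
    """
    f_roi = np.asarray(f_roi, dtype=float)
    f_np = np.asarray(f_np, dtype=float)
    if f_roi.shape != f_np.shape:
        raise ValueError(
            f"trace length mismatch: roi {f_roi.shape} vs neuropil {f_np.shape}"
        )
    return f_roi - f_np + f_np.mean()


def rolling_baseline(
    f: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 32.0,
    percentile: float = 10.0,
) -> np.ndarray:
    """Trailing-window percentile baseline F0.

    ``F0[t]`` is the ``percentile``-th percentile of ``f`` over the trailing
    window ``(t - window_s, t]``.  Before one full window has elapsed all
    available history is used, so F0 is defined from the first frame.
    Percentiles interpolate linearly between order statistics.
    """
    f = np.asarray(f, dtype=float)
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    w = int(round(window_s * frame_rate_hz))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    n = len(f)
    out = np.empty(n)
    head = min(w, n)
    # growing-window head
    for t in range(head - 1):
        out[t] = np.percentile(f[: t + 1], percentile)
    if n >= w:
        windows = np.lib.stride_tricks.sliding_window_view(f, w)
        out[w - 1:] = np.percentile(windows, percentile, axis=1)
    else:
        out[n - 1] = np.percentile(f, percentile)
    return out


def standardize(dff: np.ndarray, quiet_mask: np.ndarray) -> np.ndarray:
    """Z-score a dF/F0 trace.

    Centers on the median of the full trace and scales by the standard
    deviation computed over quiet-wakefulness samples only.
    """
    dff = np.asarray(dff, dtype=float)
    quiet_mask = np.asarray(quiet_mask, dtype=bool)
    if quiet_mask.shape != dff.shape:
        raise ValueError("quiet_mask must align with dff")
    if not quiet_mask.any():
        raise ValueError("quiet_mask selects no samples")
    sd = float(np.std(dff[quiet_mask]))
    if sd == 0:
        raise ValueError("zero standard deviation over quiet samples")
    return (dff - np.median(dff)) / sd


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal True-runs of a boolean array as (starts, stops-exclusive)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return starts, stops


def detect_events(
    z: np.ndarray,
    dff: np.ndarray,
    frame_rate_hz: float,
    z_thresh: float = 1.0,
    min_dur_s: float = 1.0,
    min_peak_dff: float = 0.05,
) -> EventTrain:
    """Detect fluorescence events as maximal supra-threshold runs.

    A run qualifies when z > ``z_thresh`` strictly on every frame, the run
    spans at least ``min_dur_s`` seconds (run length / frame rate), and its
    peak dF/F0 is at least ``min_peak_dff``.
    """
    z = np.asarray(z, dtype=float)
    dff = np.asarray(dff, dtype=float)
    if z.shape != dff.shape:
        raise ValueError("z and dff must be aligned")
    starts, stops = _runs(z > z_thresh)
    min_frames = int(np.ceil(min_dur_s * frame_rate_hz))
    keep_on, keep_off, pk_dff, pk_z = [], [], [], []
    for a, b in zip(starts, stops):
        if b - a < min_frames:
            continue
        peak = dff[a:b].max()
        if peak < min_peak_dff:
            continue
        keep_on.append(a)
        keep_off.append(b)
        pk_dff.append(peak)
        pk_z.append(z[a:b].max())
    return EventTrain(
        onsets=np.asarray(keep_on, dtype=int),
        offsets=np.asarray(keep_off, dtype=int),
        peak_dff=np.asarray(pk_dff, dtype=float),
        peak_z=np.asarray(pk_z, dtype=float),
        n_frames=len(z),
    )


def standardize_session_traces(
    roi_traces: np.ndarray,
    neuropil_traces: np.ndarray,
    quiet_mask: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 32.0,
    percentile: float = 10.0,
) -> list[StandardizedTrace]:
    """Run the full trace chain for every ROI and detect events."""
    out = []
    for f_roi, f_np in zip(np.atleast_2d(roi_traces), np.atleast_2d(neuropil_traces)):
        f = correct_neuropil(f_roi, f_np)
        f0 = rolling_baseline(f, frame_rate_hz, window_s, percentile)
        if np.any(f0 <= 0):
            raise ValueError("baseline F0 must stay positive for dF/F0")
        dff = (f - f0) / f0
        z = standardize(dff, quiet_mask)
        tr = StandardizedTrace(f_corrected=f, f0=f0, dff=dff, z=z,
                               quiet_mask=np.asarray(quiet_mask, dtype=bool))
        tr.events = detect_events(z, dff, frame_rate_hz)
        out.append(tr)
    return out
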