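"""CSD-associated calcium wave detection and propagation mapping.

The wave is found on the FOV-mean fluorescence F_FOV(t) within the first
5 min after the cortical pinprick: the initial period t_initial spans the
maximum to the minimum of the (1-s smoothed) time derivative, baseline
F_pre is the 10th percentile of the preceding 30 s, and the wave onset and
offset are the crossings of 0.1 * max(dF/F_pre over t_initial) around the
peak.

Propagation is mapped by fitting each spatial bin of the background
("neuropil") fluorescence grid to a logistic A / (1 + exp(-(t - t_onset)/tau)) + K
over -6..+14 s around the global onset.  Fits with R^2 < 0.5, tau > 2 s or
tau < 0 s are excluded.  Speed comes from regressing bin onset times on
distance along the propagation axis; direction from the wavefront contour
at the median onset time (level line of a least-squares onset plane), taking
the orthogonal vector oriented toward increasing onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WaveWindow",
    "BinOnsetFit",
    "WaveEstimate",
    "WaveNotDetectedError",
    "NoPropagationError",
    "detect_wave_window",
    "fit_bin_onsets",
    "estimate_speed_direction",
    "fiber_activation_pace",
]


class WaveNotDetectedError(RuntimeError):
    pass


class NoPropagationError(RuntimeError):
    pass


@dataclass
class WaveWindow:
    t_initial: tuple[int, int]  # frames (derivative max, derivative min)
    f_pre: float
    onset_frame: int
    offset_frame: int
    onset_s: float
    offset_s: float
    peak_dff: float
    threshold: float


@dataclass
class BinOnsetFit:
    """Per-bin logistic fit of the wave onset."""

    bin_iy: np.ndarray
    bin_ix: np.ndarray
    center_x_um: np.ndarray
    center_y_um: np.ndarray
    amplitude: np.ndarray
    t_onset: np.ndarray  # seconds, absolute session time
    tau: np.ndarray
    offset: np.ndarray   # K
    r2: np.ndarray
    included: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_iy": self.bin_iy,
                "bin_ix": self.bin_ix,
                "center_x_um": self.center_x_um,
                "center_y_um": self.center_y_um,
                "amplitude": self.amplitude,
                "t_onset_s": self.t_onset,
                "tau_s": self.tau,
                "offset": self.offset,
                "r2": self.r2,
                "included": self.included,
            }
        )


@dataclass
class WaveEstimate:
    speed_mm_per_min: float
    direction_deg: float  # image-coordinate bearing, 0 = +x, 90 = +y
    n_bins_included: int
    onset_map: BinOnsetFit
    regression_r: float = field(default=np.nan)


def roi_bin_exclusion_mask(
    roi_centroids_um: np.ndarray,
    fov_size_um: tuple[float, float],
    pixel_size_um: float,
    bin_size_px: int,
    pad_px: int = 8,
) -> np.ndarray:
    """Boolean grid of background bins contaminated by ROI pixels.

    A bin is excluded when any ROI centroid falls inside it or within
    ``pad_px`` pixels of it, so the bin fits see only background signal.
    """
    w, h = fov_size_um
    npx_x = int(round(w / pixel_size_um))
    npx_y = int(round(h / pixel_size_um))
    nbx, nby = npx_x // bin_size_px, npx_y // bin_size_px
    bin_um = bin_size_px * pixel_size_um
    pad = pad_px * pixel_size_um
    mask = np.zeros((nby, nbx), dtype=bool)
    for cx, cy in np.asarray(roi_centroids_um, dtype=float):
        ix0 = int(np.clip((cx - pad) // bin_um, 0, nbx - 1))
        ix1 = int(np.clip((cx + pad) // bin_um, 0, nbx - 1))
        iy0 = int(np.clip((cy - pad) // bin_um, 0, nby - 1))
        iy1 = int(np.clip((cy + pad) // bin_um, 0, nby - 1))
        mask[iy0: iy1 + 1, ix0: ix1 + 1] = True
    return mask


def _smooth_ma(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(np.asarray(x, dtype=float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad: pad + len(x)]


def detect_wave_window(
    f_fov: np.ndarray,
    trigger_frame: int,
    frame_rate_hz: float,
    search_s: float = 300.0,
    pre_s: float = 30.0,
    smooth_s: float = 1.0,
) -> WaveWindow:
    """Locate the CSD calcium wave on the FOV-mean fluorescence trace.

    Raises :class:`WaveNotDetectedError` when no supra-threshold excursion
    exists in the search window.
    """
    f = np.asarray(f_fov, dtype=float)
    lo = int(trigger_frame)
    hi = min(len(f), lo + int(round(search_s * frame_rate_hz)))
    if hi - lo < int(round(60 * frame_rate_hz)):
        raise ValueError("need at least 1 min of frames after the trigger")
    dfdt = np.gradient(f) * frame_rate_hz
    dfdt = _smooth_ma(dfdt, max(1, int(round(smooth_s * frame_rate_hz))))
    seg = dfdt[lo:hi]
    i_max = lo + int(np.argmax(seg))
    # derivative minimum is sought after the rise
    i_min = i_max + int(np.argmin(dfdt[i_max:hi])) if i_max < hi - 1 else i_max
    pre_lo = max(0, i_max - int(round(pre_s * frame_rate_hz)))
    if pre_lo == i_max:
        raise WaveNotDetectedError("no pre-wave baseline available")
    f_pre = float(np.percentile(f[pre_lo:i_max], 10))
    if f_pre <= 0:
        raise WaveNotDetectedError("non-positive pre-wave baseline")
    dff = (f - f_pre) / f_pre
    init = dff[i_max: i_min + 1]
    peak_rel = int(np.argmax(init))
    peak = i_max + peak_rel
    threshold = 0.1 * float(init.max())
    if threshold <= 0:
        raise WaveNotDetectedError("no supra-threshold excursion after trigger")
    # outward crossings around the peak
    onset = peak
    while onset > lo and dff[onset - 1] > threshold:
        onset -= 1
    offset = peak
    while offset < len(f) - 1 and dff[offset + 1] > threshold:
        offset += 1
    return WaveWindow(
        t_initial=(i_max, i_min),
        f_pre=f_pre,
        onset_frame=onset,
        offset_frame=offset,
        onset_s=onset / frame_rate_hz,
        offset_s=offset / frame_rate_hz,
        peak_dff=float(dff[peak]),
        threshold=threshold,
    )


def _logistic(t, A, t0, tau, K):
    return A / (1.0 + np.exp(-np.clip((t - t0) / tau, -500, 500))) + K


def _fit_logistic(
    t: np.ndarray, y: np.ndarray, tau_starts=(0.5, 1.0, 2.0), n_refine: int = 3
):
    """Multi-start logistic fit; returns (A, t0, tau, K, r2).

    Onset starts lie on a 1-s grid over the window; the best few starts by
    SSE are refined with least squares.
    """
    A0 = float(np.ptp(y))
    K0 = float(np.min(y))
    sst = float(np.sum((y - y.mean()) ** 2))
    if A0 == 0 or sst == 0:
        return A0, t[0], np.nan, K0, 0.0
    starts = []
    for t0 in np.arange(t[0], t[-1] + 1e-9, 1.0):
        for tau in tau_starts:
            sse = float(np.sum((y - _logistic(t, A0, t0, tau, K0)) ** 2))
            starts.append((sse, t0, tau))
    starts.sort(key=lambda s: s[0])
    best = None
    import warnings

    for _, t0, tau in starts[:n_refine]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _logistic, t, y, p0=[A0, t0, tau, K0], maxfev=2000
                )
        except RuntimeError:
            continue
        sse = float(np.sum((y - _logistic(t, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return A0, t[0], np.nan, K0, 0.0
    sse, (A, t0, tau, K) = best
    r2 = 1.0 - sse / sst
    return float(A), float(t0), float(tau), float(K), float(r2)


def fit_bin_onsets(
    background_grid: np.ndarray,
    window: WaveWindow,
    frame_rate_hz: float,
    bin_size_px: int,
    pixel_size_um: float,
    roi_exclusion_mask: np.ndarray | None = None,
    pre_s: float = 6.0,
    post_s: float = 14.0,
    r2_min: float = 0.5,
    tau_max_s: float = 2.0,
) -> BinOnsetFit:
    """Logistic onset fit for every background bin around the wave onset.

    ``roi_exclusion_mask`` marks bins contaminated by ROI (or ROI-adjacent)
    pixels; those are skipped entirely.  Exclusion of poor fits follows the
    rule R^2 < 0.5, tau > 2 s or tau < 0 s.
    """
    grid = np.asarray(background_grid, dtype=float)
    ny, nx, n_frames = grid.shape
    lo = max(0, window.onset_frame - int(round(pre_s * frame_rate_hz)))
    hi = min(n_frames, window.onset_frame + int(round(post_s * frame_rate_hz)) + 1)
    t = np.arange(lo, hi) / frame_rate_hz
    bin_um = bin_size_px * pixel_size_um
    rows = {k: [] for k in
            ("iy", "ix", "cx", "cy", "A", "t0", "tau", "K", "r2", "inc")}
    for iy in range(ny):
        for ix in range(nx):
            if roi_exclusion_mask is not None and roi_exclusion_mask[iy, ix]:
                continue
            y = grid[iy, ix, lo:hi]
            A, t0, tau, K, r2 = _fit_logistic(t, y)
            included = (
                np.isfinite(tau)
                and r2 >= r2_min
                and 0.0 <= tau <= tau_max_s
                and t[0] <= t0 <= t[-1]
            )
            rows["iy"].append(iy)
            rows["ix"].append(ix)
            rows["cx"].append((ix + 0.5) * bin_um)
            rows["cy"].append((iy + 0.5) * bin_um)
            rows["A"].append(A)
            rows["t0"].append(t0)
            rows["tau"].append(tau)
            rows["K"].append(K)
            rows["r2"].append(r2)
            rows["inc"].append(included)
    fit = BinOnsetFit(
        bin_iy=np.asarray(rows["iy"], dtype=int),
        bin_ix=np.asarray(rows["ix"], dtype=int),
        center_x_um=np.asarray(rows["cx"], dtype=float),
        center_y_um=np.asarray(rows["cy"], dtype=float),
        amplitude=np.asarray(rows["A"], dtype=float),
        t_onset=np.asarray(rows["t0"], dtype=float),
        tau=np.asarray(rows["tau"], dtype=float),
        offset=np.asarray(rows["K"], dtype=float),
        r2=np.asarray(rows["r2"], dtype=float),
        included=np.asarray(rows["inc"], dtype=bool),
    )
    if not fit.included.any():
        raise WaveNotDetectedError("insufficient wave coverage: all bins excluded")
    return fit


def estimate_speed_direction(
    fits: BinOnsetFit,
    min_bins: int = 6,
) -> WaveEstimate:
    """Wave speed (mm/min) and direction (degrees) from bin onset times.

    The onset map is interpolated by a least-squares plane
    ``t = a x + b y + c``; the wavefront contour at the median onset is the
    level line of that plane, and the direction is its orthogonal unit
    vector oriented toward increasing onset (the plane gradient).  Speed is
    the inverse slope of onset time regressed on distance projected along
    the direction.
    """
    inc = fits.included
    if int(inc.sum()) < min_bins:
        raise ValueError(
            f"only {int(inc.sum())} included bins; need >= {min_bins}"
        )
    x = fits.center_x_um[inc]
    y = fits.center_y_um[inc]
    t = fits.t_onset[inc]
    if np.std(t) < 1e-6:
        raise NoPropagationError("onset times identical: simultaneous activation")
    pts = np.c_[x, y]
    # collinear bin centers leave the contour normal undefined
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("bin centers are collinear: direction undefined")
    X = np.c_[x, y, np.ones_like(x)]
    (a, b, _), *_ = np.linalg.lstsq(X, t, rcond=None)
    g = np.hypot(a, b)
    if g < 1e-12:
        raise NoPropagationError("onset plane is flat: no propagation")
    ux, uy = a / g, b / g
    direction_deg = float(np.degrees(np.arctan2(uy, ux)) % 360.0)
    d = x * ux + y * uy  # um along the propagation axis
    reg = stats.linregress(d, t)
    if reg.slope <= 0:
        raise NoPropagationError("onset does not increase along the axis")
    speed_um_s = 1.0 / reg.slope
    return WaveEstimate(
        speed_mm_per_min=speed_um_s * 60.0 / 1000.0,
        direction_deg=direction_deg,
        n_bins_included=int(inc.sum()),
        onset_map=fits,
        regression_r=float(reg.rvalue),
    )


def fiber_activation_pace(
    roi_traces: np.ndarray,
    roi_positions_um: np.ndarray,
    window_frames: tuple[int, int],
    frame_rate_hz: float,
    min_length_um: float = 200.0,
    r2_min: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """Activation pace (s/mm) along one fiber's ordered ROIs.

    Each ROI's trace over ``window_frames`` is fit to a sigmoid; the pace is
    the slope of onset time regressed on arc-length distance along the
    fiber.  Near-simultaneous activation (locomotion-like) yields a pace
    near zero; the sign flips when the ROI order is reversed.
    """
    traces = np.atleast_2d(np.asarray(roi_traces, dtype=float))
    pos = np.asarray(roi_positions_um, dtype=float)
    if traces.shape[0] != pos.shape[0]:
        raise ValueError("one position per ROI trace required")
    if traces.shape[0] < 3:
        raise ValueError("need at least 3 ROIs along the fiber")
    arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pos, axis=0), axis=1))]
    if arc[-1] <= min_length_um:
        raise ValueError(
            f"fiber length {arc[-1]:.0f} um does not exceed {min_length_um} um"
        )
    lo, hi = window_frames
    t = np.arange(lo, hi) / frame_rate_hz
    rows = []
    for i, tr in enumerate(traces):
        A, t0, tau, K, r2 = _fit_logistic(t, tr[lo:hi])
        usable = np.isfinite(tau) and r2 >= r2_min and t[0] <= t0 <= t[-1]
        rows.append(
            {"roi_index": i, "arc_um": arc[i], "onset_s": t0, "tau_s": tau,
             "r2": r2, "usable": usable}
        )
    table = pd.DataFrame(rows)
    usable = table[table["usable"]]
    if len(usable) < 3:
        raise ValueError("fewer than 3 usable ROI onset fits")
    reg = stats.linregress(usable["arc_um"] / 1000.0, usable["onset_s"])
    return float(reg.slope), table
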