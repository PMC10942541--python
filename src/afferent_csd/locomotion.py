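"""Locomotion segmentation from running-wheel position.

Velocity is the first difference of wheel position resampled onto the
imaging frame clock.  The binary locomotion state is decoded with a
two-state Gaussian hidden Markov model on speed (|velocity|), bouts are
maximal locomoting runs sustained for at least 2 s, and "stillness" is the
complement after discarding a 30-s margin around every bout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .signals import _runs

logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = [
    "LocomotionSeries",
    "wheel_to_velocity",
    "fit_locomotion_hmm",
    "extract_bouts",
    "stillness_epochs",
    "segment_locomotion",
]


@dataclass
class LocomotionSeries:
    velocity: np.ndarray        # at frame rate, wheel units/s (or cm/s)
    state: np.ndarray           # boolean, True = locomoting
    bouts: pd.DataFrame         # start_s, end_s, duration_s, peak_velocity
    stillness_mask: np.ndarray  # boolean, still AND >= 30 s from any bout
    frame_rate_hz: float

    def bout_rate_per_min(self, n_frames: int | None = None) -> float:
        n = n_frames if n_frames is not None else len(self.state)
        return len(self.bouts) / (n / self.frame_rate_hz / 60.0)


def wheel_to_velocity(
    wheel_position: np.ndarray,
    wheel_rate_hz: float,
    frame_rate_hz: float,
    n_frames: int,
    units_per_cm: float | None = None,
) -> np.ndarray:
    """Instantaneous wheel velocity downsampled onto frame timestamps.

    The derivative is the first difference of the position series times the
    wheel sampling rate; each frame's value is the mean of the wheel-rate
    velocity samples whose timestamps fall in that frame's interval
    ``[k, k+1) / frame_rate_hz``.  If ``units_per_cm`` is given the result
    is converted from encoder units/s to cm/s.
    """
    w = np.asarray(wheel_position, dtype=float)
    if w.size < 2:
        raise ValueError("need at least 2 wheel samples")
    v = np.diff(w) * wheel_rate_hz
    # velocity sample i describes the step ending at sample i+1
    t = (np.arange(1, w.size)) / wheel_rate_hz
    idx = np.floor(t * frame_rate_hz).astype(int)
    valid = idx < n_frames
    sums = np.bincount(idx[valid], weights=v[valid], minlength=n_frames)
    counts = np.bincount(idx[valid], minlength=n_frames)
    out = np.zeros(n_frames)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if units_per_cm:
        out /= units_per_cm
    return out


def fit_locomotion_hmm(
    velocity: np.ndarray,
    seed: int,
    frame_rate_hz: float = 1.03,
    n_restarts: int = 20,
) -> np.ndarray:
    """Two-state Gaussian-HMM segmentation of speed into still/locomoting.

    Emissions are Gaussian on |velocity|.  The model is refit from
    ``n_restarts`` seeded initializations and the best-likelihood fit kept;
    the state with the higher emission mean is labelled locomoting and the
    Viterbi path returned, making the labelling invariant to state-index
    permutation.  A degenerate (constant) velocity series yields all-still
    with a warning.
    """
    speed = np.abs(np.asarray(velocity, dtype=float))
    if speed.size < int(60 * frame_rate_hz):
        raise ValueError("velocity series shorter than 60 s")
    if np.ptp(speed) == 0:
        warnings.warn("degenerate constant velocity; labelling all frames still")
        return np.zeros(speed.size, dtype=bool)
    X = speed.reshape(-1, 1)
    best_model, best_score = None, -np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=100,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X)
                score = model.score(X)
            except Exception:
                continue
        if score > best_score:
            best_model, best_score = model, score
    if best_model is None:
        raise RuntimeError("HMM failed to converge from every restart")
    path = best_model.predict(X)
    run_state = int(np.argmax(best_model.means_.ravel()))
    return path == run_state


def extract_bouts(
    state: np.ndarray,
    frame_rate_hz: float,
    velocity: np.ndarray | None = None,
    min_dur_s: float = 2.0,
    merge_gap_frames: int = 1,
) -> pd.DataFrame:
    """Locomotion bouts: maximal locomoting runs sustained >= ``min_dur_s``.

    Runs separated by gaps shorter than ``merge_gap_frames`` frames are
    merged first (a guard against single-sample jitter).  Peak velocity is
    reported when a velocity series is supplied.
    """
    state = np.asarray(state, dtype=bool)
    starts, stops = _runs(state)
    # merge short gaps
    if len(starts) > 1 and merge_gap_frames > 0:
        m_starts, m_stops = [starts[0]], [stops[0]]
        for a, b in zip(starts[1:], stops[1:]):
            if a - m_stops[-1] < merge_gap_frames:
                m_stops[-1] = b
            else:
                m_starts.append(a)
                m_stops.append(b)
        starts, stops = np.asarray(m_starts), np.asarray(m_stops)
    min_frames = int(np.ceil(min_dur_s * frame_rate_hz))
    rows = []
    for a, b in zip(starts, stops):
        if b - a < min_frames:
            continue
        peak = float(np.max(np.abs(velocity[a:b]))) if velocity is not None else np.nan
        rows.append(
            {
                "start_frame": int(a),
                "end_frame": int(b),
                "start_s": a / frame_rate_hz,
                "end_s": b / frame_rate_hz,
                "duration_s": (b - a) / frame_rate_hz,
                "peak_velocity": peak,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["start_frame", "end_frame", "start_s", "end_s",
                 "duration_s", "peak_velocity"],
    )


def stillness_epochs(
    state: np.ndarray,
    bouts: pd.DataFrame,
    frame_rate_hz: float,
    margin_s: float = 30.0,
) -> np.ndarray:
    """Stillness mask: not locomoting and >= ``margin_s`` from every bout.

    The margin excludes ``[start - margin, end + margin]`` around each bout,
    removing residual locomotion-evoked activity from "quiet wakefulness".
    """
    state = np.asarray(state, dtype=bool)
    mask = ~state
    margin = int(round(margin_s * frame_rate_hz))
    for _, bout in bouts.iterrows():
        a = max(0, int(bout["start_frame"]) - margin)
        b = min(len(state), int(bout["end_frame"]) + margin)
        mask[a:b] = False
    return mask


def segment_locomotion(
    wheel_position: np.ndarray,
    wheel_rate_hz: float,
    frame_rate_hz: float,
    n_frames: int,
    seed: int,
    min_bout_s: float = 2.0,
    margin_s: float = 30.0,
    units_per_cm: float | None = None,
) -> LocomotionSeries:
    """Full locomotion pipeline: velocity -> HMM state -> bouts -> stillness."""
    velocity = wheel_to_velocity(
        wheel_position, wheel_rate_hz, frame_rate_hz, n_frames, units_per_cm
    )
    state = fit_locomotion_hmm(velocity, seed=seed, frame_rate_hz=frame_rate_hz)
    bouts = extract_bouts(state, frame_rate_hz, velocity, min_dur_s=min_bout_s)
    mask = stillness_epochs(state, bouts, frame_rate_hz, margin_s=margin_s)
    return LocomotionSeries(
        velocity=velocity, state=state, bouts=bouts,
        stillness_mask=mask, frame_rate_hz=frame_rate_hz,
    )
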