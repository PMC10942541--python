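"""Synthetic recording sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes so
that every downstream stage is testable by parameter recovery:

* locomotion as a two-state Markov chain with distinct smooth velocity
  regimes, integrated into a wheel-position series at the wheel rate;
* meningeal deformation (scale, shear, Z-shift) as causally filtered
  velocity plus Gaussian noise, re-encoded into per-frame affine matrices
  and plane shifts exactly invertible by the deformation module;
* afferent fibers as groups of ROIs sharing a latent trace: GCaMP6s-like
  transients (difference-of-exponentials kernel, 0.2 s rise / 1.5 s decay)
  on Poisson event trains, plus a lagged linear drive from the planted GLM
  coefficients, plus independent per-ROI noise;
* a planar CSD calcium wave (logistic rise, plateau, slow exponential
  return) sweeping the FOV at a configurable speed and direction, painted
  into both the ROI traces and the binned background grid;
* post-CSD changes: delayed prolonged activation or immediate suppression
  of ongoing activity in planted fiber subsets, multiplicative gain on the
  deformation coefficients of sensitized fibers, unmasking of silent
  fibers, loss of coupling in others, and a scaled-down bout rate.

The baseline Poisson rate is calibrated analytically so that detected
events occupy the configured fraction of stillness time (default 6.9%):
the expected supra-threshold width of a transient of amplitude ``a`` under
unit noise is ``sum_f Phi(a h_f - 1)`` over kernel samples ``h_f``, and the
rate is occupancy / width.

The planted GLM drive is added directly to the latent z-trace (the
indicator kernel shapes only the discrete background transients); this
keeps coefficient recovery exact instead of "exact up to kernel
convolution".
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .locomotion import extract_bouts
from .session import RecordingSession, write_session

__all__ = ["SimConfig", "GroundTruth", "generate_session", "make_fixture_suite",
           "gcamp_kernel", "expected_event_width_frames"]

FIBER_ROLES = ("coupled_sensitized", "coupled_stable", "unmasked", "lost", "null")


@dataclass
class SimConfig:
    seed: int = 0
    # timing / geometry
    pre_min: float = 60.0
    post_min: float = 120.0
    frame_rate_hz: float = 1.03
    wheel_rate_hz: float = 15.5
    fov_size_um: tuple[float, float] = (626.0, 423.0)
    pixel_size_um: float = 1.223
    bin_size_px: int = 40
    plane_spacing_um: float = 5.0
    # fibers and ROIs
    n_fibers: int = 12
    rois_per_fiber: tuple[int, int] = (3, 8)
    roi_spacing_um: float = 45.0
    # transients
    gcamp_rise_s: float = 0.2
    gcamp_decay_s: float = 1.5
    event_amp_z: float = 6.0
    event_amp_jitter: float = 0.15
    event_mean_dur_frames: float = 2.0  # bursts: geometric firing duration
    target_still_occupancy: float = 0.069
    baseline_event_rate_hz: float | None = None  # derived from occupancy if None
    noise_sd: float = 1.0        # per-ROI white noise, latent z units
    dff_per_z: float = 0.02      # dF/F0 per latent z unit
    f0_base: float = 200.0       # raw fluorescence baseline (a.u.)
    np_base: float = 100.0
    np_noise: float = 0.5
    # locomotion
    bout_rate_per_min: float = 0.3
    mean_bout_s: float = 8.0
    run_speed: float = 8.0       # wheel units/s during bouts
    run_speed_sd: float = 1.5
    still_speed_sd: float = 0.05
    # deformation coupling (velocity -> series, exp filter + noise)
    deform_filter_tau_s: float = 1.0
    scale_gain: float = 0.4      # um per velocity unit
    shear_gain: float = 0.0025   # dimensionless per velocity unit
    zshift_gain: float = 0.5     # um per velocity unit
    scale_noise_um: float = 1.0
    shear_noise: float = 0.006
    zshift_noise_um: float = 1.2
    affine_rotation_sd_rad: float = 0.002
    # planted GLM couplings (latent z per standardized predictor unit)
    beta_deform: float = 0.8     # on zshift and scale
    beta_scale_frac: float = 0.6  # scale coupling = beta_deform * this
    beta_locomotion: float = 0.4  # on locomotion_state
    coupling_delay_frames: int = 0
    sens_gain: float = 2.0       # post-CSD gain on deformation coefficients
    frac_sensitized: float = 0.25
    frac_coupled_stable: float = 0.25
    frac_unmasked: float = 0.15
    frac_lost: float = 0.10
    # CSD wave
    csd: bool = True
    wave_speed_mm_per_min: float = 3.8
    wave_direction_deg: float = 90.0  # image bearing; 90 = +y (posterior)
    wave_amp_z: float = 25.0
    wave_tau_s: float = 1.0
    wave_hold_s: float = 15.0
    wave_return_tau_s: float = 20.0
    wave_delay_s: float = 20.0        # entry of the wave after the trigger
    wave_amp_bg: float = 60.0         # background-grid wave amplitude (a.u.)
    bg_base: float = 100.0
    bg_noise_frac: float = 0.0        # bin noise SD as fraction of wave amp
    # post-CSD ongoing-activity changes
    activated_fraction: float = 0.10
    suppressed_fraction: float = 0.20
    activation_delay_min: float = 25.0
    effect_duration_min: float = 25.0
    activated_occupancy: float = 0.30
    post_bout_rate_factor: float = 0.6

    def __post_init__(self):
        for name in ("activated_fraction", "suppressed_fraction",
                     "frac_sensitized", "frac_unmasked", "frac_lost"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("pre_min", "post_min", "frame_rate_hz", "wheel_rate_hz",
                     "wave_speed_mm_per_min", "mean_bout_s", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    fiber_of_roi: np.ndarray
    fiber_roles: list[str]
    glm_pre: list[dict[str, tuple[int, float]]]
    glm_post: list[dict[str, tuple[int, float]]]
    ongoing_class: list[str]
    ongoing_onset_min: np.ndarray
    ongoing_duration_min: np.ndarray
    state: np.ndarray
    velocity: np.ndarray
    bouts: pd.DataFrame
    scale_um: np.ndarray
    shear: np.ndarray
    zshift_um: np.ndarray
    wave_speed_mm_per_min: float | None
    wave_direction_deg: float | None
    wave_onset_grid_s: np.ndarray | None
    wave_onset_s: float | None
    wave_offset_s: float | None
    roi_wave_onset_s: np.ndarray | None
    roi_exclusion_mask: np.ndarray | None
    event_rate_hz: float
    dff_per_z: float
    noise_sd: float
    spike_frames: list[np.ndarray] = field(default_factory=list)

    def to_json(self, path) -> Path:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, pd.DataFrame):
                return x.to_dict(orient="records")
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        payload = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path


def gcamp_kernel(frame_rate_hz: float, rise_s: float = 0.2,
                 decay_s: float = 1.5, dur_s: float = 12.0) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak-normalized."""
    t = np.arange(0.0, dur_s, 1.0 / frame_rate_hz)
    h = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: rise must be faster than decay")
    return h / peak


def expected_event_width_frames(amp_z: float, kernel: np.ndarray,
                                z_thresh: float = 1.0) -> float:
    """Expected supra-threshold frames of one transient under unit noise."""
    return float(np.sum(norm.cdf(amp_z * kernel - z_thresh)))


def _expected_detected_frames(amp_z: float, kernel: np.ndarray,
                              quiet_sd: float, min_frames: int,
                              n_noise_pad: int = 2, n_tail: int = 8) -> float:
    """Expected frames a single transient contributes to detected events.

    Detection standardizes by the quiet SD (which includes transient shot
    noise), so a frame crosses when ``amp * h_f + eps > quiet_sd``.  Frames
    only count inside runs of at least ``min_frames``; the expectation is
    computed exactly by enumerating crossing patterns over the transient
    frames plus ``n_noise_pad`` noise-only frames on each side.
    """
    h = np.concatenate([np.zeros(n_noise_pad), kernel[:n_tail],
                        np.zeros(n_noise_pad)])
    p = norm.cdf(amp_z * h - quiet_sd)
    k = len(p)
    patterns = ((np.arange(1 << k)[:, None] >> np.arange(k)) & 1).astype(bool)
    probs = np.prod(np.where(patterns, p, 1 - p), axis=1)
    keep = probs > 1e-10
    expected = 0.0
    for bits, prob in zip(patterns[keep], probs[keep]):
        count = 0
        run = 0
        for b in np.append(bits, False):
            if b:
                run += 1
            else:
                if run >= min_frames:
                    count += run
                run = 0
        expected += prob * count
    return expected


def calibrate_event_rate(cfg: "SimConfig", kernel: np.ndarray,
                         occupancy: float) -> float:
    """Poisson rate (Hz) whose detected events occupy ``occupancy`` of time.

    Solves the fixed point between the rate and the quiet SD it induces
    (shot-noise variance of the transients inflates the standardization
    scale and shrinks the effective amplitude).
    """
    fs = cfg.frame_rate_hz
    min_frames = int(np.ceil(1.0 * fs))
    amp2 = cfg.event_amp_z**2 * (1 + cfg.event_amp_jitter**2 / 3)
    h2 = float(np.sum(kernel**2))
    rate = occupancy * fs / max(expected_event_width_frames(cfg.event_amp_z, kernel), 1e-6)
    for _ in range(30):
        quiet_sd = np.sqrt(cfg.noise_sd**2 + (rate / fs) * amp2 * h2)
        width = _expected_detected_frames(
            cfg.event_amp_z, kernel, quiet_sd, min_frames
        )
        new_rate = occupancy * fs / max(width, 1e-6)
        if abs(new_rate - rate) < 1e-9:
            rate = new_rate
            break
        rate = 0.5 * rate + 0.5 * new_rate
    return float(rate)


def _rate_at_fixed_sd(cfg: "SimConfig", kernel: np.ndarray, occupancy: float,
                      quiet_sd: float) -> float:
    """Rate reaching ``occupancy`` when standardization uses a given SD.

    Used for transient epochs (e.g. post-CSD activation) whose frames are
    standardized with the session-wide quiet SD set by the baseline rate.
    """
    fs = cfg.frame_rate_hz
    min_frames = int(np.ceil(1.0 * fs))
    width = _expected_detected_frames(cfg.event_amp_z, kernel, quiet_sd,
                                      min_frames)
    return float(occupancy * fs / max(width, 1e-6))


def _mc_occupancy(cfg: "SimConfig", kernel: np.ndarray, rate: float,
                  rng: np.random.Generator, n_frames: int = 40000,
                  sd_dff: float | None = None) -> tuple[float, float]:
    """Detected-event occupancy of a simulated trace run through the
    analysis chain (rolling baseline, standardization, event detection).

    Returns (occupancy, quiet dF/F0 SD).  When ``sd_dff`` is given it is
    used as the standardization scale (transient epochs are standardized
    with the session-wide baseline statistics, not their own).
    """
    from .signals import detect_events, rolling_baseline

    fs = cfg.frame_rate_hz
    train, _ = _event_drive(cfg, rate, n_frames, rng)
    z = np.convolve(train, kernel, mode="full")[:n_frames]
    z += cfg.noise_sd * rng.standard_normal(n_frames)
    f = cfg.f0_base * (1.0 + cfg.dff_per_z * z)
    f0 = rolling_baseline(f, fs)
    dff = (f - f0) / f0
    sd = float(dff.std()) if sd_dff is None else sd_dff
    zs = (dff - np.median(dff)) / sd
    ev = detect_events(zs, dff, fs)
    return ev.occupancy, float(dff.std())


def _calibration_key(cfg: "SimConfig") -> tuple:
    return (cfg.frame_rate_hz, cfg.gcamp_rise_s, cfg.gcamp_decay_s,
            cfg.event_amp_z, cfg.event_amp_jitter, cfg.event_mean_dur_frames,
            cfg.noise_sd, cfg.dff_per_z, cfg.f0_base,
            cfg.target_still_occupancy, cfg.activated_occupancy)


_CALIBRATION_CACHE: dict[tuple, tuple[float, float, float]] = {}


def calibrate_rates(cfg: "SimConfig") -> tuple[float, float, float]:
    """Baseline and activated-epoch Poisson rates hitting the configured
    detected-event occupancies, plus the implied quiet dF/F0 SD.

    Fixed point between rate and detection through the full analysis chain,
    solved by a short seeded Monte-Carlo iteration (the analytic
    run-enumeration width serves as the initial guess).  Deterministic and
    independent of the session seed; results are cached per configuration.
    """
    key = _calibration_key(cfg)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    kernel = gcamp_kernel(cfg.frame_rate_hz, cfg.gcamp_rise_s, cfg.gcamp_decay_s)
    rng = np.random.default_rng(987654321)
    rate = calibrate_event_rate(cfg, kernel, cfg.target_still_occupancy)
    sd_dff = None
    for _ in range(4):
        occ, sd_dff = _mc_occupancy(cfg, kernel, rate, rng)
        if occ > 0:
            rate *= (cfg.target_still_occupancy / occ) ** 0.7
    act = _rate_at_fixed_sd(
        cfg, kernel, cfg.activated_occupancy, sd_dff / cfg.dff_per_z
    )
    for _ in range(3):
        occ, _ = _mc_occupancy(cfg, kernel, act, rng, sd_dff=sd_dff)
        if occ > 0:
            act *= (cfg.activated_occupancy / occ) ** 0.7
    _CALIBRATION_CACHE[key] = (float(rate), float(act), float(sd_dff))
    return _CALIBRATION_CACHE[key]


def _event_drive(cfg: "SimConfig", rate_series, n_frames: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent firing drive from a Poisson burst train.

    Burst onsets are Poisson with the per-frame rate; each burst sustains
    its (jittered) amplitude for a geometric number of frames (mean
    ``event_mean_dur_frames``), emulating the multi-spike bursts behind
    afferent calcium transients.  Returns (drive, onset_frames).
    """
    fs = cfg.frame_rate_hz
    rates = np.broadcast_to(np.asarray(rate_series, dtype=float), (n_frames,))
    onsets = np.flatnonzero(rng.random(n_frames) < rates / fs)
    drive = np.zeros(n_frames)
    if onsets.size:
        durs = rng.geometric(1.0 / max(cfg.event_mean_dur_frames, 1.0),
                             onsets.size)
        amps = cfg.event_amp_z * (
            1 + cfg.event_amp_jitter * rng.uniform(-1, 1, onsets.size)
        )
        for k, L, a in zip(onsets, durs, amps):
            drive[k: k + L] += a
    return drive, onsets


def _wave_shape(t_rel: np.ndarray, tau: float, hold: float,
                return_tau: float) -> np.ndarray:
    """Unit-amplitude wave: logistic rise, plateau, exponential return."""
    rise = 1.0 / (1.0 + np.exp(-np.clip(t_rel / tau, -500, 500)))
    decay = np.exp(-np.clip(t_rel - hold, 0, None) / return_tau)
    return rise * decay


def _simulate_locomotion(cfg: SimConfig, n_frames: int, trigger_frame: int | None,
                         rng: np.random.Generator):
    fs = cfg.frame_rate_hz
    p_enter_pre = cfg.bout_rate_per_min / 60.0 / fs
    p_exit = 1.0 / (cfg.mean_bout_s * fs)
    state = np.zeros(n_frames, dtype=bool)
    u = rng.random(n_frames)
    for k in range(1, n_frames):
        p_enter = p_enter_pre
        if trigger_frame is not None and k >= trigger_frame:
            p_enter *= cfg.post_bout_rate_factor
        if state[k - 1]:
            state[k] = u[k] >= p_exit
        else:
            state[k] = u[k] < p_enter
    run_noise = rng.normal(0.0, cfg.run_speed_sd, n_frames)
    # smooth the run-speed fluctuation over ~1 s
    kern = np.exp(-np.arange(0, 3 * fs) / fs)
    kern /= kern.sum()
    run_noise = np.convolve(run_noise, kern, mode="same")
    velocity = np.where(
        state,
        np.clip(cfg.run_speed + run_noise, 0.5, None),
        rng.normal(0.0, cfg.still_speed_sd, n_frames),
    )
    return state, velocity


def _wheel_from_velocity(cfg: SimConfig, velocity: np.ndarray) -> np.ndarray:
    fs, ws = cfg.frame_rate_hz, cfg.wheel_rate_hz
    n_frames = len(velocity)
    n_wheel = int(round(n_frames / fs * ws))
    t_wheel = np.arange(n_wheel) / ws
    idx = np.minimum((t_wheel * fs).astype(int), n_frames - 1)
    v_wheel = velocity[idx]
    return np.concatenate([[0.0], np.cumsum(v_wheel[1:]) / ws])


def _causal_exp_filter(x: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    t = np.arange(0, 5 * tau_s, 1.0 / fs)
    k = np.exp(-t / tau_s)
    k /= k.sum()
    return np.convolve(x, k, mode="full")[: len(x)]


def _affine_from_deformation(cfg: SimConfig, scale_um, shear, rng):
    from .deformation import reference_radius_um

    r_ref = reference_radius_um(cfg.fov_size_um)
    stretch = np.asarray(scale_um) / r_ref
    prod = (1.0 + stretch) ** 2
    diff = 2.0 * np.asarray(shear)
    ssum = np.sqrt(diff**2 + 4.0 * prod)
    s1 = (ssum + diff) / 2.0
    s2 = (ssum - diff) / 2.0
    theta = rng.normal(0.0, cfg.affine_rotation_sd_rad, len(s1))
    c, s = np.cos(theta), np.sin(theta)
    A = np.empty((len(s1), 2, 2))
    A[:, 0, 0] = c * s1
    A[:, 0, 1] = -s * s2
    A[:, 1, 0] = s * s1
    A[:, 1, 1] = c * s2
    return A


def _assign_roles(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_fibers
    counts = {
        "coupled_sensitized": int(round(cfg.frac_sensitized * n)),
        "coupled_stable": int(round(cfg.frac_coupled_stable * n)),
        "unmasked": int(round(cfg.frac_unmasked * n)),
        "lost": int(round(cfg.frac_lost * n)),
    }
    roles = []
    for r, c in counts.items():
        roles += [r] * c
    roles += ["null"] * max(0, n - len(roles))
    roles = roles[:n]
    rng.shuffle(roles)
    return roles


def _coupling(cfg: SimConfig) -> dict[str, tuple[int, float]]:
    d = cfg.coupling_delay_frames
    return {
        "zshift": (d, cfg.beta_deform),
        "scale": (d, cfg.beta_deform * cfg.beta_scale_frac),
        "locomotion_state": (d, cfg.beta_locomotion),
    }


def _scaled(coupling: dict, deform_gain: float) -> dict:
    deform = ("scale", "shear", "zshift")
    return {
        f: (d, b * (deform_gain if f in deform else 1.0))
        for f, (d, b) in coupling.items()
    }


def generate_session(cfg: SimConfig) -> tuple[RecordingSession, GroundTruth]:
    """Simulate one full recording session plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.frame_rate_hz
    n_frames = int(round((cfg.pre_min + cfg.post_min) * 60 * fs))
    trigger_frame = int(round(cfg.pre_min * 60 * fs)) if cfg.csd else None

    # --- locomotion, wheel, deformation -------------------------------
    state, velocity = _simulate_locomotion(cfg, n_frames, trigger_frame, rng)
    wheel = _wheel_from_velocity(cfg, velocity)
    filt_v = _causal_exp_filter(velocity, cfg.deform_filter_tau_s, fs)
    scale_um = cfg.scale_gain * filt_v + rng.normal(0, cfg.scale_noise_um, n_frames)
    shear = np.abs(cfg.shear_gain * filt_v + rng.normal(0, cfg.shear_noise, n_frames))
    zshift_um = cfg.zshift_gain * filt_v + rng.normal(0, cfg.zshift_noise_um, n_frames)
    affine = _affine_from_deformation(cfg, scale_um, shear, rng)
    translation = rng.normal(0.0, 0.5, (n_frames, 2))
    zshift_planes = zshift_um / cfg.plane_spacing_um
    bouts = extract_bouts(state, fs, velocity, min_dur_s=2.0)

    # --- fiber geometry ------------------------------------------------
    w, h = cfg.fov_size_um
    fiber_of_roi, centroids = [], []
    for f in range(cfg.n_fibers):
        n_roi = int(rng.integers(cfg.rois_per_fiber[0], cfg.rois_per_fiber[1] + 1))
        theta = rng.uniform(0, 2 * np.pi)
        length = (n_roi - 1) * cfg.roi_spacing_um
        x0 = rng.uniform(0.1 * w, 0.9 * w)
        y0 = rng.uniform(0.1 * h, 0.9 * h)
        for i in range(n_roi):
            x = np.clip(x0 + np.cos(theta) * (i * length / max(n_roi - 1, 1)), 1, w - 1)
            y = np.clip(y0 + np.sin(theta) * (i * length / max(n_roi - 1, 1)), 1, h - 1)
            centroids.append((x, y))
            fiber_of_roi.append(f)
    fiber_of_roi = np.asarray(fiber_of_roi)
    centroids = np.asarray(centroids)
    n_rois = len(centroids)

    # --- planted GLM couplings per fiber -------------------------------
    roles = _assign_roles(cfg, rng)
    base = _coupling(cfg)
    glm_pre: list[dict] = []
    glm_post: list[dict] = []
    for role in roles:
        if role == "coupled_sensitized":
            glm_pre.append(dict(base))
            glm_post.append(_scaled(base, cfg.sens_gain))
        elif role == "coupled_stable":
            glm_pre.append(dict(base))
            glm_post.append(dict(base))
        elif role == "unmasked":
            glm_pre.append({})
            glm_post.append(dict(base))
        elif role == "lost":
            glm_pre.append(dict(base))
            glm_post.append({})
        else:
            glm_pre.append({})
            glm_post.append({})

    # standardized predictors (baseline statistics, as the analysis uses)
    predictors = {
        "locomotion_state": state.astype(float),
        "velocity": velocity,
        "scale": scale_um,
        "shear": shear,
        "zshift": zshift_um,
    }
    pre_slice = slice(0, trigger_frame if trigger_frame is not None else n_frames)
    x_std = {}
    for fam, x in predictors.items():
        m, s = x[pre_slice].mean(), x[pre_slice].std()
        x_std[fam] = (x - m) / s if s > 0 else np.zeros_like(x)

    def drive_for(coupling: dict) -> np.ndarray:
        out = np.zeros(n_frames)
        for fam, (d, b) in coupling.items():
            x = x_std[fam]
            if d >= 0:
                out[d:] += b * x[: n_frames - d] if d else b * x
            else:
                out[:d] += b * x[-d:]
        return out

    # --- ongoing-activity classes --------------------------------------
    kernel = gcamp_kernel(fs, cfg.gcamp_rise_s, cfg.gcamp_decay_s)
    cal_rate, act_rate, _ = calibrate_rates(cfg)
    rate = (
        cfg.baseline_event_rate_hz
        if cfg.baseline_event_rate_hz is not None
        else cal_rate
    )

    ongoing = ["none"] * cfg.n_fibers
    onset_min = np.full(cfg.n_fibers, np.nan)
    dur_min = np.full(cfg.n_fibers, np.nan)
    if cfg.csd:
        n_act = int(round(cfg.activated_fraction * cfg.n_fibers))
        n_sup = int(round(cfg.suppressed_fraction * cfg.n_fibers))
        order = rng.permutation(cfg.n_fibers)
        for f in order[:n_act]:
            ongoing[f] = "activated"
        for f in order[n_act: n_act + n_sup]:
            ongoing[f] = "suppressed"

    # --- CSD wave geometry ---------------------------------------------
    wave_speed = wave_dir = None
    onset_grid = roi_onsets = None
    wave_onset_s = wave_offset_s = None
    excl_mask = None
    npx_x = int(round(w / cfg.pixel_size_um))
    npx_y = int(round(h / cfg.pixel_size_um))
    nbx, nby = npx_x // cfg.bin_size_px, npx_y // cfg.bin_size_px
    bin_um = cfg.bin_size_px * cfg.pixel_size_um
    t_frames = np.arange(n_frames) / fs
    if cfg.csd:
        speed_um_s = cfg.wave_speed_mm_per_min * 1000.0 / 60.0
        ang = np.radians(cfg.wave_direction_deg)
        ux, uy = np.cos(ang), np.sin(ang)
        corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
        proj0 = (corners @ np.array([ux, uy])).min()
        t_entry = trigger_frame / fs + cfg.wave_delay_s

        def onset_at(p):
            return t_entry + ((p @ np.array([ux, uy])) - proj0) / speed_um_s

        bx = (np.arange(nbx) + 0.5) * bin_um
        by = (np.arange(nby) + 0.5) * bin_um
        bxx, byy = np.meshgrid(bx, by)
        onset_grid = onset_at(np.stack([bxx.ravel(), byy.ravel()], axis=1)).reshape(nby, nbx)
        roi_onsets = onset_at(centroids)
        latest = max(onset_grid.max(), roi_onsets.max())
        if latest > trigger_frame / fs + 300.0 - cfg.wave_hold_s:
            raise ValueError(
                "infeasible config: wave does not cross the FOV within the "
                "5-min detection window"
            )
        wave_speed = cfg.wave_speed_mm_per_min
        wave_dir = cfg.wave_direction_deg
        # onset/offset by the analysis convention: outward crossings of
        # 10% of the peak FOV-mean response, computed on the noiseless shape
        mean_shape = np.zeros(n_frames)
        for o in onset_grid.ravel():
            mean_shape += _wave_shape(
                t_frames - o, cfg.wave_tau_s, cfg.wave_hold_s,
                cfg.wave_return_tau_s,
            )
        mean_shape /= onset_grid.size
        thr = 0.1 * mean_shape.max()
        peak_i = int(np.argmax(mean_shape))
        i0 = peak_i
        while i0 > 0 and mean_shape[i0 - 1] > thr:
            i0 -= 1
        i1 = peak_i
        while i1 < n_frames - 1 and mean_shape[i1 + 1] > thr:
            i1 += 1
        wave_onset_s = float(i0 / fs)
        wave_offset_s = float(i1 / fs)
        from .wave import roi_bin_exclusion_mask

        excl_mask = roi_bin_exclusion_mask(
            centroids, cfg.fov_size_um, cfg.pixel_size_um, cfg.bin_size_px
        )

    # --- background grid -----------------------------------------------
    bg = np.full((nby, nbx, n_frames), cfg.bg_base, dtype=float)
    if cfg.csd:
        for iy in range(nby):
            for ix in range(nbx):
                bg[iy, ix] += cfg.wave_amp_bg * _wave_shape(
                    t_frames - onset_grid[iy, ix],
                    cfg.wave_tau_s, cfg.wave_hold_s, cfg.wave_return_tau_s,
                )
        if cfg.bg_noise_frac > 0:
            bg += rng.normal(0, cfg.bg_noise_frac * cfg.wave_amp_bg, bg.shape)

    # --- fiber latent traces and ROI fluorescence -----------------------
    roi_traces = np.empty((n_rois, n_frames))
    np_traces = cfg.np_base + rng.normal(0, cfg.np_noise, (n_rois, n_frames))
    spike_frames: list[np.ndarray] = []
    act_delay_frames = int(round(cfg.activation_delay_min * 60 * fs))
    eff_frames = int(round(cfg.effect_duration_min * 60 * fs))
    for f in range(cfg.n_fibers):
        rate_series = np.full(n_frames, rate)
        if cfg.csd and ongoing[f] != "none":
            off_frame = int(round(wave_offset_s * fs))
            if ongoing[f] == "activated":
                a = off_frame + act_delay_frames
                rate_series[a: a + eff_frames] = act_rate
                onset_min[f] = cfg.activation_delay_min
            else:
                rate_series[off_frame: off_frame + eff_frames] = 0.0
                onset_min[f] = 0.0
            dur_min[f] = cfg.effect_duration_min
        train, idx = _event_drive(cfg, rate_series, n_frames, rng)
        spike_frames.append(idx)
        transients = np.convolve(train, kernel, mode="full")[:n_frames]
        z_fiber = transients.copy()
        if trigger_frame is None:
            z_fiber += drive_for(glm_pre[f])
        else:
            d_pre = drive_for(glm_pre[f])
            d_post = drive_for(glm_post[f])
            z_fiber[:trigger_frame] += d_pre[:trigger_frame]
            z_fiber[trigger_frame:] += d_post[trigger_frame:]
        members = np.flatnonzero(fiber_of_roi == f)
        for r in members:
            z_roi = z_fiber + cfg.noise_sd * rng.standard_normal(n_frames)
            if cfg.csd:
                z_roi = z_roi + cfg.wave_amp_z * _wave_shape(
                    t_frames - roi_onsets[r],
                    cfg.wave_tau_s, cfg.wave_hold_s, cfg.wave_return_tau_s,
                )
            dff = cfg.dff_per_z * z_roi
            roi_traces[r] = cfg.f0_base * (1.0 + dff)

    session = RecordingSession(
        session_id=f"synthetic-{cfg.seed}",
        frame_rate_hz=fs,
        wheel_rate_hz=cfg.wheel_rate_hz,
        fov_size_um=cfg.fov_size_um,
        pixel_size_um=cfg.pixel_size_um,
        bin_size_px=cfg.bin_size_px,
        plane_spacing_um=cfg.plane_spacing_um,
        roi_traces=roi_traces,
        neuropil_traces=np_traces,
        roi_centroids_um=centroids,
        background_grid=bg,
        wheel_position=wheel,
        affine_linear=affine,
        affine_translation=translation,
        zshift_series=zshift_planes,
        csd_trigger_frame=trigger_frame,
        meta={"generator": "afferent_csd.synth", "seed": cfg.seed},
    ).validate()

    truth = GroundTruth(
        fiber_of_roi=fiber_of_roi,
        fiber_roles=roles,
        glm_pre=glm_pre,
        glm_post=glm_post,
        ongoing_class=ongoing,
        ongoing_onset_min=onset_min,
        ongoing_duration_min=dur_min,
        state=state,
        velocity=velocity,
        bouts=bouts,
        scale_um=scale_um,
        shear=shear,
        zshift_um=zshift_um,
        wave_speed_mm_per_min=wave_speed,
        wave_direction_deg=wave_dir,
        wave_onset_grid_s=onset_grid,
        wave_onset_s=wave_onset_s,
        wave_offset_s=wave_offset_s,
        roi_wave_onset_s=roi_onsets,
        roi_exclusion_mask=excl_mask,
        event_rate_hz=float(rate),
        dff_per_z=cfg.dff_per_z,
        noise_sd=cfg.noise_sd,
        spike_frames=spike_frames,
    )
    return session, truth


def make_fixture_suite(out_dir, seed: int = 1234) -> list[Path]:
    """Write a small named fixture set used by the test suite.

    Fixtures: a noiseless planar wave, a pure-noise cohort (all planted GLM
    coefficients zero, no post-CSD changes), a sensitization cohort, and an
    ongoing-activity cohort.  All are deterministic for a given seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    configs = {
        "noiseless_wave": SimConfig(
            seed=seed, pre_min=10, post_min=15, n_fibers=4,
            bg_noise_frac=0.0, activated_fraction=0.0, suppressed_fraction=0.0,
        ),
        "pure_noise": SimConfig(
            seed=seed + 1, pre_min=15, post_min=15, n_fibers=6,
            frac_sensitized=0.0, frac_coupled_stable=0.0, frac_unmasked=0.0,
            frac_lost=0.0, activated_fraction=0.0, suppressed_fraction=0.0,
            csd=False,
        ),
        "sensitization_cohort": SimConfig(
            seed=seed + 2, pre_min=30, post_min=30, n_fibers=10,
            activated_fraction=0.0, suppressed_fraction=0.0,
        ),
        "ongoing_cohort": SimConfig(
            seed=seed + 3, pre_min=20, post_min=65, n_fibers=10,
            frac_sensitized=0.0, frac_coupled_stable=0.0, frac_unmasked=0.0,
            frac_lost=0.0,
        ),
    }
    paths = []
    for name, cfg in configs.items():
        session, truth = generate_session(cfg)
        p = out_dir / f"{name}.h5"
        write_session(session, p)
        truth.to_json(out_dir / f"{name}.truth.json")
        paths.append(p)
    return paths
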