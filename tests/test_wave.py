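import numpy as np
import pytest

from afferent_csd.synth import SimConfig, generate_session
from afferent_csd.wave import (BinOnsetFit, NoPropagationError,
                               WaveNotDetectedError, WaveWindow,
                               detect_wave_window, estimate_speed_direction,
                               fiber_activation_pace, fit_bin_onsets)

FS = 1.03


# --- wave window detection ----------------------------------------------

def _gaussian_bump_fov(amp=0.6, base=100.0, tp_s=120.0, sigma_s=8.0,
                       dur_s=400.0):
    t = np.arange(0, dur_s, 1 / FS)
    dff = amp * np.exp(-((t - tp_s) ** 2) / (2 * sigma_s**2))
    return base * (1 + dff), t


def test_flat_fov_trace_no_wave():
    with pytest.raises(WaveNotDetectedError):
        detect_wave_window(np.full(600, 80.0), 10, FS)


def test_bump_crossings_match_closed_form():
    f, t = _gaussian_bump_fov()
    w = detect_wave_window(f, 40, FS)
    half_width = 8.0 * np.sqrt(2 * np.log(10))  # 10%-of-peak crossing
    assert w.onset_s == pytest.approx(120 - half_width, abs=1.5 / FS)
    assert w.offset_s == pytest.approx(120 + half_width, abs=1.5 / FS)
    assert w.peak_dff == pytest.approx(0.6, rel=0.05)


def test_bump_detection_scale_invariant():
    f, _ = _gaussian_bump_fov()
    a = detect_wave_window(f, 40, FS)
    b = detect_wave_window(10 * f, 40, FS)
    assert (a.onset_frame, a.offset_frame) == (b.onset_frame, b.offset_frame)


# --- per-bin logistic fits ----------------------------------------------

@pytest.fixture(scope="module")
def wave_session():
    cfg = SimConfig(seed=77, pre_min=8, post_min=12, n_fibers=3,
                    bg_noise_frac=0.0)
    return cfg, *generate_session(cfg)


def test_noiseless_bins_all_included_with_exact_onsets(wave_session):
    cfg, s, truth = wave_session
    w = detect_wave_window(s.background_grid.mean(axis=(0, 1)),
                           s.csd_trigger_frame, FS)
    fits = fit_bin_onsets(s.background_grid, w, FS, s.bin_size_px,
                          s.pixel_size_um,
                          roi_exclusion_mask=truth.roi_exclusion_mask)
    assert fits.included.all()
    err = [abs(t0 - truth.wave_onset_grid_s[iy, ix])
           for iy, ix, t0 in zip(fits.bin_iy, fits.bin_ix, fits.t_onset)]
    assert max(err) < 1 / FS


def test_slow_rise_bins_excluded_by_tau_rule():
    cfg = SimConfig(seed=78, pre_min=8, post_min=12, n_fibers=3,
                    bg_noise_frac=0.0, wave_tau_s=3.0)
    s, truth = generate_session(cfg)
    w = detect_wave_window(s.background_grid.mean(axis=(0, 1)),
                           s.csd_trigger_frame, FS)
    with pytest.raises(WaveNotDetectedError, match="excluded"):
        fit_bin_onsets(s.background_grid, w, FS, s.bin_size_px,
                       s.pixel_size_um,
                       roi_exclusion_mask=truth.roi_exclusion_mask)


def test_pure_noise_bins_excluded(rng):
    n_frames = 400
    grid = 100 + rng.normal(0, 5, (4, 5, n_frames))
    window = WaveWindow(t_initial=(200, 210), f_pre=100.0, onset_frame=200,
                        offset_frame=230, onset_s=200 / FS, offset_s=230 / FS,
                        peak_dff=0.5, threshold=0.05)
    with pytest.raises(WaveNotDetectedError):
        fit_bin_onsets(grid, window, FS, 40, 1.223)


# --- speed and direction -------------------------------------------------

def _plane_fits(direction_deg, speed_mm_min, nx=8, ny=6, bin_um=49.0,
                t0=600.0):
    ang = np.radians(direction_deg)
    ux, uy = np.cos(ang), np.sin(ang)
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cx = (ix.ravel() + 0.5) * bin_um
    cy = (iy.ravel() + 0.5) * bin_um
    speed_um_s = speed_mm_min * 1000 / 60
    onsets = t0 + (cx * ux + cy * uy) / speed_um_s
    n = nx * ny
    return BinOnsetFit(
        bin_iy=iy.ravel(), bin_ix=ix.ravel(), center_x_um=cx, center_y_um=cy,
        amplitude=np.ones(n), t_onset=onsets, tau=np.ones(n),
        offset=np.zeros(n), r2=np.ones(n), included=np.ones(n, dtype=bool))


def _ang_err(a, b):
    return abs((a - b + 180) % 360 - 180)


def test_planar_onsets_recover_speed_and_direction():
    est = estimate_speed_direction(_plane_fits(90.0, 3.8))
    assert est.speed_mm_per_min == pytest.approx(3.8, rel=1e-6)
    assert _ang_err(est.direction_deg, 90.0) < 1e-6


def test_rotated_wave_rotates_direction_only():
    a = estimate_speed_direction(_plane_fits(0.0, 3.8))
    b = estimate_speed_direction(_plane_fits(90.0, 3.8))
    assert _ang_err(a.direction_deg, 0.0) < 1e-6
    assert _ang_err(b.direction_deg, 90.0) < 1e-6
    assert a.speed_mm_per_min == pytest.approx(b.speed_mm_per_min)


def test_simultaneous_onsets_no_propagation():
    fits = _plane_fits(90.0, 3.8)
    fits.t_onset[:] = 600.0
    with pytest.raises(NoPropagationError):
        estimate_speed_direction(fits)


def test_collinear_bins_direction_undefined():
    fits = _plane_fits(0.0, 3.8, ny=1, nx=8)
    with pytest.raises(ValueError, match="collinear"):
        estimate_speed_direction(fits)


def test_too_few_bins_rejected():
    fits = _plane_fits(90.0, 3.8)
    fits.included[5:] = False
    with pytest.raises(ValueError, match="included bins"):
        estimate_speed_direction(fits)


# --- along-fiber pace ----------------------------------------------------

def _fiber_traces(onsets_s, n_frames=200, tau=0.5):
    t = np.arange(n_frames) / FS
    return np.stack([5.0 / (1 + np.exp(-(t - o) / tau)) for o in onsets_s])


def test_planted_sequential_onsets_give_pace():
    pos = np.c_[np.arange(4) * 100.0, np.zeros(4)]  # 300 um fiber
    onsets = 60.0 + np.arange(4) * 1.0              # 1 s per 100 um
    traces = _fiber_traces(onsets)
    pace, table = fiber_activation_pace(traces, pos, (40, 120), FS)
    assert pace == pytest.approx(10.0, rel=0.05)
    assert table["usable"].all()


def test_simultaneous_activation_near_zero_pace():
    pos = np.c_[np.arange(4) * 100.0, np.zeros(4)]
    traces = _fiber_traces(np.full(4, 60.0))
    pace, _ = fiber_activation_pace(traces, pos, (40, 120), FS)
    assert abs(pace) < 0.5


def test_reversed_order_flips_pace_sign():
    pos = np.c_[np.arange(4) * 100.0, np.zeros(4)]
    onsets = 60.0 + np.arange(4) * 1.0
    traces = _fiber_traces(onsets)
    fwd, _ = fiber_activation_pace(traces, pos, (40, 120), FS)
    rev, _ = fiber_activation_pace(traces[::-1], pos[::-1], (40, 120), FS)
    assert rev == pytest.approx(-fwd, rel=1e-6)


def test_short_fiber_rejected():
    pos = np.c_[np.arange(4) * 50.0, np.zeros(4)]  # 150 um < 200 um
    traces = _fiber_traces(np.full(4, 60.0))
    with pytest.raises(ValueError, match="length"):
        fiber_activation_pace(traces, pos, (40, 120), FS)


def test_too_few_rois_rejected():
    pos = np.c_[[0.0, 300.0], [0.0, 0.0]]
    traces = _fiber_traces([60.0, 61.0])
    with pytest.raises(ValueError, match="3 ROIs"):
        fiber_activation_pace(traces, pos, (40, 120), FS)
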