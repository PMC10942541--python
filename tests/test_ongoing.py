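import numpy as np
import pytest

from afferent_csd.ongoing import bin_ongoing_rate, classify_ongoing_change
from afferent_csd.signals import EventTrain, _runs

FS = 1.03
BIN = int(round(60 * FS))  # frames per 1-min bin


def _train(ind):
    ind = np.asarray(ind, dtype=bool)
    on, off = _runs(ind)
    return EventTrain(onsets=on, offsets=off,
                      peak_dff=np.full(len(on), 0.1),
                      peak_z=np.full(len(on), 2.0), n_frames=len(ind))


# --- binned rates --------------------------------------------------------

def test_no_events_zero_bins():
    n = 5 * BIN
    rates, cov = bin_ongoing_rate(_train(np.zeros(n, dtype=bool)),
                                  np.ones(n, dtype=bool), FS)
    np.testing.assert_allclose(rates, 0.0)
    np.testing.assert_allclose(cov, 1.0)


def test_saturated_events_give_unit_bins():
    n = 3 * BIN
    rates, _ = bin_ongoing_rate(_train(np.ones(n, dtype=bool)),
                                np.ones(n, dtype=bool), FS)
    np.testing.assert_allclose(rates, 1.0)


def test_forced_ratio_in_fully_still_minute():
    n = 2 * BIN
    ind = np.zeros(n, dtype=bool)
    k = int(round(12 * FS))       # 12 s of a 60-s still bin -> 0.2
    ind[:k] = True
    rates, _ = bin_ongoing_rate(_train(ind), np.ones(n, dtype=bool), FS)
    assert rates[0] == pytest.approx(k / BIN)
    assert rates[0] == pytest.approx(0.2, abs=0.01)


def test_low_coverage_bins_missing():
    n = 2 * BIN
    still = np.ones(n, dtype=bool)
    still[: int(0.8 * BIN)] = False  # first bin only 20% still
    rates, cov = bin_ongoing_rate(_train(np.zeros(n, dtype=bool)), still, FS)
    assert np.isnan(rates[0]) and cov[0] < 0.5
    assert rates[1] == 0.0


# --- change classification ----------------------------------------------

def _profile(rates, **kw):
    kw.setdefault("wave_onset_min", 20.0)
    kw.setdefault("wave_offset_min", 21.0)
    return classify_ongoing_change(np.asarray(rates, dtype=float),
                                   np.ones(len(rates)), **kw)


def _rates(baseline=0.06, n_pre=20, post=()):
    r = [baseline] * n_pre
    rng = np.random.default_rng(5)
    r = list(0.05 + 0.02 * rng.random(n_pre))
    r += list(post)
    return r


def test_unchanged_post_is_none():
    rates = _rates(post=[0.06] * 60)
    prof = _profile(rates)
    assert prof.classification == "none"
    assert prof.onset_latency_min is None and prof.duration_min is None


def test_step_activation_latency_and_duration():
    # occupancy steps 5% -> 30% at +25 min after the wave, for 25 min
    post = [0.05] * 25 + [0.30] * 25 + [0.05] * 20
    prof = _profile(_rates(post=post))
    assert prof.classification == "activated"
    assert prof.onset_latency_min == pytest.approx(25.0, abs=1.0)
    assert prof.duration_min == pytest.approx(25.0, abs=2.0)


def test_immediate_silence_is_suppressed():
    post = [0.0] * 25 + [0.06] * 30
    prof = _profile(_rates(post=post))
    assert prof.classification == "suppressed"
    assert prof.onset_latency_min <= 1.0
    assert prof.duration_min == pytest.approx(25.0, abs=2.0)


def test_eight_minute_run_too_short():
    post = [0.05] * 5 + [0.35] * 8 + [0.05] * 40
    assert _profile(_rates(post=post)).classification == "none"


def test_late_onset_outside_window_is_none():
    post = [0.05] * 35 + [0.35] * 15
    prof = _profile(_rates(post=post), onset_window_min=30.0)
    assert prof.classification == "none"


def test_missing_bins_bridge_a_run():
    post = [0.0] * 8 + [np.nan] * 4 + [0.0] * 10 + [0.06] * 20
    prof = _profile(_rates(post=post))
    assert prof.classification == "suppressed"
    assert prof.duration_min == pytest.approx(22.0, abs=1.0)


def test_insufficient_baseline_raises():
    with pytest.raises(ValueError, match="baseline"):
        _profile([0.05] * 5 + [0.0] * 40, wave_onset_min=5.0,
                 wave_offset_min=6.0)


def test_classification_invariant_to_appended_excluded_frames():
    n = 40 * BIN
    ind = np.zeros(n, dtype=bool)
    ind[: int(0.07 * 20) * BIN] = False
    rng = np.random.default_rng(11)
    # sparse baseline events throughout; silence after minute 21
    for start in rng.integers(0, 20 * BIN, 25):
        ind[start: start + 3] = True
    still = np.ones(n, dtype=bool)
    r1, c1 = bin_ongoing_rate(_train(ind), still, FS)

    extra = 5 * BIN
    ind2 = np.r_[ind, np.zeros(extra, dtype=bool)]
    still2 = np.r_[still, np.zeros(extra, dtype=bool)]  # appended not-still
    r2, c2 = bin_ongoing_rate(_train(ind2), still2, FS)
    np.testing.assert_allclose(r1, r2[: len(r1)])
    p1 = classify_ongoing_change(r1, c1, 18.0, 19.0)
    p2 = classify_ongoing_change(r2, c2, 18.0, 19.0)
    assert p1.classification == p2.classification


def test_planted_cohort_recovered(csd_session):
    """Full-chain recovery of activated/suppressed/none classes."""
    from afferent_csd.signals import detect_events
    from afferent_csd.wave import detect_wave_window

    a = csd_session
    s = a.session
    w = detect_wave_window(s.background_grid.mean(axis=(0, 1)),
                           s.csd_trigger_frame, s.frame_rate_hz)
    hits = 0
    for f in range(a.cfg.n_fibers):
        ev = detect_events(a.fiber_z(f), a.fiber_dff(f), s.frame_rate_hz)
        rates, cov = bin_ongoing_rate(ev, a.locomotion.stillness_mask,
                                      s.frame_rate_hz)
        prof = classify_ongoing_change(rates, cov, w.onset_s / 60,
                                       w.offset_s / 60)
        hits += prof.classification == a.truth.ongoing_class[f]
    assert hits >= a.cfg.n_fibers - 1
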