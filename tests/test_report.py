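import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from afferent_csd.report import fdr_adjust, paired_stats, run_pipeline
from afferent_csd.session import write_session
from afferent_csd.synth import SimConfig, generate_session


# --- FDR -----------------------------------------------------------------

def test_single_p_unchanged():
    np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])


def test_bh_stepup_hand_computed():
    # BH: p_(i) * m / i with a running minimum from the largest rank down
    got = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])
    got = fdr_adjust([0.001, 0.02, 0.8])
    np.testing.assert_allclose(got, [0.003, 0.03, 0.8])


def test_all_ones_stay_ones():
    np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)


def test_out_of_range_rejected():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_adjusted_at_least_raw_and_bounded(ps):
    adj = fdr_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)


# --- paired statistics ---------------------------------------------------

def test_paired_t_matches_textbook_formula():
    pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    post = np.array([1.4, 2.1, 3.8, 4.2, 5.9])
    res = paired_stats(pre, post, test="paired_t", seed=1)
    d = post - pre
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert res.statistic == pytest.approx(t)
    assert res.p_value == pytest.approx(
        2 * sps.t.sf(abs(t), df=len(d) - 1))
    assert res.ci_low < d.mean() < res.ci_high


def test_identical_samples_flagged_degenerate():
    x = np.arange(5, dtype=float)
    res = paired_stats(x, x, test="wilcoxon", seed=0)
    assert res.flagged and res.p_value == 1.0
    assert (res.ci_low, res.ci_high) == (0.0, 0.0)


def test_wilcoxon_detects_clear_shift(rng):
    pre = rng.normal(0, 1, 30)
    res = paired_stats(pre, pre + 2.0, test="wilcoxon", seed=0)
    assert res.p_value < 1e-4
    assert res.ci_low > 1.5


def test_bootstrap_ci_deterministic_per_seed(rng):
    pre = rng.normal(0, 1, 20)
    post = pre + rng.normal(0.5, 1, 20)
    a = paired_stats(pre, post, seed=42)
    b = paired_stats(pre, post, seed=42)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def test_paired_power_at_one_sd_shift():
    # a 1-SD shift at n=20 should be detected most of the time
    r = np.random.default_rng(99)
    hits = sum(
        paired_stats(r.normal(0, 1, 20), r.normal(1, 1, 20),
                     seed=0).p_value < 0.05
        for _ in range(50)
    )
    assert hits >= 40


def test_unknown_test_rejected():
    with pytest.raises(ValueError):
        paired_stats([1, 2, 3], [1, 2, 4], test="anova")


# --- pipeline ------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_session_path(tmp_path_factory):
    cfg = SimConfig(seed=555, pre_min=20, post_min=30, n_fibers=5)
    session, _ = generate_session(cfg)
    p = tmp_path_factory.mktemp("sess") / "tiny.h5"
    write_session(session, p)
    return p


def test_pipeline_produces_all_sections(tiny_session_path, tmp_path):
    rep = run_pipeline(tiny_session_path, out_dir=tmp_path / "out", seed=0)
    assert "wave" in rep.sections
    assert "ongoing_counts" in rep.sections
    assert "sensitization" in rep.sections
    for p in rep.paths.values():
        assert json.loads(json.dumps(p)) and __import__("pathlib").Path(p).exists()
    report = json.loads((tmp_path / "out" / "report.json").read_text())
    assert report["sections"]["wave"]["speed_mm_per_min"] > 0


def test_pipeline_deterministic_rerun(tiny_session_path, tmp_path):
    r1 = run_pipeline(tiny_session_path, out_dir=tmp_path / "a", seed=0)
    r2 = run_pipeline(tiny_session_path, out_dir=tmp_path / "b", seed=0)
    assert r1.sections["wave"] == r2.sections["wave"]
    assert r1.sections["sensitization"]["category_counts"] == \
        r2.sections["sensitization"]["category_counts"]


def test_pipeline_without_csd_skips_csd_stages(tmp_path):
    cfg = SimConfig(seed=556, pre_min=20, post_min=1, csd=False, n_fibers=4)
    session, _ = generate_session(cfg)
    p = tmp_path / "nocsd.h5"
    write_session(session, p)
    rep = run_pipeline(p, out_dir=tmp_path / "out", seed=0)
    assert "wave" in rep.skipped and "ongoing" in rep.skipped
    assert "sensitization_glm" in rep.skipped
    assert "bouts" in rep.paths


def test_pipeline_outputs_confined_to_out_dir(tiny_session_path, tmp_path):
    out = tmp_path / "only_here"
    before = set(tmp_path.iterdir())
    run_pipeline(tiny_session_path, out_dir=out, seed=0)
    after = set(tmp_path.iterdir())
    assert after - before == {out}


# --- CLI -----------------------------------------------------------------

def test_cli_simulate_and_events(tmp_path):
    from afferent_csd.cli import main

    sess = tmp_path / "s.h5"
    truth = tmp_path / "t.json"
    cfgp = tmp_path / "cfg.json"
    cfgp.write_text(json.dumps({"pre_min": 12, "post_min": 1, "csd": False,
                                "n_fibers": 3}))
    assert main(["simulate", "--config", str(cfgp), "--seed", "5",
                 "--out", str(sess), "--truth", str(truth)]) == 0
    assert sess.exists() and json.loads(truth.read_text())["fiber_of_roi"]
    out = tmp_path / "events.csv"
    assert main(["events", "--in", str(sess), "--out", str(out)]) == 0
    assert out.exists()


def test_cli_validation_error_exit_code(tmp_path):
    from afferent_csd.cli import main

    cfgp = tmp_path / "bad.json"
    cfgp.write_text(json.dumps({"not_a_key": 1}))
    assert main(["simulate", "--config", str(cfgp),
                 "--out", str(tmp_path / "x.h5")]) == 1
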