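import numpy as np
import pytest

from afferent_csd.glm import (FAMILIES, GlmFit, build_design,
                              classify_sensitization, cohort_summary,
                              family_contributions, fit_glm)

FS = 1.03


def _families(rng, n=3000):
    state = (rng.random(n) < 0.25).astype(float)
    velocity = state * rng.normal(8, 1, n)
    return {
        "locomotion_state": state,
        "velocity": velocity,
        "scale": 0.3 * velocity + rng.normal(0, 1, n),
        "shear": rng.normal(0, 0.01, n),
        "zshift": 0.4 * velocity + rng.normal(0, 1.2, n),
    }


@pytest.fixture(scope="module")
def design():
    return build_design(_families(np.random.default_rng(3)), FS)


# --- design construction -------------------------------------------------

def test_design_shape_13_delays_per_family(design):
    # at ~1 Hz a -6..+6 s window is 13 one-frame shifts; 5 families -> 65
    assert design.matrix.shape[1] == 65
    for fam in FAMILIES:
        assert np.sum(design.family == fam) == 13
    assert design.delay_s.min() == pytest.approx(-6 / FS)
    assert design.delay_s.max() == pytest.approx(+6 / FS)


def test_constant_family_dropped(rng):
    fams = _families(rng)
    fams["shear"] = np.zeros_like(fams["shear"])
    d = build_design(fams, FS)
    assert d.matrix.shape[1] == 52
    assert all(f == "shear" for f, _ in d.dropped)


def test_columns_are_standardized(design):
    np.testing.assert_allclose(design.matrix.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(design.matrix.std(axis=0), 1, atol=0.1)


def test_impulse_shift_oracle(rng):
    n = 200
    k = 100
    x = np.zeros(n)
    x[k] = 1.0
    fams = {f: rng.normal(0, 1, n) for f in FAMILIES}
    fams["zshift"] = x
    d = build_design(fams, FS)
    n_lag = 6
    for dcol in (-3, 0, 4):
        col = d.matrix[:, (d.family == "zshift") & (d.delay_frames == dcol)]
        # column at delay dcol holds x(t - dcol): spike appears at row k+dcol
        assert np.argmax(col.ravel()) == k + dcol - n_lag


def test_reference_standardization_reuses_stats(rng):
    fams = _families(rng)
    d1 = build_design(fams, FS)
    shifted = {k: v + 5.0 for k, v in fams.items()}
    d2 = build_design(shifted, FS, reference=d1)
    np.testing.assert_allclose(d2.col_mean, d1.col_mean)
    np.testing.assert_allclose(d2.col_sd, d1.col_sd)
    # a uniform +5 offset shows up as shifted standardized columns
    assert (d2.matrix.mean(axis=0) > d1.matrix.mean(axis=0)).all()


def test_short_series_rejected(rng):
    fams = {k: v[:10] for k, v in _families(rng).items()}
    with pytest.raises(ValueError, match="lag"):
        build_design(fams, FS)


# --- model fitting -------------------------------------------------------

def test_perfect_linear_response_near_unit_deviance(design, rng):
    col = design.matrix[:, 30]
    fit = fit_glm(design, 0.7 * col, seed=0)
    assert fit.dev_explained_holdout >= 0.99
    assert fit.well_fit


def test_zero_variance_response_rejected(design):
    with pytest.raises(ValueError, match="variance"):
        fit_glm(design, np.zeros(design.n_rows), seed=0)


def test_short_epoch_rejected(rng):
    fams = {k: v[:400] for k, v in _families(rng).items()}
    d = build_design(fams, FS)
    with pytest.raises(ValueError, match="duration"):
        fit_glm(d, np.ones(d.n_rows), seed=0)


def test_single_column_coupling_recovered(design, rng):
    col = np.flatnonzero((design.family == "zshift")
                         & (design.delay_frames == 0))[0]
    y = 0.8 * design.matrix[:, col] + rng.standard_normal(design.n_rows)
    fit = fit_glm(design, y, seed=0)
    bz = np.abs(fit.beta[fit.family == "zshift"])
    assert fit.well_fit
    assert bz.max() == pytest.approx(0.8, rel=0.25)
    peak_delay = fit.delay_s[fit.family == "zshift"][np.argmax(bz)]
    assert abs(peak_delay) <= 1.01 / FS


def test_noise_response_not_well_fit(design, rng):
    devs = [fit_glm(design, rng.standard_normal(design.n_rows), seed=0)
            .dev_explained_holdout for _ in range(5)]
    assert all(d < 0.05 for d in devs)
    # in-sample fit never beaten by holdout on average (no leakage)
    fits = [fit_glm(design, rng.standard_normal(design.n_rows), seed=0)
            for _ in range(3)]
    assert np.mean([f.dev_explained_train - f.dev_explained_holdout
                    for f in fits]) >= 0


def test_fit_deterministic(design, rng):
    y = rng.standard_normal(design.n_rows)
    a = fit_glm(design, y, seed=0)
    b = fit_glm(design, y, seed=0)
    np.testing.assert_array_equal(a.beta, b.beta)
    assert a.lam == b.lam


# --- family ablation -----------------------------------------------------

def test_zshift_driven_response_attributed_to_deformation(design, rng):
    col = np.flatnonzero((design.family == "zshift")
                         & (design.delay_frames == 0))[0]
    y = 1.0 * design.matrix[:, col] + 0.5 * rng.standard_normal(design.n_rows)
    fit = fit_glm(design, y, seed=0)
    deltas = family_contributions(design, y, fit)
    assert deltas["deformation"] > 5 * max(deltas["locomotion"], 1e-6)
    assert deltas["zshift"] > deltas["scale"]


def test_locomotion_driven_response_reverses_ordering(design, rng):
    col = np.flatnonzero((design.family == "locomotion_state")
                         & (design.delay_frames == 0))[0]
    y = 1.0 * design.matrix[:, col] + 0.5 * rng.standard_normal(design.n_rows)
    fit = fit_glm(design, y, seed=0)
    deltas = family_contributions(design, y, fit)
    assert deltas["locomotion"] > deltas["deformation"]


def test_null_response_all_deltas_near_zero(design, rng):
    y = rng.standard_normal(design.n_rows)
    fit = fit_glm(design, y, seed=0)
    deltas = family_contributions(design, y, fit)
    assert all(v <= 0.02 for v in deltas.values())


# --- sensitization decision table ---------------------------------------

def _fake_fit(dev, peaks):
    fams, betas = [], []
    for fam, pk in peaks.items():
        fams += [fam] * 3
        betas += [pk, pk / 2, 0.0]
    return GlmFit(beta=np.array(betas, dtype=float), intercept=0.0,
                  alpha=0.01, lam=0.1, dev_explained_holdout=dev,
                  dev_explained_train=dev, family=np.array(fams),
                  delay_s=np.zeros(len(fams)), n_train=100, n_holdout=30)


BASE = {"locomotion_state": 0.3, "zshift": 0.4, "scale": 0.2}


@pytest.mark.parametrize("pre,post,expected", [
    ((0.2, BASE), (0.2, {**BASE, "zshift": 0.8, "scale": 0.4}),
     "sensitized_both_fit"),
    ((0.2, BASE), (0.2, BASE), "unchanged"),
    ((0.2, BASE), (0.2, {**BASE, "zshift": 0.2}), "desensitized_worse"),
    ((0.01, {}), (0.2, BASE), "sensitized_unmasked"),
    ((0.2, BASE), (0.01, {}), "desensitized_lost"),
    ((0.01, {}), (0.01, {}), "never_fit"),
], ids=["gain", "same", "loss", "unmasked", "lost", "never"])
def test_sensitization_decision_table(pre, post, expected):
    call = classify_sensitization(_fake_fit(*pre), _fake_fit(*post))
    assert call.category == expected


def test_noise_level_peaks_cannot_drive_a_call():
    pre = _fake_fit(0.2, {**BASE, "shear": 0.02})
    post = _fake_fit(0.2, {**BASE, "shear": 0.08})  # 4x rise, but tiny
    assert classify_sensitization(pre, post).category == "unchanged"


# --- cohort summary ------------------------------------------------------

def test_cohort_counts_and_contingency():
    calls = [classify_sensitization(_fake_fit(0.01, {}), _fake_fit(0.2, BASE))
             for _ in range(4)]
    calls += [classify_sensitization(_fake_fit(0.01, {}), _fake_fit(0.01, {}))
              for _ in range(6)]
    ongoing = ["activated", "none"] * 5
    out = cohort_summary(calls, ongoing)
    assert out["category_counts"]["sensitized_unmasked"] == 4
    assert out["category_counts"]["never_fit"] == 6
    assert out["contingency"].sum() == 10
    assert not out["degenerate"]
    assert 0 <= out["p_value"] <= 1


def test_degenerate_contingency_flagged():
    calls = [classify_sensitization(_fake_fit(0.01, {}), _fake_fit(0.2, BASE))
             for _ in range(4)]
    out = cohort_summary(calls, ["none"] * 4)
    assert out["degenerate"] and np.isnan(out["p_value"])


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        cohort_summary([])
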