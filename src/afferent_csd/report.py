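"""Pipeline orchestration, cohort statistics and report generation.

``run_pipeline`` executes the full analysis chain on one session container:
trace standardization and event detection -> locomotion segmentation ->
deformation extraction -> fiber clustering -> CSD wave mapping -> ongoing-
activity classification -> pre/post encoding models and sensitization
calls -> summary statistics with false-discovery-rate correction.  Stages
that need a CSD (wave, ongoing, sensitization) are skipped, and noted, when
the session has no trigger.

Statistical helpers follow the conventions used throughout: two-tailed
paired t or Wilcoxon signed-rank tests with seeded percentile-bootstrap
confidence intervals (2,000 resamples) for the mean difference, and
Benjamini-Hochberg step-up FDR adjustment within each statistics table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import fibers as fib
from . import glm as glm_mod
from . import locomotion as loco
from . import ongoing as ong
from . import signals as sig
from . import wave as wav
from .deformation import deformation_from_session
from .session import read_session

__all__ = ["PipelineReport", "run_pipeline", "paired_stats", "fdr_adjust",
           "StatResult", "default_config"]


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    flagged: bool = False


def paired_stats(
    pre, post, test: str = "paired_t", seed: int = 0, n_boot: int = 2000
) -> StatResult:
    """Two-tailed paired comparison with a bootstrap CI of the mean diff.

    ``test`` is ``paired_t`` or ``wilcoxon``.  Degenerate all-zero
    differences are flagged (Wilcoxon is undefined there) and reported with
    p = 1 and a [0, 0] interval.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or len(pre) < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    diff = post - pre
    if np.all(diff == 0):
        return StatResult(test, 0.0, 1.0, 0.0, 0.0, len(pre), flagged=True)
    if test == "paired_t":
        res = sps.ttest_rel(post, pre)
    elif test == "wilcoxon":
        res = sps.wilcoxon(post, pre)
    else:
        raise ValueError(f"unknown test '{test}'")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diff), size=(n_boot, len(diff)))
    boots = diff[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return StatResult(
        test=test, statistic=float(res.statistic), p_value=float(res.pvalue),
        ci_low=float(lo), ci_high=float(hi), n=len(pre),
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PipelineReport:
    out_dir: Path
    paths: dict[str, str] = field(default_factory=dict)
    sections: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def to_json(self) -> Path:
        p = Path(self.out_dir) / "report.json"

        def conv(x):
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        p.write_text(json.dumps(
            {"paths": self.paths, "sections": conv(self.sections),
             "skipped": self.skipped},
            indent=2,
        ))
        return p


def default_config() -> dict:
    return {
        "quiet_margin_s": 30.0,
        "min_bout_s": 2.0,
        "corr_threshold": 0.7,
        "cluster_cutoff": 0.75,
        "glm": {"alpha": 0.01, "train_fraction": 0.75, "max_lag_s": 6.0,
                "rel_increase": 0.25, "post_start_after_wave_s": 60.0},
        "ongoing": {"k_sd": 2.0, "run_min": 10.0, "onset_window_min": 30.0,
                    "min_baseline_bins": 15},
    }


def _load_config(config) -> dict:
    cfg = default_config()
    if config is None:
        return cfg
    if isinstance(config, dict):
        user = config
    else:
        text = Path(config).read_text()
        user = yaml.safe_load(text) or {}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _wave_figure(out_dir: Path, fits, estimate) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ny = fits.bin_iy.max() + 1
    nx = fits.bin_ix.max() + 1
    grid = np.full((ny, nx), np.nan)
    for iy, ix, t0, inc in zip(fits.bin_iy, fits.bin_ix, fits.t_onset,
                               fits.included):
        if inc:
            grid[iy, ix] = t0
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, cmap="viridis")
    fig.colorbar(im, ax=ax, label="onset (s)")
    ax.set_title(f"wave onset map — {estimate.speed_mm_per_min:.2f} mm/min, "
                 f"{estimate.direction_deg:.0f}°")
    p = Path(out_dir) / "wave_onset_map.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    return p


def _ongoing_figure(out_dir: Path, profiles) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.vstack([p.bin_rate for p in profiles])
    order = np.argsort([p.classification for p in profiles])
    fig, ax = plt.subplots(figsize=(7, 3.5))
    im = ax.imshow(mat[order], aspect="auto", cmap="magma",
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label="event occupancy")
    ax.set_xlabel("minute")
    ax.set_ylabel("afferent (grouped by class)")
    p = Path(out_dir) / "ongoing_activity.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    return p


class _StageLogger:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash
        self.path.write_text("")

    def log(self, stage: str, **info):
        rec = {"stage": stage, "t": time.time(), "config": self.config_hash}
        rec.update(info)
        with open(self.path, "a") as f:
            f.write(json.dumps(rec) + "\n")


def run_pipeline(session_path, config=None, out_dir="pipeline_out",
                 seed: int = 0) -> PipelineReport:
    """Run every analysis stage on one session and write the report.

    Deterministic for a fixed seed; all outputs land under ``out_dir``.
    Stage failures abort with the stage name attached to the exception.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]
    logger = _StageLogger(out_dir / "pipeline.log.jsonl", chash)
    report = PipelineReport(out_dir=out_dir)
    stage = "load"
    try:
        session = read_session(session_path)
        fs = session.frame_rate_hz
        logger.log(stage, session=session.session_id, n_frames=session.n_frames)

        stage = "locomotion"
        t0 = time.time()
        locom = loco.segment_locomotion(
            session.wheel_position, session.wheel_rate_hz, fs,
            session.n_frames, seed=seed,
            min_bout_s=cfg["min_bout_s"], margin_s=cfg["quiet_margin_s"],
        )
        bouts_path = out_dir / "bouts.csv"
        locom.bouts.to_csv(bouts_path, index=False)
        report.paths["bouts"] = str(bouts_path)
        logger.log(stage, n_bouts=len(locom.bouts), dt=time.time() - t0)

        stage = "signals"
        t0 = time.time()
        quiet = locom.stillness_mask
        traces = sig.standardize_session_traces(
            session.roi_traces, session.neuropil_traces, quiet, fs
        )
        ev_rows = []
        for i, tr in enumerate(traces):
            for a, b, pk in zip(tr.events.onsets, tr.events.offsets,
                                tr.events.peak_dff):
                ev_rows.append({"roi": i, "onset_s": a / fs, "offset_s": b / fs,
                                "peak_dff": pk})
        ev_path = out_dir / "events.csv"
        pd.DataFrame(ev_rows, columns=["roi", "onset_s", "offset_s",
                                       "peak_dff"]).to_csv(ev_path, index=False)
        report.paths["events"] = str(ev_path)
        logger.log(stage, n_events=len(ev_rows), dt=time.time() - t0)

        stage = "deformation"
        deform = deformation_from_session(session)

        stage = "clustering"
        t0 = time.time()
        graph = fib.event_correlation(
            [tr.events for tr in traces], quiet,
            corr_threshold=cfg["corr_threshold"],
        )
        fmap = fib.cluster_fibers(graph, cutoff=cfg["cluster_cutoff"])
        fib_path = out_dir / "fibers.csv"
        fmap.to_frame().to_csv(fib_path, index=False)
        report.paths["fibers"] = str(fib_path)
        fiber_z, fiber_dff = [], []
        for f in range(fmap.n_fibers):
            m = fmap.members(f)
            fiber_z.append(fib.fiber_trace(traces, m))
            fiber_dff.append(np.mean([traces[i].dff for i in m], axis=0))
        fiber_events = [
            sig.detect_events(z, d, fs) for z, d in zip(fiber_z, fiber_dff)
        ]
        logger.log(stage, n_fibers=fmap.n_fibers, dt=time.time() - t0)

        window = None
        if session.csd_trigger_frame is not None:
            stage = "wave"
            t0 = time.time()
            f_fov = session.background_grid.mean(axis=(0, 1))
            window = wav.detect_wave_window(f_fov, session.csd_trigger_frame, fs)
            excl = wav.roi_bin_exclusion_mask(
                session.roi_centroids_um, session.fov_size_um,
                session.pixel_size_um, session.bin_size_px,
            )
            bin_fits = wav.fit_bin_onsets(
                session.background_grid, window, fs,
                session.bin_size_px, session.pixel_size_um,
                roi_exclusion_mask=excl,
            )
            estimate = wav.estimate_speed_direction(bin_fits)
            bins_path = out_dir / "wave_bins.csv"
            bin_fits.to_frame().to_csv(bins_path, index=False)
            wave_path = out_dir / "wave.json"
            wave_path.write_text(json.dumps({
                "speed_mm_per_min": estimate.speed_mm_per_min,
                "direction_deg": estimate.direction_deg,
                "n_bins_included": estimate.n_bins_included,
                "onset_s": window.onset_s,
                "offset_s": window.offset_s,
                "peak_dff": window.peak_dff,
            }, indent=2))
            report.paths["wave"] = str(wave_path)
            report.paths["wave_bins"] = str(bins_path)
            report.sections["wave"] = {
                "speed_mm_per_min": estimate.speed_mm_per_min,
                "direction_deg": estimate.direction_deg,
                "n_bins_included": estimate.n_bins_included,
            }
            logger.log(stage, speed=estimate.speed_mm_per_min,
                       dt=time.time() - t0)
        else:
            report.skipped.append("wave")

        ongoing_profiles: list[ong.OngoingActivityProfile] = []
        if window is not None:
            stage = "ongoing"
            t0 = time.time()
            rows = []
            for f, events in enumerate(fiber_events):
                rates, coverage = ong.bin_ongoing_rate(events, quiet, fs)
                prof = ong.classify_ongoing_change(
                    rates, coverage,
                    wave_onset_min=window.onset_s / 60.0,
                    wave_offset_min=window.offset_s / 60.0,
                    **{k: cfg["ongoing"][k] for k in
                       ("k_sd", "run_min", "onset_window_min",
                        "min_baseline_bins")},
                )
                ongoing_profiles.append(prof)
                rows.append({
                    "fiber": f, "class": prof.classification,
                    "latency_min": prof.onset_latency_min,
                    "duration_min": prof.duration_min,
                    "baseline_rate": prof.baseline_mean,
                })
            ong_path = out_dir / "ongoing.csv"
            pd.DataFrame(rows).to_csv(ong_path, index=False)
            report.paths["ongoing"] = str(ong_path)
            counts = pd.Series([p.classification for p in ongoing_profiles])
            report.sections["ongoing_counts"] = counts.value_counts().to_dict()
            logger.log(stage, dt=time.time() - t0)
        else:
            report.skipped.append("ongoing")

        stage = "glm"
        t0 = time.time()
        gcfg = cfg["glm"]
        families_full = {
            "locomotion_state": locom.state.astype(float),
            "velocity": locom.velocity,
            "scale": deform.scale,
            "shear": deform.shear,
            "zshift": deform.zshift,
        }
        trig = session.csd_trigger_frame
        calls, glm_rows = [], []
        if trig is not None and window is not None:
            post_start = int(round(
                (window.offset_s + gcfg["post_start_after_wave_s"]) * fs
            ))
            pre_sl = slice(0, trig)
            post_sl = slice(post_start, session.n_frames)
            pre_design = glm_mod.build_design(
                {k: v[pre_sl] for k, v in families_full.items()},
                fs, max_lag_s=gcfg["max_lag_s"],
            )
            post_design = glm_mod.build_design(
                {k: v[post_sl] for k, v in families_full.items()},
                fs, max_lag_s=gcfg["max_lag_s"], reference=pre_design,
            )
            for f, z in enumerate(fiber_z):
                fit_pre = glm_mod.fit_glm(
                    pre_design, z[pre_sl], alpha=gcfg["alpha"],
                    train_fraction=gcfg["train_fraction"], seed=seed,
                )
                fit_post = glm_mod.fit_glm(
                    post_design, z[post_sl], alpha=gcfg["alpha"],
                    train_fraction=gcfg["train_fraction"], seed=seed,
                )
                glm_mod.family_contributions(pre_design, z[pre_sl], fit_pre)
                glm_mod.family_contributions(post_design, z[post_sl], fit_post)
                call = glm_mod.classify_sensitization(
                    fit_pre, fit_post, rel_increase=gcfg["rel_increase"]
                )
                calls.append(call)
                glm_rows.append({
                    "fiber": f, "category": call.category,
                    "dev_pre": fit_pre.dev_explained_holdout,
                    "dev_post": fit_post.dev_explained_holdout,
                    **{f"peak_pre_{k}": v for k, v in
                       call.family_summary_pre.items()},
                    **{f"peak_post_{k}": v for k, v in
                       call.family_summary_post.items()},
                    **{f"delta_pre_{k}": v for k, v in
                       fit_pre.family_delta.items()},
                    **{f"delta_post_{k}": v for k, v in
                       fit_post.family_delta.items()},
                })
            sens_path = out_dir / "sensitization.csv"
            pd.DataFrame(glm_rows).to_csv(sens_path, index=False)
            report.paths["sensitization"] = str(sens_path)
            ocls = ([p.classification for p in ongoing_profiles]
                    if ongoing_profiles else None)
            summary = glm_mod.cohort_summary(calls, ocls)
            summary.pop("contingency", None)
            report.sections["sensitization"] = summary
        else:
            report.skipped.append("sensitization_glm")
        logger.log(stage, n_calls=len(calls), dt=time.time() - t0)

        stage = "figures"
        if window is not None:
            try:
                fig_path = _wave_figure(out_dir, bin_fits, estimate)
                report.paths["wave_figure"] = str(fig_path)
                if ongoing_profiles:
                    fig_path = _ongoing_figure(out_dir, ongoing_profiles)
                    report.paths["ongoing_figure"] = str(fig_path)
            except Exception as exc:  # figures are best-effort
                logger.log(stage, warning=str(exc))

        stage = "statistics"
        stats_rows = []
        if trig is not None:
            pre_b = locom.bouts[locom.bouts["end_frame"] <= trig]
            post_b = locom.bouts[locom.bouts["start_frame"] >= trig]
            pre_min = trig / fs / 60.0
            post_min = (session.n_frames - trig) / fs / 60.0
            report.sections["bout_rate_per_min"] = {
                "pre": len(pre_b) / pre_min, "post": len(post_b) / post_min,
            }
            for metric in ("duration_s", "peak_velocity"):
                a, b = pre_b[metric].values, post_b[metric].values
                if len(a) >= 3 and len(b) >= 3:
                    res = sps.mannwhitneyu(a, b, alternative="two-sided")
                    stats_rows.append({
                        "comparison": f"bout_{metric}_pre_vs_post",
                        "test": "mannwhitneyu",
                        "statistic": float(res.statistic),
                        "p": float(res.pvalue),
                    })
        if stats_rows:
            tbl = pd.DataFrame(stats_rows)
            tbl["p_fdr"] = fdr_adjust(tbl["p"].values)
            stats_path = out_dir / "stats.csv"
            tbl.to_csv(stats_path, index=False)
            report.paths["stats"] = str(stats_path)
            report.sections["stats"] = tbl.to_dict(orient="records")

        report.paths["report"] = str(report.to_json())
        logger.log("done")
        return report
    except Exception as exc:
        logger.log("error", stage=stage, error=str(exc))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
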