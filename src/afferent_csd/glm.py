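"""Lagged elastic-net encoding models and sensitization classification.

Each afferent's standardized activity is modelled as a Gaussian GLM on five
predictor families — binary locomotion state, velocity, and the three
deformation series (scale, shear, Z-shift) — each expanded into temporally
shifted copies spanning -6..+6 s at one-frame steps.  The model is fit on
the first 75% of the epoch with elastic-net regularization (mixing
parameter alpha = 0.01, i.e. nearly ridge), the penalty weight chosen by
10-fold blocked cross-validation within the training segment, and judged by
the deviance explained on the held-out last 25% (well fit when >= 0.05).

Family contributions are the drop in held-out deviance explained when a
family's columns are removed and the model refit at the same penalty.

An afferent is sensitized when a family's peak |beta| rises by at least 10%
post-CSD (both epochs well fit), or when it is well fit only post-CSD
(unmasked).  Predictors are standardized with baseline-epoch statistics for
both epochs so coefficients compare per physical unit of deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV

FAMILIES = ("locomotion_state", "velocity", "scale", "shear", "zshift")
FAMILY_GROUPS = {
    "locomotion": ("locomotion_state", "velocity"),
    "deformation": ("scale", "shear", "zshift"),
    "scale": ("scale",),
    "shear": ("shear",),
    "zshift": ("zshift",),
}

__all__ = [
    "LaggedDesign",
    "GlmFit",
    "SensitizationCall",
    "build_design",
    "fit_glm",
    "family_contributions",
    "classify_sensitization",
    "cohort_summary",
    "FAMILIES",
    "FAMILY_GROUPS",
]


@dataclass
class LaggedDesign:
    matrix: np.ndarray          # [n_valid_rows, n_cols], standardized
    family: np.ndarray          # per-column family name
    delay_s: np.ndarray         # per-column delay in seconds (+ = leads)
    delay_frames: np.ndarray
    col_mean: np.ndarray        # standardization statistics actually applied
    col_sd: np.ndarray
    valid: slice                # rows of the source series kept after trimming
    frame_rate_hz: float
    dropped: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def response(self, z: np.ndarray) -> np.ndarray:
        """Align a response series with the trimmed design rows.

        Accepts either the full-length source series (trimmed here) or a
        series already aligned with the design rows.
        """
        z = np.asarray(z, dtype=float)
        if len(z) == self.n_rows:
            return z
        return z[self.valid]

    def columns_for(self, families: tuple[str, ...]) -> np.ndarray:
        return np.flatnonzero(np.isin(self.family, families))

    def stats(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Standardization statistics keyed by (family, delay) for reuse."""
        return self.family, self.delay_frames, self.col_mean, self.col_sd


def build_design(
    families: dict[str, np.ndarray],
    frame_rate_hz: float,
    max_lag_s: float = 6.0,
    reference: LaggedDesign | None = None,
) -> LaggedDesign:
    """Build the lagged, standardized design matrix.

    ``families`` maps family name to its frame-rate series.  A column with
    positive delay ``d`` holds ``x(t - d)``: the predictor leads the
    response.  Rows where any shift is undefined are trimmed symmetrically
    (``max_lag`` frames at each end).  Columns are z-scored; when a
    ``reference`` design is given its statistics are applied instead (used
    to standardize the post-CSD epoch with baseline statistics).
    Zero-variance columns are dropped and recorded.
    """
    names = [f for f in FAMILIES if f in families]
    if not names:
        raise ValueError("no known predictor families supplied")
    n = len(np.asarray(families[names[0]]))
    n_lag = int(round(max_lag_s * frame_rate_hz))
    if n <= 2 * n_lag + 1:
        raise ValueError("series shorter than twice the maximum lag")
    valid = slice(n_lag, n - n_lag)
    ref_stats = None
    if reference is not None:
        ref_stats = {
            (f, int(d)): (m, s)
            for f, d, m, s in zip(*reference.stats())
        }
    cols, fam_meta, delay_meta, means, sds, dropped = [], [], [], [], [], []
    for fam in names:
        x = np.asarray(families[fam], dtype=float)
        if x.shape != (n,):
            raise ValueError(f"family '{fam}' is not aligned ({x.shape})")
        for d in range(-n_lag, n_lag + 1):
            col = x[n_lag - d: n - n_lag - d]
            if ref_stats is not None:
                key = (fam, d)
                if key not in ref_stats:
                    dropped.append((fam, d))
                    continue
                m, s = ref_stats[key]
            else:
                m, s = float(col.mean()), float(col.std())
                if s == 0.0:
                    dropped.append((fam, d))
                    continue
            cols.append((col - m) / s)
            fam_meta.append(fam)
            delay_meta.append(d)
            means.append(m)
            sds.append(s)
    if not cols:
        raise ValueError("all predictor columns are constant")
    return LaggedDesign(
        matrix=np.column_stack(cols),
        family=np.asarray(fam_meta),
        delay_s=np.asarray(delay_meta, dtype=float) / frame_rate_hz,
        delay_frames=np.asarray(delay_meta, dtype=int),
        col_mean=np.asarray(means),
        col_sd=np.asarray(sds),
        valid=valid,
        frame_rate_hz=frame_rate_hz,
        dropped=dropped,
    )


@dataclass
class GlmFit:
    beta: np.ndarray
    intercept: float
    alpha: float                     # elastic-net mixing parameter (l1 ratio)
    lam: float                       # selected penalty weight
    dev_explained_holdout: float
    dev_explained_train: float
    family: np.ndarray
    delay_s: np.ndarray
    n_train: int
    n_holdout: int
    family_delta: dict[str, float] = field(default_factory=dict)

    @property
    def well_fit(self) -> bool:
        return self.dev_explained_holdout >= 0.05

    def family_peaks(self) -> dict[str, float]:
        """Peak |beta| across delays for every family."""
        return {
            fam: float(np.max(np.abs(self.beta[self.family == fam]), initial=0.0))
            for fam in dict.fromkeys(self.family)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"family": self.family, "delay_s": self.delay_s, "beta": self.beta}
        )


def _split(n: int, train_fraction: float) -> int:
    return int(round(n * train_fraction))


def _deviance_explained(y_true, y_pred, null_value) -> float:
    sse = float(np.sum((y_true - y_pred) ** 2))
    sse_null = float(np.sum((y_true - null_value) ** 2))
    if sse_null == 0:
        return 0.0
    return 1.0 - sse / sse_null


def fit_glm(
    design: LaggedDesign,
    z: np.ndarray,
    train_fraction: float = 0.75,
    alpha: float = 0.01,
    seed: int = 0,
    cv_folds: int = 10,
    n_lambdas: int = 30,
    min_duration_s: float = 600.0,
) -> GlmFit:
    """Fit the elastic-net encoding model for one afferent epoch.

    The train/holdout split is contiguous (first 75% / last 25%) to respect
    temporal autocorrelation, and the cross-validation folds within the
    training segment are contiguous blocks.  The null model for deviance is
    the training-set mean.  The procedure is deterministic for a given
    design and response.
    """
    y = design.response(z)
    if design.n_rows / design.frame_rate_hz < min_duration_s:
        raise ValueError("epoch shorter than the minimum fitting duration")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    X = design.matrix
    n_train = _split(len(y), train_fraction)
    X_tr, y_tr = X[:n_train], y[:n_train]
    X_ho, y_ho = X[n_train:], y[n_train:]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv_model = ElasticNetCV(
            l1_ratio=alpha,
            alphas=n_lambdas,
            eps=1e-3,
            cv=cv_folds,
            fit_intercept=True,
            max_iter=3000,
            random_state=seed,
        )
        cv_model.fit(X_tr, y_tr)
    null_value = float(y_tr.mean())
    dev_ho = _deviance_explained(y_ho, cv_model.predict(X_ho), null_value)
    dev_tr = _deviance_explained(y_tr, cv_model.predict(X_tr), null_value)
    return GlmFit(
        beta=np.asarray(cv_model.coef_, dtype=float),
        intercept=float(cv_model.intercept_),
        alpha=alpha,
        lam=float(cv_model.alpha_),
        dev_explained_holdout=dev_ho,
        dev_explained_train=dev_tr,
        family=design.family.copy(),
        delay_s=design.delay_s.copy(),
        n_train=n_train,
        n_holdout=len(y) - n_train,
    )


def family_contributions(
    design: LaggedDesign,
    z: np.ndarray,
    fit: GlmFit,
    groups: dict[str, tuple[str, ...]] | None = None,
    train_fraction: float = 0.75,
) -> dict[str, float]:
    """Held-out deviance lost when a predictor group is ablated.

    Each reduced model is refit at the penalty selected for the full model;
    deltas are floored at zero for reporting.  The result is stored on the
    fit's ``family_delta``.
    """
    groups = FAMILY_GROUPS if groups is None else groups
    y = design.response(z)
    X = design.matrix
    n_train = _split(len(y), train_fraction)
    null_value = float(y[:n_train].mean())
    deltas = {}
    import warnings

    for name, fams in groups.items():
        keep = ~np.isin(design.family, fams)
        if keep.all():
            deltas[name] = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = ElasticNet(
                alpha=fit.lam, l1_ratio=fit.alpha, fit_intercept=True,
                max_iter=3000,
            )
            model.fit(X[:n_train][:, keep], y[:n_train])
        dev_red = _deviance_explained(
            y[n_train:], model.predict(X[n_train:][:, keep]), null_value
        )
        deltas[name] = max(0.0, fit.dev_explained_holdout - dev_red)
    fit.family_delta = deltas
    return deltas


CATEGORIES = (
    "sensitized_both_fit",
    "sensitized_unmasked",
    "desensitized_worse",
    "desensitized_lost",
    "unchanged",
    "never_fit",
)


@dataclass
class SensitizationCall:
    category: str
    family_summary_pre: dict[str, float]
    family_summary_post: dict[str, float]

    @property
    def sensitized(self) -> bool:
        return self.category.startswith("sensitized")

    @property
    def desensitized(self) -> bool:
        return self.category.startswith("desensitized")


def classify_sensitization(
    fit_pre: GlmFit,
    fit_post: GlmFit,
    rel_increase: float = 0.25,
    min_peak: float = 0.10,
) -> SensitizationCall:
    """Decision table over pre/post fit quality and coefficient change.

    Both epochs well fit: sensitized when any family's peak |beta| rises by
    at least ``rel_increase`` relatively; desensitized when no family rises
    and at least one falls by the same margin; otherwise unchanged.  Only
    families whose larger peak reaches ``min_peak`` participate, and the
    margin is referenced to ``max(peak_pre, min_peak)``, so noise-level
    coefficients cannot drive a call.  The margin must exceed the typical
    cross-epoch estimation noise of a family peak (roughly 15-25% here);
    a genuine gain such as a doubling clears it by a wide margin.
    Only post well fit: sensitized_unmasked.  Only pre: desensitized_lost.
    Neither: never_fit.
    """
    pre = fit_pre.family_peaks()
    post = fit_post.family_peaks()
    fams = sorted(set(pre) | set(post))
    if fit_pre.well_fit and fit_post.well_fit:
        rises, falls = [], []
        for fam in fams:
            a, b = pre.get(fam, 0.0), post.get(fam, 0.0)
            if max(a, b) < min_peak:
                continue
            base = max(a, min_peak)
            if b - a >= rel_increase * base:
                rises.append(fam)
            elif a - b >= rel_increase * base:
                falls.append(fam)
        if rises:
            category = "sensitized_both_fit"
        elif falls:
            category = "desensitized_worse"
        else:
            category = "unchanged"
    elif fit_post.well_fit:
        category = "sensitized_unmasked"
    elif fit_pre.well_fit:
        category = "desensitized_lost"
    else:
        category = "never_fit"
    return SensitizationCall(
        category=category, family_summary_pre=pre, family_summary_post=post
    )


def cohort_summary(
    calls: list[SensitizationCall],
    ongoing_classes: list[str] | None = None,
) -> dict:
    """Category counts and the sensitization-by-ongoing-class contingency.

    Returns category counts; when per-afferent ongoing-activity classes are
    supplied, a 2 x k contingency table (sensitized yes/no by ongoing
    class) with its chi-square statistic and p-value.  Degenerate tables
    (a dimension with a single level, or an all-zero margin) are flagged
    and carry NaN statistics.
    """
    if not calls:
        raise ValueError("empty cohort")
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    out: dict = {"category_counts": counts, "n": len(calls)}
    if ongoing_classes is not None:
        if len(ongoing_classes) != len(calls):
            raise ValueError("ongoing classes must align with calls")
        classes = sorted(set(ongoing_classes))
        sens = np.array([c.sensitized for c in calls])
        table = np.array(
            [
                [np.sum(sens & (np.asarray(ongoing_classes) == cl)) for cl in classes],
                [np.sum(~sens & (np.asarray(ongoing_classes) == cl)) for cl in classes],
            ]
        )
        out["contingency_classes"] = classes
        out["contingency"] = table
        degenerate = (
            len(classes) < 2
            or table.sum(axis=1).min() == 0
            or table.sum(axis=0).min() == 0
        )
        out["degenerate"] = bool(degenerate)
        if degenerate:
            out["chi2"], out["p_value"] = float("nan"), float("nan")
        else:
            res = stats.chi2_contingency(table)
            out["chi2"], out["p_value"] = float(res.statistic), float(res.pvalue)
    return out
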