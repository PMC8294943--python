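"""Evaluation harness: ridge regression with repeated CV and model comparison.

Feature matrices (latent or ROI) are evaluated by how well they predict
demographic/clinical targets under ridge regression with fivefold
cross-validation repeated ten times.  Continuous targets are scored by
RMSE; the binary diagnosis target is scored by accuracy after
thresholding the ridge prediction at 0.5.  Feature columns are
standardized using training-fold statistics only, so held-out subjects
never leak into the fit.

Architectures are compared by a two-way fixed-effects ANOVA
(channels x blocks, with interaction) on the per-repeat mean scores,
followed by Tukey HSD within each factor; a feature set is compared
against the ROI baseline by an unpaired, equal-variance two-sample
t-test on the repeat means.  Significance level 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .features import FeatureMatrix

__all__ = [
    "RegressionReport",
    "FittedRidge",
    "AnovaTable",
    "ridge_cv",
    "fit_ridge",
    "compare_models_anova",
    "compare_to_roi_ttest",
]

ALPHA_LEVEL = 0.05


@dataclass
class RegressionReport:
    """Per-(repeat, fold) scores for one target/feature-set pair."""

    target: str
    provenance: dict
    records: pd.DataFrame       # columns: repeat, fold, score
    metric: str                 # "rmse" | "accuracy"
    n_subjects: int
    folds: int
    repeats: int
    ridge_penalty: float
    seed: int

    @property
    def repeat_means(self) -> np.ndarray:
        return (self.records.groupby("repeat")["score"].mean()
                .sort_index().to_numpy())

    @property
    def mean(self) -> float:
        return float(self.repeat_means.mean())

    @property
    def sd(self) -> float:
        return float(self.repeat_means.std(ddof=1))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {"target": self.target, "metric": self.metric,
                "mean": self.mean, "sd": self.sd, "n": self.n_subjects,
                "folds": self.folds, "repeats": self.repeats,
                "ridge_penalty": self.ridge_penalty, "seed": self.seed}


@dataclass
class FittedRidge:
    """A ridge fit on standardized features, with its input-space gradient.

    ``coef`` applies to standardized columns; since standardization is
    affine, the gradient of the prediction with respect to the raw
    features is simply ``coef / scale`` — the quantity saliency needs.
    """

    coef: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    penalty: float
    target: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self.feature_mean) / self.feature_scale
        return Xs @ self.coef + self.intercept

    def feature_gradient(self) -> np.ndarray:
        return self.coef / self.feature_scale


def _standardize_cols(X: np.ndarray):
    """Column mean/scale with numerically-constant columns left unscaled.

    Latent features are float32 and contain dead units whose "variance"
    is rounding noise (~1e-6 of the live columns'); amplifying those to
    unit variance lets a single out-of-fold subject explode a ridge
    prediction.  Columns below 1e-6 of the largest column SD keep scale
    1 — after centering they contribute nothing to the fit.
    """
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    floor = 1e-6 * scale.max() if scale.max() > 0 else 0.0
    scale[scale <= floor] = 1.0
    return mean, scale


def fit_ridge(features: FeatureMatrix | np.ndarray, y, penalty: float = 1.0,
              target: str = "") -> FittedRidge:
    """Full-data ridge fit (used for saliency, not for evaluation)."""
    X = features.matrix if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(y, dtype=np.float64)
    mean, scale = _standardize_cols(X.astype(np.float64))
    Xs = (X - mean) / scale
    model = Ridge(alpha=penalty)
    model.fit(Xs, y)
    return FittedRidge(coef=model.coef_.astype(np.float64),
                       intercept=float(model.intercept_),
                       feature_mean=mean, feature_scale=scale,
                       penalty=penalty, target=target)


def _inner_cv_penalty(X, y, grid, folds, seed) -> float:
    """Choose the ridge penalty by CV *within* the training fold."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best, best_err = grid[0], np.inf
    for alpha in grid:
        errs = []
        for tr, te in kf.split(X):
            mean, scale = _standardize_cols(X[tr].astype(np.float64))
            m = Ridge(alpha=alpha).fit((X[tr] - mean) / scale, y[tr])
            pred = m.predict((X[te] - mean) / scale)
            errs.append(np.mean((pred - y[te]) ** 2))
        err = float(np.mean(errs))
        if err < best_err:
            best, best_err = alpha, err
    return best


def ridge_cv(features: FeatureMatrix | np.ndarray, target, folds: int = 5,
             repeats: int = 10, ridge_penalty: float = 1.0, seed: int = 0,
             target_name: str = "", binary: bool | None = None,
             penalty_grid=None) -> RegressionReport:
    """Repeated k-fold ridge evaluation.

    For each repeat the subjects are reshuffled (seeded) into ``folds``
    folds; the model is fitted on the training folds — with feature
    columns standardized by training-fold statistics — and scored on
    the held-out fold.  Continuous targets yield RMSE; a {0,1} target
    (``binary=True`` or auto-detected) yields accuracy of the
    0.5-thresholded prediction.

    With ``penalty_grid`` given, the penalty is re-selected inside every
    training fold by an inner 3-fold CV — held-out subjects never touch
    the selection.  Rows with missing targets must be removed by the
    caller (clinical targets exist for patients only).
    """
    X = features.matrix if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(target, dtype=np.float64)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise ValueError("target must be 1D with one value per subject")
    if np.isnan(y).any():
        raise ValueError("target has missing values; restrict rows first")
    if len(y) < folds:
        raise ValueError(f"{len(y)} subjects is fewer than {folds} folds")
    if np.allclose(y, y[0]):
        raise ValueError("constant target")
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}

    base = np.random.default_rng(seed)
    fold_seeds = base.integers(0, 2**31 - 1, size=repeats)
    records = []
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(fold_seeds[rep]))
        for fold, (tr, te) in enumerate(kf.split(X)):
            alpha = ridge_penalty
            if penalty_grid is not None:
                alpha = _inner_cv_penalty(X[tr], y[tr], list(penalty_grid),
                                          3, int(fold_seeds[rep]))
            mean, scale = _standardize_cols(X[tr].astype(np.float64))
            model = Ridge(alpha=alpha)
            model.fit((X[tr] - mean) / scale, y[tr])
            pred = model.predict((X[te] - mean) / scale)
            if binary:
                score = float(np.mean((pred >= 0.5) == (y[te] >= 0.5)))
            else:
                score = float(np.sqrt(np.mean((pred - y[te]) ** 2)))
            records.append({"repeat": rep, "fold": fold, "score": score})
    prov = features.provenance if isinstance(features, FeatureMatrix) else {}
    return RegressionReport(
        target=target_name, provenance=prov,
        records=pd.DataFrame.from_records(records),
        metric="accuracy" if binary else "rmse",
        n_subjects=len(y), folds=folds, repeats=repeats,
        ridge_penalty=ridge_penalty, seed=seed)


@dataclass
class AnovaTable:
    table: pd.DataFrame         # statsmodels anova_lm layout
    tukey_blocks: object
    tukey_channels: object

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[f"C({factor})", "PR(>F)"])

    def f_value(self, factor: str) -> float:
        return float(self.table.loc[f"C({factor})", "F"])


def compare_models_anova(grid_reports: dict) -> AnovaTable:
    """Two-way ANOVA with interaction over an architecture grid.

    ``grid_reports`` maps ``(n_blocks, channels)`` to a
    :class:`RegressionReport` or to an array of per-repeat scores.  The
    unit of replication is the repeat-level mean.  The grid must be
    complete (every combination of the block levels and channel levels
    present) with equal replication.
    """
    rows = []
    for (blocks, channels), rep in grid_reports.items():
        scores = rep.repeat_means if isinstance(rep, RegressionReport) else np.asarray(rep, dtype=float)
        for s in scores:
            rows.append({"blocks": int(blocks), "channels": int(channels),
                         "score": float(s)})
    df = pd.DataFrame(rows)
    blocks_lv = sorted(df["blocks"].unique())
    chan_lv = sorted(df["channels"].unique())
    counts = df.groupby(["blocks", "channels"]).size()
    if len(counts) != len(blocks_lv) * len(chan_lv):
        raise ValueError("incomplete architecture grid (missing cells)")
    if counts.nunique() != 1:
        raise ValueError("unequal replication across cells")
    fit = ols("score ~ C(channels) * C(blocks)", data=df).fit()
    table = anova_lm(fit, typ=2)
    tukey_blocks = pairwise_tukeyhsd(df["score"], df["blocks"], alpha=ALPHA_LEVEL)
    tukey_channels = pairwise_tukeyhsd(df["score"], df["channels"], alpha=ALPHA_LEVEL)
    return AnovaTable(table=table, tukey_blocks=tukey_blocks,
                      tukey_channels=tukey_channels)


def compare_to_roi_ttest(cae_report: RegressionReport,
                         roi_report: RegressionReport):
    """Unpaired equal-variance t-test on the two sets of repeat means.

    Returns ``(t, p, significant)`` with significance at the 0.05 level.
    """
    a = cae_report.repeat_means
    b = roi_report.repeat_means
    if len(a) != len(b):
        raise ValueError("reports have unequal repeat counts")
    if cae_report.target != roi_report.target:
        raise ValueError("reports target different variables")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate pooled variance: equal means -> no evidence at all
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0, False
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), bool(p < ALPHA_LEVEL)
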