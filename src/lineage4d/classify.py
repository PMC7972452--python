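"""Penalized-logistic-regression outcome prediction with repeated CV.

The pipeline mirrors a glmnet-style workflow: drop low-variance and
high-missingness features, impute remaining gaps with the outcome-class
mean, min–max scale each column to [0, 1], then fit L1-penalized logistic
regression along a geometric lambda path inside stratified 5-fold
cross-validation repeated many times.  Each repetition picks the lambda
with minimal cross-validated mean squared error between predicted
probabilities and the 0/1 outcome, records the features selected by a
full-data refit at that lambda, and the repetition with the global minimum
CV error is reported as the best model together with its ROC curve.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ArgumentError

log = logging.getLogger(__name__)


@dataclass
class LassoConfig:
    n_repeats: int = 250
    k_folds: int = 5
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-3
    variance_filter: float = 0.025
    missing_filter: float = 0.25
    imputation: str = "group_mean"  # or "overall_mean"
    cv_loss: str = "mse"  # or "deviance"
    seed: int = 0

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ArgumentError("k_folds must be >= 2")
        if self.imputation not in ("group_mean", "overall_mean"):
            raise ArgumentError(f"unknown imputation {self.imputation!r}")
        if self.cv_loss not in ("mse", "deviance"):
            raise ArgumentError(f"unknown cv_loss {self.cv_loss!r}")
        if not 0 < self.lambda_min_ratio < 1:
            raise ArgumentError("lambda_min_ratio must be in (0, 1)")


@dataclass
class PreprocessReport:
    dropped_low_variance: list[str]
    dropped_missing: list[str]
    n_imputed: int
    constant_columns: list[str]


def preprocess(
    table: pd.DataFrame, labels: pd.Series, config: LassoConfig | None = None
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Filter, impute, and 0–1 scale a feature table.

    Order: (1) drop features whose min–max-rescaled variance falls below the
    variance filter (a unit-free reading of the "low overall variance"
    rule); (2) drop features with a missing fraction above the missingness
    filter; (3) impute remaining gaps with the outcome-class mean (overall
    mean as fallback); (4) min–max scale to [0, 1].  Rows are never dropped.
    """
    config = config or LassoConfig()
    config.validate()
    labels = labels.reindex(table.index)
    if labels.isna().any():
        raise ArgumentError("every embryo needs an outcome label")

    df = table.astype(float).copy()

    def _minmax(col: pd.Series) -> pd.Series:
        lo, hi = col.min(), col.max()
        if not np.isfinite(lo) or hi == lo:
            return pd.Series(0.0, index=col.index).where(col.notna())
        return (col - lo) / (hi - lo)

    scaled_var = df.apply(lambda c: _minmax(c).var(ddof=1))
    constant = [c for c in df.columns if df[c].notna().any() and df[c].nunique(dropna=True) <= 1]
    low_var = scaled_var.index[
        scaled_var.isna() | (scaled_var < config.variance_filter)
    ].tolist()
    df = df.drop(columns=low_var)

    miss_frac = df.isna().mean()
    high_missing = miss_frac.index[miss_frac > config.missing_filter].tolist()
    df = df.drop(columns=high_missing)

    n_imputed = int(df.isna().sum().sum())
    if n_imputed:
        overall = df.mean()
        if config.imputation == "group_mean":
            for g, sub in df.groupby(labels):
                gm = sub.mean().fillna(overall)
                df.loc[sub.index] = sub.fillna(gm)
        else:
            df = df.fillna(overall)
        still = df.columns[df.isna().any()].tolist()
        if still:
            log.warning("columns %s fell back to overall-mean imputation", still)
            df = df.fillna(overall)

    df = df.apply(_minmax)
    report = PreprocessReport(
        dropped_low_variance=low_var,
        dropped_missing=high_missing,
        n_imputed=n_imputed,
        constant_columns=constant,
    )
    return df, report


# ---------------------------------------------------------------------------
# lasso path helpers
# ---------------------------------------------------------------------------

def lambda_path(X: np.ndarray, y: np.ndarray, config: LassoConfig) -> np.ndarray:
    """Geometric shrinkage path bracketing the smallest all-zero lambda.

    The top of the path sits 50% above the gradient bound so the
    intercept-only ("empty") model is always reachable.
    """
    n = X.shape[0]
    resid = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ resid)) / n)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(
        lam_max * 1.5, lam_max * config.lambda_min_ratio, config.n_lambda
    )


def _fit_at_lambda(X, y, lam: float) -> LogisticRegression:
    n = X.shape[0]
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * lam),
        solver="liblinear",
        intercept_scaling=100.0,  # keep the intercept effectively unpenalized
        max_iter=1000,
        tol=1e-4,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


@dataclass
class LassoResult:
    lambdas: np.ndarray
    per_repeat: pd.DataFrame  # repeat, lambda, cv_mse, cv_accuracy, n_selected
    selected_sets: list[tuple[str, ...]]
    inclusion_frequency: pd.Series
    accuracy_mean: float
    accuracy_sd: float
    model_size_counts: pd.Series
    best_repeat: int
    best_model: LogisticRegression | None
    best_features: tuple[str, ...]
    best_coefficients: pd.Series
    feature_names: tuple[str, ...] = ()

    def summary(self) -> dict:
        return {
            "n_repeats": int(len(self.per_repeat)),
            "accuracy_mean": round(float(self.accuracy_mean), 6),
            "accuracy_sd": round(float(self.accuracy_sd), 6),
            "best_repeat": int(self.best_repeat),
            "best_cv_mse": round(float(self.per_repeat["cv_mse"].min()), 6),
            "best_features": list(self.best_features),
            "model_size_counts": {
                str(k): int(v) for k, v in self.model_size_counts.items()
            },
            "inclusion_frequency": {
                k: round(float(v), 4)
                for k, v in self.inclusion_frequency.sort_values(
                    ascending=False
                ).items()
                if v > 0
            },
        }


def lasso_cv(
    table: pd.DataFrame, labels: pd.Series, config: LassoConfig | None = None
) -> LassoResult:
    """Repeated stratified k-fold CV over an L1 logistic path.

    ``labels`` must be binary; internally the alphabetically larger class is
    coded 1.  Deterministic for a fixed (table, labels, config).
    """
    config = config or LassoConfig()
    config.validate()
    labels = labels.reindex(table.index)
    classes = sorted(map(str, labels.dropna().unique()))
    if len(classes) != 2:
        raise ArgumentError(f"need binary labels, got {classes}")
    y = (labels.astype(str) == classes[1]).to_numpy(dtype=int)
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ArgumentError("feature table contains missing values; run preprocess")
    n = X.shape[0]
    if min((y == 0).sum(), (y == 1).sum()) < config.k_folds:
        raise ArgumentError("need >= k_folds embryos per class")

    lams = lambda_path(X, y, config)
    feature_names = tuple(table.columns)

    records = []
    selected_sets: list[tuple[str, ...]] = []
    best = (np.inf, -1, None, ())
    rng = np.random.default_rng(config.seed)
    for rep in range(config.n_repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(
            n_splits=config.k_folds, shuffle=True, random_state=fold_seed
        )
        prob = np.full((n, lams.size), np.nan)
        for train, test in skf.split(X, y):
            if len(np.unique(y[train])) < 2:
                continue
            for k, lam in enumerate(lams):
                m = _fit_at_lambda(X[train], y[train], lam)
                prob[test, k] = m.predict_proba(X[test])[:, 1]
        if config.cv_loss == "deviance":
            p_clip = np.clip(prob, 1e-12, 1 - 1e-12)
            loss = -2.0 * np.nanmean(
                y[:, None] * np.log(p_clip) + (1 - y[:, None]) * np.log1p(-p_clip),
                axis=0,
            )
        else:
            loss = np.nanmean((prob - y[:, None]) ** 2, axis=0)
        k_star = int(np.nanargmin(loss))
        cv_mse = float(loss[k_star])
        cv_acc = float(np.nanmean((prob[:, k_star] >= 0.5) == y))
        full = _fit_at_lambda(X, y, lams[k_star])
        sel = tuple(
            f for f, c in zip(feature_names, full.coef_.ravel()) if abs(c) > 1e-10
        )
        selected_sets.append(sel)
        records.append(
            {
                "repeat": rep,
                "lambda": float(lams[k_star]),
                "cv_mse": cv_mse,
                "cv_accuracy": cv_acc,
                "n_selected": len(sel),
            }
        )
        if cv_mse < best[0]:
            best = (cv_mse, rep, full, sel)

    per_repeat = pd.DataFrame(records)
    inclusion = pd.Series(0.0, index=list(feature_names))
    for sel in selected_sets:
        for f in sel:
            inclusion[f] += 1.0
    inclusion /= max(len(selected_sets), 1)
    sizes = per_repeat["n_selected"].value_counts().sort_index()

    best_model = best[2]
    best_coef = pd.Series(
        best_model.coef_.ravel() if best_model is not None else [],
        index=list(feature_names) if best_model is not None else [],
    )
    return LassoResult(
        lambdas=lams,
        per_repeat=per_repeat,
        selected_sets=selected_sets,
        inclusion_frequency=inclusion,
        accuracy_mean=float(per_repeat["cv_accuracy"].mean()),
        accuracy_sd=float(per_repeat["cv_accuracy"].std(ddof=1)),
        model_size_counts=sizes,
        best_repeat=int(best[1]),
        best_model=best_model,
        best_features=best[3],
        best_coefficients=best_coef,
        feature_names=feature_names,
    )


@dataclass
class RocResult:
    points: pd.DataFrame  # threshold, sensitivity, specificity
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float
    sensitivity_at_half: float
    specificity_at_half: float


def roc_summary(probabilities: np.ndarray, y: np.ndarray) -> RocResult:
    """ROC points over the sorted unique predicted probabilities."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ArgumentError("ROC undefined for single-class input")
    fpr, tpr, thr = _sk_roc_curve(y, probabilities)
    sens, spec = tpr, 1.0 - fpr
    auc = float(np.trapezoid(tpr, fpr))
    j = sens + spec - 1.0
    jbest = int(np.argmax(j))
    pred_half = probabilities >= 0.5
    tp = int(np.sum(pred_half & (y == 1)))
    tn = int(np.sum(~pred_half & (y == 0)))
    return RocResult(
        points=pd.DataFrame(
            {"threshold": thr, "sensitivity": sens, "specificity": spec}
        ),
        auc=auc,
        youden_threshold=float(thr[jbest]),
        youden_sensitivity=float(sens[jbest]),
        youden_specificity=float(spec[jbest]),
        sensitivity_at_half=tp / max(int((y == 1).sum()), 1),
        specificity_at_half=tn / max(int((y == 0).sum()), 1),
    )


def roc_of_best_model(result: LassoResult, table: pd.DataFrame, labels: pd.Series) -> RocResult:
    classes = sorted(map(str, labels.dropna().unique()))
    y = (labels.reindex(table.index).astype(str) == classes[1]).to_numpy(dtype=int)
    prob = result.best_model.predict_proba(table.to_numpy(dtype=float))[:, 1]
    return roc_summary(prob, y)


def stage_report(
    stage_tables: dict[int, pd.DataFrame],
    labels: pd.Series,
    config: LassoConfig | None = None,
) -> dict[int, dict]:
    """Preprocess + repeated-CV Lasso per developmental stage.

    Embryo sets are restricted to the intersection across stages so that the
    same embryos are classified at every stage.
    """
    config = config or LassoConfig()
    common = None
    for df in stage_tables.values():
        idx = set(df.index)
        common = idx if common is None else (common & idx)
    common = sorted(common or [])
    if not common:
        raise ArgumentError("no embryos shared across stages")
    out = {}
    for stage in sorted(stage_tables):
        table = stage_tables[stage].loc[common]
        lab = labels.reindex(common)
        clean, report = preprocess(table, lab, config)
        res = lasso_cv(clean, lab, config)
        roc = roc_of_best_model(res, clean, lab) if res.best_model is not None else None
        out[stage] = {
            "n_embryos": len(common),
            "n_features_in": int(table.shape[1]),
            "n_features_used": int(clean.shape[1]),
            "preprocess": {
                "dropped_low_variance": len(report.dropped_low_variance),
                "dropped_missing": len(report.dropped_missing),
                "n_imputed": report.n_imputed,
            },
            "lasso": res.summary(),
            "roc": None
            if roc is None
            else {
                "auc": round(roc.auc, 6),
                "sensitivity_at_half": round(roc.sensitivity_at_half, 6),
                "specificity_at_half": round(roc.specificity_at_half, 6),
                "youden_sensitivity": round(roc.youden_sensitivity, 6),
                "youden_specificity": round(roc.youden_specificity, 6),
            },
            "_result": res,
        }
    return out
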