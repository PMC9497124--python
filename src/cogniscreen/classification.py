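"""SVM training, cross-validation, metrics and four-model comparison.

The classifier is a soft-margin kernel SVM (scikit-learn SVC) with the
MCI group as the positive class (+1).  Model evaluation follows the
screening-study protocol: stratified subject-level 5-fold CV on the
training cohort with the whole pipeline (normalization → MRMR → SVM)
re-fit inside each fold, then a single-shot evaluation of the refit
model on an independent test cohort.  Accuracy, sensitivity and
specificity are reported as mean ± SD over folds; AUC comes from the
trapezoidal rule over the empirical ROC of the pooled out-of-fold
decision scores, with a stratified bootstrap percentile 95 % CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features_assembly import FeatureTable, fit_apply_normalization
from .mrmr import mrmr_rank

log = logging.getLogger(__name__)

__all__ = [
    "SVMConfig",
    "CVResult",
    "default_grid",
    "fit_svm",
    "grid_search",
    "cross_validate",
    "compute_metrics",
    "roc_auc_ci",
    "compare_models",
]

KERNEL_ORDER = {"linear": 0, "rbf": 1, "poly": 2, "sigmoid": 3}


@dataclass(frozen=True)
class SVMConfig:
    """Kernel SVM hyper-parameters (defaults: the RBF optimum C=1.1, gamma=0.001)."""

    kernel: str = "rbf"
    C: float = 1.1
    gamma: float = 0.001
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_ORDER:
            raise ValueError(f"kernel must be one of {sorted(KERNEL_ORDER)}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel != "linear" and self.gamma <= 0:
            raise ValueError("gamma must be positive for non-linear kernels")


def default_grid(
    Cs=(0.1, 0.5, 1.1, 4.0, 17.0, 20.0),
    gammas=(0.001, 0.01, 0.02, 0.1),
) -> list[SVMConfig]:
    """Hyper-parameter grid spanning the four kernels and the printed C/gamma values."""
    grid = [SVMConfig(kernel="linear", C=c) for c in Cs]
    for kernel in ("rbf", "poly", "sigmoid"):
        grid += [SVMConfig(kernel=kernel, C=c, gamma=g) for c in Cs for g in gammas]
    return grid


def fit_svm(X: np.ndarray, y: np.ndarray, config: SVMConfig | None = None) -> SVC:
    """Fit a soft-margin kernel SVM; labels must contain both classes."""
    config = config or SVMConfig()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("single-class training set")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    clf = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma if config.kernel != "linear" else "scale",
        degree=config.degree,
    )
    clf.fit(X, y)
    return clf


def compute_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Accuracy / sensitivity / specificity in percent from confusion counts.

    MCI is the positive class.  Empty denominators flag the metric as
    undefined (NaN).
    """
    for v in (tp, fn, tn, fp):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")
    out = {"accuracy": 100.0 * (tp + tn) / n}
    out["sensitivity"] = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else np.nan
    out["specificity"] = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else np.nan
    return out


def roc_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """AUC by the trapezoidal rule with a stratified bootstrap 95 % CI.

    ``labels`` are +1/-1 with +1 positive; ``scores`` are continuous
    decision values.  The CI resamples positives and negatives
    independently (percentile method).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        q = rng.choice(neg, size=neg.size, replace=True)
        # rank formulation of the trapezoidal AUC, ties counted half
        boot[b] = (
            np.mean(p[:, None] > q[None, :]) + 0.5 * np.mean(p[:, None] == q[None, :])
            if p.size * q.size <= 250_000
            else _rank_auc(p, q)
        )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {
        "auc": auc,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "fpr": fpr,
        "tpr": tpr,
    }


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    from scipy.stats import rankdata

    allv = np.concatenate([pos, neg])
    ranks = rankdata(allv)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


@dataclass
class CVResult:
    """Per-fold cross-validation metrics plus pooled ROC/AUC."""

    fold_metrics: pd.DataFrame  # one row per fold: accuracy/sensitivity/specificity
    summary: dict  # mean/sd per metric (%)
    auc: dict  # auc, ci_low, ci_high, fpr, tpr (pooled out-of-fold scores)
    scores: np.ndarray
    score_labels: np.ndarray
    artifacts: list[dict]  # per-fold fitted components, for leakage checks
    config: SVMConfig


def _fit_fold(
    X_tr: pd.DataFrame,
    y_tr: np.ndarray,
    X_te: pd.DataFrame,
    config: SVMConfig,
    select_k: int | None,
    criterion: str,
    n_bins: int,
) -> tuple[np.ndarray, dict]:
    """Normalization → MRMR → SVM on training data; scores for the held-out set."""
    ntb_cols = [c for c in X_tr.columns if c.startswith("ntb.")]
    tr_n, te_n, params = fit_apply_normalization(X_tr, X_te, minmax_cols=ntb_cols)
    cols = list(tr_n.columns)
    ranking = None
    if select_k is not None and select_k < len(cols):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranking = mrmr_rank(tr_n, y_tr, k=select_k, criterion=criterion, n_bins=n_bins)
        cols = ranking.features
    clf = fit_svm(tr_n[cols].to_numpy(), y_tr, config)
    scores = clf.decision_function(te_n[cols].to_numpy())
    artifact = {
        "norm_mean": dict(params.mean),
        "norm_sd": dict(params.sd),
        "norm_minmax": dict(params.minmax),
        "features": list(cols),
        "dual_coef": clf.dual_coef_.copy(),
        "intercept": clf.intercept_.copy(),
        "support": clf.support_.copy(),
    }
    return scores, artifact


def cross_validate(
    table: FeatureTable,
    config: SVMConfig | None = None,
    k: int = 5,
    seed: int = 0,
    select_k: int | None = None,
    criterion: str = "miq",
    n_bins: int = 8,
    n_boot: int = 2000,
) -> CVResult:
    """Stratified subject-level k-fold CV with a leakage-safe pipeline.

    Normalization statistics, MRMR ranking and the SVM are all fit on
    the training folds only.  Metrics are computed per validation fold
    and summarized as mean ± SD; the AUC uses the pooled out-of-fold
    decision scores.
    """
    config = config or SVMConfig()
    X = table.data
    y = table.labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(f"need at least k={k} subjects per class, got {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, artifacts = [], []
    all_scores = np.empty_like(y, dtype=float)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        scores, artifact = _fit_fold(
            X.iloc[tr], y[tr], X.iloc[te], config, select_k, criterion, n_bins
        )
        all_scores[te] = scores
        pred = np.where(scores >= 0, 1, -1)
        tp = int(np.sum((pred == 1) & (y[te] == 1)))
        fn = int(np.sum((pred == -1) & (y[te] == 1)))
        tn = int(np.sum((pred == -1) & (y[te] == -1)))
        fp = int(np.sum((pred == 1) & (y[te] == -1)))
        m = compute_metrics(tp, fn, tn, fp)
        m["fold"] = fold
        rows.append(m)
        artifact["test_index"] = te.copy()
        artifacts.append(artifact)
        log.debug("fold %d: acc=%.1f%% features=%s", fold, m["accuracy"], artifact["features"][:5])
    fold_metrics = pd.DataFrame(rows).set_index("fold")
    summary = {}
    for metric in ("accuracy", "sensitivity", "specificity"):
        summary[f"{metric}_mean"] = float(fold_metrics[metric].mean())
        summary[f"{metric}_sd"] = float(fold_metrics[metric].std(ddof=1))
    auc = roc_auc_ci(all_scores, y, n_boot=n_boot, seed=seed)
    return CVResult(
        fold_metrics=fold_metrics,
        summary=summary,
        auc=auc,
        scores=all_scores,
        score_labels=y,
        artifacts=artifacts,
        config=config,
    )


def grid_search(
    table: FeatureTable,
    grid: list[SVMConfig] | None = None,
    folds: int = 5,
    seed: int = 0,
    select_k: int | None = None,
    n_boot: int = 200,
) -> tuple[SVMConfig, pd.DataFrame]:
    """Exhaustive CV over a hyper-parameter grid.

    Best configuration maximizes mean CV accuracy; ties break by
    smaller C, then kernel order linear < rbf < poly < sigmoid.
    """
    grid = grid or default_grid()
    if not grid:
        raise ValueError("empty grid")
    rows = []
    for cfg in grid:
        res = cross_validate(
            table, cfg, k=folds, seed=seed, select_k=select_k, n_boot=n_boot
        )
        rows.append(
            {
                "kernel": cfg.kernel,
                "C": cfg.C,
                "gamma": cfg.gamma,
                "accuracy_mean": res.summary["accuracy_mean"],
                "accuracy_sd": res.summary["accuracy_sd"],
                "sensitivity_mean": res.summary["sensitivity_mean"],
                "specificity_mean": res.summary["specificity_mean"],
                "auc": res.auc["auc"],
            }
        )
    results = pd.DataFrame(rows)
    order = sorted(
        range(len(grid)),
        key=lambda i: (
            -results.loc[i, "accuracy_mean"],
            grid[i].C,
            KERNEL_ORDER[grid[i].kernel],
        ),
    )
    best = grid[order[0]]
    log.info("grid search best: %s (acc %.1f%%)", best, results.loc[order[0], "accuracy_mean"])
    return best, results


def _evaluate_holdout(
    train: FeatureTable,
    test: FeatureTable,
    config: SVMConfig,
    select_k: int | None,
    criterion: str,
    n_bins: int,
    n_boot: int,
    seed: int,
) -> tuple[dict, dict]:
    """Refit on all of the training cohort, evaluate once on the test cohort."""
    scores, artifact = _fit_fold(
        train.data,
        train.labels.to_numpy(),
        test.data,
        config,
        select_k,
        criterion,
        n_bins,
    )
    y = test.labels.to_numpy()
    pred = np.where(scores >= 0, 1, -1)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == -1) & (y == 1)))
    tn = int(np.sum((pred == -1) & (y == -1)))
    fp = int(np.sum((pred == 1) & (y == -1)))
    metrics = compute_metrics(tp, fn, tn, fp)
    metrics.update(roc_auc_ci(scores, y, n_boot=n_boot, seed=seed))
    # dispersion comparable to fold SDs: bootstrap SD of accuracy over resamples
    rng = np.random.default_rng(seed)
    accs = np.empty(n_boot)
    correct = (pred == y).astype(float)
    for b in range(n_boot):
        accs[b] = 100.0 * np.mean(rng.choice(correct, size=correct.size, replace=True))
    metrics["accuracy_boot_sd"] = float(np.std(accs, ddof=1))
    return metrics, artifact


def compare_models(
    cohort1: FeatureTable,
    cohort2: FeatureTable | None = None,
    config: SVMConfig | None = None,
    seed: int = 0,
    select_k: int | None = 20,
    criterion: str = "miq",
    n_bins: int = 8,
    k: int = 5,
    n_boot: int = 2000,
    views: tuple[str, ...] = ("clinical", "ntb_only", "physio_only", "all"),
) -> dict:
    """Four-model comparison: clinical, NTB-only, physiological, combined.

    For each view: stratified 5-fold CV on cohort 1, then (when cohort 2
    is given) a single-shot evaluation of the model refit on all of
    cohort 1.  Returns a JSON-ready report with per-view CV summaries,
    AUC + 95 % CI, ROC points and hold-out metrics.
    """
    config = config or SVMConfig()
    report: dict = {
        "config": {"kernel": config.kernel, "C": config.C, "gamma": config.gamma},
        "seed": seed,
        "select_k": select_k,
        "views": {},
    }
    for view in views:
        t1 = cohort1.view(view)
        if t1.data.shape[1] == 0:
            raise ValueError(f"view {view!r} missing from cohort 1")
        res = cross_validate(
            t1, config, k=k, seed=seed, select_k=select_k,
            criterion=criterion, n_bins=n_bins, n_boot=n_boot,
        )
        entry: dict = {
            "n_train": len(t1),
            "cv": {
                **res.summary,
                "auc": res.auc["auc"],
                "auc_ci": [res.auc["ci_low"], res.auc["ci_high"]],
                "roc": {
                    "fpr": [float(v) for v in res.auc["fpr"]],
                    "tpr": [float(v) for v in res.auc["tpr"]],
                },
            },
        }
        if cohort2 is not None:
            t2 = cohort2.view(view)
            if t2.data.shape[1] == 0:
                raise ValueError(f"view {view!r} missing from cohort 2")
            metrics, artifact = _evaluate_holdout(
                t1, t2, config, select_k, criterion, n_bins, n_boot, seed
            )
            entry["n_test"] = len(t2)
            entry["test"] = {
                "accuracy": metrics["accuracy"],
                "sensitivity": metrics["sensitivity"],
                "specificity": metrics["specificity"],
                "accuracy_boot_sd": metrics["accuracy_boot_sd"],
                "auc": metrics["auc"],
                "auc_ci": [metrics["ci_low"], metrics["ci_high"]],
                "roc": {
                    "fpr": [float(v) for v in metrics["fpr"]],
                    "tpr": [float(v) for v in metrics["tpr"]],
                },
            }
            entry["_final_artifact"] = artifact  # stripped before serialization
        report["views"][view] = entry
    return report
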