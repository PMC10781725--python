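"""Leave-one-study-out (LOSO) cross-validated biomarker classification.

Disease status is predicted from the meta-analysis DEGs with either an
elastic-net regularized logistic model or a random forest. Expression is
standardized per gene within each study (mean 0, sd 1) to remove
between-study location/scale heterogeneity — the standardization constants
never cross a study boundary, so no information leaks from a held-out study
into training. Each outer fold holds out one whole study; hyperparameters
are tuned by stratified inner CV on the pooled training studies; the
reported figure is the mean of the per-held-out-study accuracies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io_core import normalize_symbol
from .preprocessing import ExpressionStudy

logger = logging.getLogger("psymeta")


def _default_lambda_grid() -> list[float]:
    return list(np.logspace(-4, 1, 50))


@dataclass
class PredictionConfig:
    """Model choice, tuning grids and CV layout.

    Elastic net uses the glmnet-style parametrization: ``alpha`` is the
    L1/L2 mixing weight in [0, 1] and ``lam`` the regularization strength.
    Random forest tunes ntree and mtry (features per split); mtry entries
    are either integers or the strings 'sqrt', 'third', 'half' resolved
    against the feature count at fit time.
    """

    model: str = "elastic_net"
    alpha_grid: list[float] = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    lambda_grid: list[float] = field(default_factory=_default_lambda_grid)
    ntree_grid: list[int] = field(default_factory=lambda: [500, 1000])
    mtry_grid: list = field(default_factory=lambda: ["sqrt", "third", "half"])
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("elastic_net", "random_forest"):
            raise ValueError(f"unknown model {self.model!r}")
        if not self.alpha_grid or not self.lambda_grid or not self.ntree_grid or not self.mtry_grid:
            raise ValueError("tuning grids must be non-empty")
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_grid):
            raise ValueError("elastic-net alpha must lie in [0, 1]")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda must be positive")
        if any(t < 100 for t in self.ntree_grid):
            raise ValueError("ntree must be >= 100")


@dataclass
class CVReport:
    """Per-held-out-study accuracies plus the final-model feature ranking."""

    model: str
    study_ids: list[str]
    accuracies: list[float]
    mean_accuracy: float
    best_params: list[dict]
    feature_names: list[str]
    feature_scores: np.ndarray  # |coef| (elastic net) or importance (forest), final all-data fit
    seed: int


def standardize_per_gene(
    studies: list[ExpressionStudy], genes: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Stack studies into a samples x genes matrix, standardized within study.

    Every gene must be present in every study. Within each study each gene
    is centered and scaled to mean 0 / sd 1; a zero-variance gene becomes a
    zero column for that study (with a warning). Returns (X, y, study_ids
    per sample, gene order); y is 1 for cases.
    """
    genes = [normalize_symbol(g) for g in genes]
    blocks, ys, sids = [], [], []
    for study in studies:
        missing = [g for g in genes if g not in study.values.index]
        if missing:
            raise ValueError(f"{study.study_id}: genes missing from study: {missing[:5]}")
        x = study.values.loc[genes].to_numpy(float).T  # samples x genes
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.warning(
                "%s: %d zero-variance gene(s) set to 0 after standardization",
                study.study_id,
                int(zero.sum()),
            )
        sd_safe = np.where(zero, 1.0, sd)
        z = (x - mu) / sd_safe
        z[:, zero] = 0.0
        blocks.append(z)
        ys.append((study.groups[study.values.columns].to_numpy() == "case").astype(int))
        sids.append(np.full(x.shape[0], study.study_id, dtype=object))
    return (
        np.vstack(blocks),
        np.concatenate(ys),
        np.concatenate(sids),
        genes,
    )


def _resolve_mtry(setting, p: int) -> int:
    if setting == "sqrt":
        v = int(round(np.sqrt(p)))
    elif setting == "third":
        v = int(round(p / 3))
    elif setting == "half":
        v = int(round(p / 2))
    else:
        v = int(setting)
    return min(max(v, 1), p)


def _make_estimator(cfg: PredictionConfig, params: dict, n_train: int, p: int, seed: int):
    if cfg.model == "elastic_net":
        # glmnet (alpha, lambda) -> sklearn (l1_ratio, C = 1 / (n * lambda))
        return LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            l1_ratio=params["alpha"],
            C=1.0 / (n_train * params["lam"]),
            max_iter=5000,
            tol=1e-4,
            random_state=seed,
        )
    return RandomForestClassifier(
        n_estimators=params["ntree"],
        max_features=_resolve_mtry(params["mtry"], p),
        random_state=seed,
        n_jobs=1,
    )


def _param_grid(cfg: PredictionConfig):
    if cfg.model == "elastic_net":
        return [{"alpha": a, "lam": l} for a in cfg.alpha_grid for l in cfg.lambda_grid]
    return [{"ntree": t, "mtry": m} for t in cfg.ntree_grid for m in cfg.mtry_grid]


def _tune(X: np.ndarray, y: np.ndarray, cfg: PredictionConfig, seed: int) -> dict:
    """Stratified inner-CV grid search maximizing accuracy; first best wins."""
    n_splits = min(cfg.inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("inner CV needs both classes at least twice in training data")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_params, best_acc = None, -1.0
    for params in _param_grid(cfg):
        correct = 0
        total = 0
        for tr, te in folds:
            est = _make_estimator(cfg, params, len(tr), X.shape[1], seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[tr], y[tr])
            correct += int((est.predict(X[te]) == y[te]).sum())
            total += len(te)
        acc = correct / total
        if acc > best_acc:
            best_acc, best_params = acc, params
    return best_params


def loso_cv(
    X: np.ndarray,
    y: np.ndarray,
    study_ids: np.ndarray,
    cfg: PredictionConfig,
    feature_names: list[str] | None = None,
) -> CVReport:
    """Leave-one-study-out CV with nested tuning; deterministic given cfg.seed."""
    studies = list(pd.unique(study_ids))
    if len(studies) < 3:
        raise ValueError("LOSO CV needs >= 3 studies")
    accuracies, best_params_all = [], []
    for held_out in studies:
        test = study_ids == held_out
        Xtr, ytr = X[~test], y[~test]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"training fold holding out {held_out!r} has a single class")
        params = _tune(Xtr, ytr, cfg, cfg.seed)
        est = _make_estimator(cfg, params, len(ytr), X.shape[1], cfg.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xtr, ytr)
        acc = float((est.predict(X[test]) == y[test]).mean())
        accuracies.append(acc)
        best_params_all.append(params)

    # final fit on all studies pooled, for the feature ranking
    final_params = _tune(X, y, cfg, cfg.seed)
    final = _make_estimator(cfg, final_params, len(y), X.shape[1], cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    if cfg.model == "elastic_net":
        scores = np.abs(final.coef_.ravel())
    else:
        scores = final.feature_importances_

    names = feature_names if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    return CVReport(
        model=cfg.model,
        study_ids=[str(s) for s in studies],
        accuracies=accuracies,
        mean_accuracy=float(np.mean(accuracies)),
        best_params=best_params_all + [final_params],
        feature_names=list(names),
        feature_scores=scores,
        seed=cfg.seed,
    )


def top_features(report: CVReport, k: int) -> list[str]:
    """Top-k features of the final all-data fit, ranked by score magnitude."""
    if k == 0:
        return []
    nonzero = int((report.feature_scores > 0).sum())
    if k > nonzero:
        logger.warning("top_features: only %d features have nonzero scores (asked for %d)", nonzero, k)
    order = np.argsort(-report.feature_scores, kind="mergesort")
    return [report.feature_names[i] for i in order[: min(k, len(order))] if report.feature_scores[i] > 0]
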