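"""Classifiers and the cross-validated evaluation protocol.

The evaluation mirrors common chemometric practice: several independent
"sessions", each a stratified k-fold cross-validation with its own random
seed, where *every* data-dependent step — ANOVA filtering, elastic-net
tuning/selection, classifier training — is refit inside each training fold
so no selection information leaks into the test folds.  Fold predictions
are pooled into one confusion matrix per session; the headline number is
the mean and SD (across sessions) of the macro accuracy, i.e. the mean of
the confusion-matrix diagonal expressed as per-class recall.  Overall
(micro) accuracy is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .fuse import SpectralDataset, CompositeAxis
from .select import (
    FeatureMask, EnetFit, anova_filter, enet_fit, enet_path, enet_select,
    default_lambda_path, _cv_deviance,
)

__all__ = [
    "PipelineConfig", "CVResult", "EnetClassifier", "SVMBenchmark",
    "train_enet_classifier", "train_svm_benchmark", "repeated_cv", "summarize",
    "summarize_many",
]


class EnetClassifier:
    """Prediction wrapper around an :class:`EnetFit`."""

    def __init__(self, fit: EnetFit):
        if fit.coefficients.shape[1] == 0:
            raise ValueError("classifier needs a non-empty feature set")
        self.fit = fit
        self.classes_ = fit.classes

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.fit.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        scores = self.fit.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


def train_enet_classifier(X_selected, y, alpha: float, lam: float,
                          **fit_kwargs) -> EnetClassifier:
    """Fit the elastic-net multinomial classifier on selected features."""
    X_selected = np.asarray(X_selected, dtype=float)
    if X_selected.shape[1] == 0:
        raise ValueError("empty feature set")
    return EnetClassifier(enet_fit(X_selected, y, alpha, lam, **fit_kwargs))


class SVMBenchmark:
    """Linear maximum-margin benchmark with the same predict interface."""

    def __init__(self, model: SVC):
        self.model = model
        self.classes_ = model.classes_

    def predict(self, X) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))

    @property
    def support_(self):
        return self.model.support_


def train_svm_benchmark(X_selected, y, C: float = 1.0) -> SVMBenchmark:
    """Linear SVM (one-vs-rest decision function), deterministic."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("SVM benchmark needs at least 2 classes")
    model = SVC(kernel="linear", C=C, decision_function_shape="ovr", random_state=0)
    model.fit(np.asarray(X_selected, dtype=float), y)
    return SVMBenchmark(model)


@dataclass
class PipelineConfig:
    """Per-fold modelling pipeline settings.

    ``tuning`` selects how (alpha, lambda) are chosen inside each training
    fold: ``"split"`` holds out ``inner_val_fraction`` of the fold once and
    scores a warm-started lambda path per alpha (fast default), ``"cv"``
    runs the full repeated inner cross-validation of
    :func:`~specfuse.select.enet_select`, and ``"fixed"`` uses
    ``fixed_alpha`` with lambda = ``fixed_lambda_ratio`` x lambda_max of
    the training fold.  ``strategy="late"`` applies ANOVA + elastic-net
    selection per modality block of a hybrid dataset and concatenates only
    the selected channels before the final classifier.
    """

    anova_keep: int = 200
    alpha_grid: tuple = (0.1, 0.5, 1.0)
    n_lambdas: int = 20
    lambda_min_ratio: float = 1e-3
    tuning: str = "split"  # "split" | "cv" | "fixed"
    inner_val_fraction: float = 0.2
    fixed_alpha: float = 0.5
    fixed_lambda_ratio: float = 0.05
    inner_cv_folds: int = 10
    inner_cv_repeats: int = 3
    classifier: str = "enet"  # "enet" | "svm"
    svm_C_grid: tuple = (0.1, 1.0, 10.0)
    strategy: str = "single"  # "single" | "late"
    max_iter: int = 500
    tol: float = 1e-4         # refit tolerance; prediction-grade, not KKT-grade
    refit_obj_tol: float = 1e-6
    tune_max_iter: int = 12       # looser settings for the tuning path only
    tune_tol: float = 1e-4
    dfmax: int = 100              # stop the tuning path past this many actives
    tune_subsample_per_class: Optional[int] = 40  # cap the tuning search set


def _tune_and_fit(X, y, config: PipelineConfig, seed: int) -> EnetFit:
    """Choose (alpha, lambda) on training data only, then refit on all of it."""
    if config.tuning == "fixed":
        from .select import lambda_max
        lam = config.fixed_lambda_ratio * lambda_max(X, y, config.fixed_alpha)
        return enet_fit(X, y, config.fixed_alpha, lam,
                        max_iter=config.max_iter, tol=config.tol,
                        obj_tol=config.refit_obj_tol)
    if config.tuning == "cv":
        _, fit = enet_select(
            X, y, alpha_grid=config.alpha_grid, n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
            cv_folds=config.inner_cv_folds, cv_repeats=config.inner_cv_repeats,
            seed=seed, max_iter=config.max_iter, tol=config.tol,
        )
        return fit
    if config.tuning != "split":
        raise ValueError(f"unknown tuning mode {config.tuning!r}")
    splitter = StratifiedShuffleSplit(
        n_splits=1, test_size=config.inner_val_fraction, random_state=seed
    )
    tr, va = next(splitter.split(X, y))
    # search on a stratified subsample; validate on the full held-out split
    cap = config.tune_subsample_per_class
    if cap is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for c in np.unique(y[tr]):
            members = tr[y[tr] == c]
            if members.size > cap:
                members = rng.choice(members, size=cap, replace=False)
            keep.append(members)
        tr = np.sort(np.concatenate(keep))
    best = None  # (deviance, alpha, lambda)
    for alpha in config.alpha_grid:
        lams = default_lambda_path(X[tr], y[tr], alpha,
                                   config.n_lambdas, config.lambda_min_ratio)
        fits = enet_path(X[tr], y[tr], alpha, lams,
                         max_iter=config.tune_max_iter, tol=config.tune_tol,
                         obj_tol=1e-7, dfmax=config.dfmax)
        for fit in fits:
            dev = _cv_deviance(fit, X[va], y[va])
            if best is None or dev < best[0]:
                best = (dev, alpha, fit.lam)
    _, alpha_star, lam_star = best
    return enet_fit(X, y, alpha_star, lam_star, max_iter=config.max_iter,
                    tol=config.tol, obj_tol=config.refit_obj_tol)


class FoldPipeline:
    """ANOVA -> elastic-net selection -> classifier, fit on one training fold."""

    def __init__(self, config: PipelineConfig, axis=None):
        self.config = config
        self.axis = axis
        self.anova_masks: list[FeatureMask] = []
        self.blocks: list[np.ndarray] = []       # global column indices per block
        self.selected_columns: Optional[np.ndarray] = None
        self.enet: Optional[EnetFit] = None
        self.classifier = None

    def _block_columns(self, n_channels: int) -> list[np.ndarray]:
        if self.config.strategy == "late":
            if not isinstance(self.axis, CompositeAxis):
                raise ValueError("late-fusion strategy needs a hybrid dataset "
                                 "with a composite axis")
            return [np.nonzero(self.axis.block(m))[0] for m in ("libs", "raman")]
        return [np.arange(n_channels)]

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> "FoldPipeline":
        cfg = self.config
        self.blocks = [b for b in self._block_columns(X.shape[1]) if b.size]
        selected: list[np.ndarray] = []
        self.anova_masks = []
        for cols in self.blocks:
            keep = min(cfg.anova_keep, cols.size)
            mask = anova_filter(X[:, cols], keep, y)
            self.anova_masks.append(mask)
            kept_global = cols[mask.indices]
            if cfg.strategy == "late":
                fit = _tune_and_fit(X[:, kept_global], y, cfg, seed)
                selected.append(kept_global[fit.active_channels])
            else:
                selected.append(kept_global)
        self.selected_columns = np.concatenate(selected)
        if self.selected_columns.size == 0:
            raise ValueError("no features survived selection")
        Xsel = X[:, self.selected_columns]
        self.enet = _tune_and_fit(Xsel, y, cfg, seed)
        if cfg.classifier == "enet":
            self.classifier = EnetClassifier(self.enet)
            self._final_cols = self.selected_columns
        elif cfg.classifier == "svm":
            active = self.selected_columns[self.enet.active_channels]
            if active.size == 0:
                active = self.selected_columns
            self._final_cols = active
            C = _tune_svm_C(X[:, active], y, cfg.svm_C_grid, seed)
            self.classifier = train_svm_benchmark(X[:, active], y, C=C)
        else:
            raise ValueError(f"unknown classifier {cfg.classifier!r}")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(X[:, self._final_cols])


def _tune_svm_C(X, y, C_grid: Sequence[float], seed: int) -> float:
    if len(C_grid) == 1:
        return float(C_grid[0])
    splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    best = None
    for C in C_grid:
        correct = 0
        total = 0
        for tr, va in splitter.split(X, y):
            clf = train_svm_benchmark(X[tr], y[tr], C=C)
            correct += int(np.sum(clf.predict(X[va]) == y[va]))
            total += len(va)
        acc = correct / total
        if best is None or acc > best[0]:
            best = (acc, float(C))
    return best[1]


@dataclass
class CVResult:
    """Per-session confusion matrices and diagonal summaries."""

    confusions: list            # one K x K count matrix per session
    per_class_accuracy: np.ndarray  # sessions x K
    mean_accuracy: float        # mean of session macro accuracies
    sd_accuracy: float          # SD (ddof=1) of session macro accuracies
    micro_mean: float
    micro_sd: float
    seeds: list
    classes: np.ndarray
    settings: dict

    @property
    def session_macro(self) -> np.ndarray:
        return self.per_class_accuracy.mean(axis=1)


def repeated_cv(
    dataset: SpectralDataset,
    pipeline_config: PipelineConfig,
    k: int = 10,
    sessions: int = 10,
    seeds: Optional[Sequence[int]] = None,
    fold_hook: Optional[Callable] = None,
) -> CVResult:
    """Ten-session repeated stratified k-fold evaluation (leakage-free).

    Each session uses its own seed for the stratified split and for the
    inner tuning; ANOVA filtering, elastic-net tuning/selection and the
    classifier are refit inside every training fold.  ``fold_hook(session,
    fold, pipeline)`` is called after each fold fit (instrumentation, e.g.
    leakage checks).
    """
    if seeds is None:
        seeds = list(range(1, sessions + 1))
    if len(seeds) != sessions:
        raise ValueError(f"need {sessions} seeds, got {len(seeds)}")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate session seeds: sessions will repeat exactly")
    y = dataset.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("repeated CV needs at least 2 classes")
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"class {small[0]!r} has fewer than k={k} members")
    X = dataset.matrix
    confusions = []
    per_class = np.zeros((sessions, classes.size))
    micro = np.zeros(sessions)
    for s, seed in enumerate(seeds):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
        y_pred = np.empty(y.shape, dtype=object)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            pipe = FoldPipeline(pipeline_config, axis=dataset.axis)
            pipe.fit(X[tr], y[tr], seed=int(seed) * 100 + f)
            y_pred[te] = pipe.predict(X[te])
            if fold_hook is not None:
                fold_hook(s, f, pipe)
        cm = confusion_matrix(y, y_pred, labels=classes)
        confusions.append(cm)
        rowsum = cm.sum(axis=1)
        per_class[s] = np.divide(np.diag(cm), rowsum, where=rowsum > 0,
                                 out=np.zeros(classes.size))
        micro[s] = np.trace(cm) / cm.sum()
    macro = per_class.mean(axis=1)
    sd = float(np.std(macro, ddof=1)) if sessions > 1 else 0.0
    micro_sd = float(np.std(micro, ddof=1)) if sessions > 1 else 0.0
    return CVResult(
        confusions=confusions,
        per_class_accuracy=per_class,
        mean_accuracy=float(macro.mean()),
        sd_accuracy=sd,
        micro_mean=float(micro.mean()),
        micro_sd=micro_sd,
        seeds=list(seeds),
        classes=classes,
        settings={"k": k, "sessions": sessions, **asdict(pipeline_config)},
    )


def summarize(result: CVResult) -> pd.DataFrame:
    """One-row report: macro / micro mean (SD) percentages, two decimals."""
    if not result.confusions:
        raise ValueError("empty CVResult")
    return pd.DataFrame(
        {
            "macro_pct": [f"{100 * result.mean_accuracy:.2f} ({100 * result.sd_accuracy:.2f})"],
            "micro_pct": [f"{100 * result.micro_mean:.2f} ({100 * result.micro_sd:.2f})"],
            "sessions": [len(result.confusions)],
            "classes": [result.classes.size],
        }
    )


def summarize_many(results: dict[str, CVResult]) -> pd.DataFrame:
    """Method x input-setting table of mean (SD) percentages."""
    rows = {}
    for name, res in results.items():
        rows[name] = summarize(res).iloc[0]
    return pd.DataFrame(rows).T
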