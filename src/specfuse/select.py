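"""Feature selection: univariate ANOVA filtering and multivariate
elastic-net multinomial selection.

High-dimensional spectra (hundreds to thousands of channels, most of them
baseline or noise) are reduced in two stages.  First a one-way ANOVA
F-statistic per channel removes features with very small between-class
effect sizes, keeping the ``keep_n`` largest-F channels.  Second a
regularized multinomial logistic regression with an elastic-net penalty,

    argmin_B  -1/n sum_i sum_k 1(y_i = k) log softmax_k(x_i' B_k)
              + lambda sum_k [ alpha ||B_k||_1 + (1/2)(1-alpha) ||B_k||_2^2 ],

performs multivariate selection while building the classifier itself: the
l1 part zeroes out irrelevant channels, the l2 part stabilizes correlated
ones.  (alpha, lambda) are tuned by repeated stratified cross-validation
over a warm-started lambda path.  The coordinate-descent solver lives in
:mod:`specfuse._enet_solver`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.feature_selection import f_classif
from sklearn.model_selection import RepeatedStratifiedKFold

from ._enet_solver import cd_multinomial, standardize
from .fuse import SpectralDataset

__all__ = [
    "FeatureMask", "EnetFit",
    "anova_filter", "enet_objective", "enet_fit", "enet_path",
    "lambda_max", "enet_select",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
DEFAULT_LAMBDA_MIN_RATIO = 1e-4
DEFAULT_N_LAMBDAS = 50


@dataclass(frozen=True)
class FeatureMask:
    """Indices of channels surviving a selection stage."""

    indices: np.ndarray
    provenance: str  # "anova" | "enet" | "manual"
    source_dims: int
    channel_origin: Optional[tuple] = None  # (modality, native index) per column

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        idx = np.sort(idx)
        object.__setattr__(self, "indices", idx)
        if self.provenance not in ("anova", "enet", "manual"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if idx.size:
            if idx[0] < 0 or idx[-1] >= self.source_dims:
                raise ValueError("mask indices out of range")
            if np.unique(idx).size != idx.size:
                raise ValueError("mask indices must be unique")

    def __len__(self) -> int:
        return self.indices.size

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix)[:, self.indices]


@dataclass(frozen=True)
class EnetFit:
    """A fitted elastic-net multinomial model.

    ``coefficients`` is K x p on the standardized-feature scale;
    ``feature_mean`` / ``feature_scale`` record the standardization so the
    fit can score new data.  ``classes`` fixes the row order of the
    coefficient matrix.
    """

    coefficients: np.ndarray  # (K, p)
    intercepts: np.ndarray    # (K,)
    alpha: float
    lam: float
    n_iter: int
    converged: bool
    classes: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    @property
    def active_channels(self) -> np.ndarray:
        """Indices of features with a nonzero coefficient in any class."""
        return np.nonzero(np.any(self.coefficients != 0.0, axis=0))[0]

    def symmetry_gap(self) -> float:
        """Max |sum_k beta_jk| over features — identifiability diagnostic.

        The symmetric multinomial parameterization is over-parameterized;
        the penalty resolves it and drives the per-feature class sums
        toward zero.  Large values indicate an unconverged or unpenalized
        fit, not an error.
        """
        if self.coefficients.size == 0:
            return 0.0
        return float(np.max(np.abs(self.coefficients.sum(axis=0))))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale
        return Xs @ self.coefficients.T + self.intercepts

    def predict_log_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.decision_scores(X)
        return eta - logsumexp(eta, axis=1, keepdims=True)


def _as_matrix_labels(X, y=None):
    if isinstance(X, SpectralDataset):
        return X.matrix, X.labels
    return np.asarray(X, dtype=float), np.asarray(y)


def anova_filter(X, keep_n: int, y=None) -> FeatureMask:
    """Keep the ``keep_n`` channels with the largest one-way ANOVA F.

    The F statistic is the ratio of between-class to within-class mean
    squares per channel.  Channels with zero within-class variance but
    between-class spread get F = +inf (kept first, with a warning);
    channels constant everywhere get F = 0.  Ties break toward the lower
    channel index.
    """
    mat, labels = _as_matrix_labels(X, y)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("ANOVA filtering needs at least 2 classes")
    if np.min(counts) < 2:
        raise ValueError("ANOVA filtering needs >= 2 samples per class")
    if keep_n > mat.shape[1]:
        raise ValueError(f"keep_n = {keep_n} exceeds channel count {mat.shape[1]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        F, _ = f_classif(mat, labels)
    n_inf = int(np.sum(np.isinf(F)))
    if n_inf:
        warnings.warn(f"{n_inf} channels have zero within-class variance; F set to +inf")
    F = np.nan_to_num(F, nan=0.0, posinf=np.inf)
    order = np.argsort(-F, kind="stable")  # stable: ties -> lower index first
    return FeatureMask(order[:keep_n], "anova", mat.shape[1])


def enet_objective(X, y, coefficients, intercepts, alpha: float, lam: float) -> float:
    """Penalized negative log-likelihood, penalty summed over classes.

    Pure function of its inputs; no standardization is applied here.
    ``coefficients`` is (K, p) in the order of ``np.unique(y)``.
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(coefficients, dtype=float)
    b0 = np.asarray(intercepts, dtype=float)
    if not (np.all(np.isfinite(B)) and np.all(np.isfinite(b0))):
        raise ValueError("coefficients and intercepts must be finite")
    y = np.asarray(y)
    classes = np.unique(y)
    if B.shape != (classes.size, X.shape[1]):
        raise ValueError(f"coefficient shape {B.shape} inconsistent with "
                         f"{classes.size} classes x {X.shape[1]} features")
    eta = X @ B.T + b0
    log_p = eta - logsumexp(eta, axis=1, keepdims=True)
    k_of = np.searchsorted(classes, y)
    nll = -np.mean(log_p[np.arange(X.shape[0]), k_of])
    penalty = lam * np.sum(
        alpha * np.abs(B).sum(axis=1) + 0.5 * (1.0 - alpha) * (B**2).sum(axis=1)
    )
    return float(nll + penalty)


def lambda_max(X, y, alpha: float) -> float:
    """Smallest penalty at which the solution is entirely zero.

    With standardized features and null-model probabilities equal to the
    class frequencies pi_k, the coefficient block stays at zero iff
    |<x_j, 1(y=k) - pi_k>| / n <= lambda * alpha for every (j, k).
    """
    Xs, _, _ = standardize(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    n = Xs.shape[0]
    pi = np.array([(y == c).mean() for c in classes])
    R = (y[:, None] == classes[None, :]).astype(float) - pi  # (n, K)
    grad = np.abs(Xs.T @ R) / n
    gmax = float(grad.max()) if grad.size else 0.0
    a = max(alpha, 1e-3)  # ridge-only grids reuse the near-lasso scale
    return gmax / a


def _prepare(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    y_idx = np.searchsorted(classes, y).astype(np.int64)
    Xs, mean, scale = standardize(X)
    Xt = np.ascontiguousarray(Xs.T)
    return Xt, y_idx, classes, mean, scale


def enet_fit(X, y, alpha: float, lam: float, max_iter: int = 10_000,
             tol: float = 1e-6, obj_tol: float = 1e-9,
             warm_start: Optional[tuple] = None,
             strict: bool = False) -> EnetFit:
    """Fit the elastic-net multinomial model at one (alpha, lambda).

    Features are standardized internally (constant channels get zero
    weight); coefficients are reported on the standardized scale and the
    intercepts absorb the centering.  ``warm_start`` takes ``(beta, b)``
    from a neighbouring fit on the lambda path.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    Xt, y_idx, classes, mean, scale = _prepare(X, y)
    p, n = Xt.shape
    K = classes.size
    if K < 2:
        raise ValueError("need at least 2 classes")
    if warm_start is not None:
        beta = np.array(warm_start[0], dtype=float, copy=True)
        b = np.array(warm_start[1], dtype=float, copy=True)
    else:
        beta = np.zeros((p, K))
        pi = np.bincount(y_idx, minlength=K) / n
        b = np.log(np.clip(pi, 1e-12, None))
        b -= b.mean()
    n_iter, converged = cd_multinomial(Xt, y_idx, K, float(alpha), float(lam),
                                       beta, b, int(max_iter), float(tol),
                                       float(obj_tol))
    if not converged and strict:
        raise RuntimeError(f"coordinate descent did not converge in {max_iter} iterations")
    return EnetFit(beta.T.copy(), b.copy(), float(alpha), float(lam),
                   int(n_iter), bool(converged), classes, mean, scale)


def enet_path(X, y, alpha: float, lambdas: Sequence[float],
              max_iter: int = 10_000, tol: float = 1e-6,
              obj_tol: float = 1e-9,
              dfmax: Optional[int] = None) -> list[EnetFit]:
    """Warm-started fits along a decreasing lambda path.

    ``dfmax`` stops the path early once a fit activates more than that
    many channels (the near-unpenalized tail is expensive and never wins
    model selection); the returned list may then be shorter than
    ``lambdas``.
    """
    lams = sorted((float(l) for l in lambdas), reverse=True)
    fits: list[EnetFit] = []
    warm = None
    for lam in lams:
        fit = enet_fit(X, y, alpha, lam, max_iter=max_iter, tol=tol,
                       obj_tol=obj_tol, warm_start=warm)
        warm = (fit.coefficients.T, fit.intercepts)
        fits.append(fit)
        if dfmax is not None and fit.active_channels.size > dfmax:
            break
    return fits


def default_lambda_path(X, y, alpha: float, n_lambdas: int = DEFAULT_N_LAMBDAS,
                        min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO) -> np.ndarray:
    lmax = lambda_max(X, y, alpha)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def _cv_deviance(fit: EnetFit, X_val, y_val) -> float:
    log_p = fit.predict_log_proba(np.asarray(X_val, dtype=float))
    k_of = np.searchsorted(fit.classes, np.asarray(y_val))
    known = k_of < fit.classes.size
    k_of = np.clip(k_of, 0, fit.classes.size - 1)
    match = known & (fit.classes[k_of] == np.asarray(y_val))
    ll = np.where(match, log_p[np.arange(len(y_val)), k_of], np.log(1e-12))
    return float(-2.0 * ll.mean())


def enet_select(
    X, y=None, *,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    lambda_path: Optional[Sequence[float]] = None,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    cv_folds: int = 10,
    cv_repeats: int = 3,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-5,
) -> tuple[FeatureMask, EnetFit]:
    """Tune (alpha, lambda) by repeated stratified CV and select features.

    For each alpha, fits a warm-started lambda path per training split and
    scores validation deviance; the minimum-deviance (alpha, lambda) wins
    (no one-standard-error rule).  The winner is refit on all data and the
    mask contains every channel with a nonzero coefficient in any class.
    """
    mat, labels = _as_matrix_labels(X, y)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("elastic-net selection needs at least 2 classes")
    if np.min(counts) < cv_folds:
        raise ValueError(
            f"smallest class has {np.min(counts)} samples; need >= {cv_folds} for "
            f"{cv_folds}-fold CV"
        )
    best = None  # (mean deviance, alpha, lambda)
    for alpha in alpha_grid:
        if lambda_path is None:
            lams = default_lambda_path(mat, labels, alpha, n_lambdas, lambda_min_ratio)
        else:
            lams = np.sort(np.asarray(lambda_path, dtype=float))[::-1]
        dev = np.zeros(len(lams))
        cnt = np.zeros(len(lams))
        splitter = RepeatedStratifiedKFold(
            n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed
        )
        for tr, va in splitter.split(mat, labels):
            fits = enet_path(mat[tr], labels[tr], alpha, lams, max_iter=max_iter, tol=tol)
            for i, fit in enumerate(fits):
                dev[i] += _cv_deviance(fit, mat[va], labels[va])
                cnt[i] += 1
        dev = np.where(cnt > 0, dev / np.maximum(cnt, 1), np.inf)
        # enet_path sorts descending; align
        lams_sorted = np.sort(np.asarray(lams, dtype=float))[::-1]
        i_best = int(np.argmin(dev))
        if best is None or dev[i_best] < best[0]:
            best = (float(dev[i_best]), float(alpha), float(lams_sorted[i_best]))
    _, alpha_star, lam_star = best
    final = enet_fit(mat, labels, alpha_star, lam_star, max_iter=max_iter, tol=tol)
    active = final.active_channels
    if active.size == 0:
        raise ValueError("no features survived elastic-net selection "
                         "(lambda path may contain only lambda_max)")
    mask = FeatureMask(active, "enet", mat.shape[1])
    return mask, final
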