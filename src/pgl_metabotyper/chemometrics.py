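"""Chemometric engine: PCA screening and from-scratch PLS-DA with MCCV.

PLS-DA is implemented as NIPALS PLS2 on a column-centered one-hot class
matrix, with per-component deflation and the regression coefficients
``B = W (P'W)^{-1} Q'``.  Model validation pools predictions from repeated
stratified random train/test splits (Monte-Carlo cross-validation) into a
single aggregated confusion matrix, from which Se/Sp/PPV/NPV/accuracy are
derived, optionally after collapsing a set of classes into one positive
category (e.g. germline-mutation carriers).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import stats

from pgl_metabotyper.quantification import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "ConvergenceError",
    "FeatureMatrix",
    "MCCVConfig",
    "MCCVResult",
    "PCAResult",
    "PLSDAModel",
    "Performance",
    "PreprocessParams",
    "apply_preprocess",
    "mccv",
    "pca",
    "performance",
    "plsda_fit",
    "plsda_predict",
    "preprocess",
    "round_half_away",
    "select_components_q2",
]


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge; the message names the component."""


# ---------------------------------------------------------------------------
# preprocessing


@dataclasses.dataclass(frozen=True)
class PreprocessParams:
    mean: np.ndarray
    scale: np.ndarray
    kept: np.ndarray  # boolean mask of retained features
    mode: str


def preprocess(X: np.ndarray, mode: str = "unit_variance") -> tuple[np.ndarray, PreprocessParams]:
    """Mean-center and scale columns; returns transformed X and the params.

    Modes: ``none`` (centering only), ``unit_variance`` (divide by SD),
    ``pareto`` (divide by sqrt(SD)).  Zero-variance features are dropped with
    a warning under the scaled modes.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("preprocess needs a 2-D matrix with >= 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if mode == "none":
        scale = np.ones_like(sd)
    elif mode == "unit_variance":
        scale = sd.copy()
    elif mode == "pareto":
        scale = np.sqrt(sd)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    kept = scale > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance feature(s) under {mode} scaling",
            stacklevel=2,
        )
    params = PreprocessParams(mean=mean, scale=scale, kept=kept, mode=mode)
    return apply_preprocess(X, params), params


def apply_preprocess(X: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Transform rows exactly as the training matrix was transformed."""
    X = np.asarray(X, dtype=float)
    Xc = X - params.mean
    scale = np.where(params.kept, params.scale, 1.0)
    Xc = Xc / scale
    return Xc[:, params.kept]


# ---------------------------------------------------------------------------
# PCA


@dataclasses.dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # features x components, orthonormal columns
    explained_variance: np.ndarray  # per-component variance of scores
    explained_variance_ratio: np.ndarray
    hotelling_t2: np.ndarray
    t2_limit: float
    outlier_flags: np.ndarray


def pca(Xc: np.ndarray, n_components: int) -> PCAResult:
    """PCA of a centered matrix via SVD, with 95% Hotelling-T2 flags."""
    Xc = np.asarray(Xc, dtype=float)
    n, p = Xc.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components {n_components} exceeds min(n-1, p) = {min(n - 1, p)}")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if not np.any(s > 1e-12 * max(n, p)):
        raise ValueError("degenerate matrix of rank 0")
    total_var = float(np.sum(s**2)) / (n - 1)
    loadings = Vt[:n_components].T
    scores = Xc @ loadings
    ev = s[:n_components] ** 2 / (n - 1)
    k = n_components
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.sum(scores**2 / np.where(ev > 0, ev, np.inf), axis=1)
    if n > k:
        f_crit = stats.f.ppf(0.95, k, n - k)
        t2_limit = k * (n - 1) * (n + 1) / (n * (n - k)) * f_crit
    else:
        t2_limit = np.inf
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=ev,
        explained_variance_ratio=ev / total_var,
        hotelling_t2=t2,
        t2_limit=float(t2_limit),
        outlier_flags=t2 > t2_limit,
    )


# ---------------------------------------------------------------------------
# PLS-DA


@dataclasses.dataclass
class PLSDAModel:
    classes: list[str]
    params: PreprocessParams
    n_components: int
    weights: np.ndarray  # W: features x components
    x_loadings: np.ndarray  # P
    y_loadings: np.ndarray  # Q: classes x components
    coefficients: np.ndarray  # B: features x classes
    scores: np.ndarray  # training T
    y_mean: np.ndarray  # class-column means of the dummy Y


def _dummy_matrix(y: np.ndarray, classes: list[str]) -> np.ndarray:
    Y = np.zeros((y.size, len(classes)))
    for j, c in enumerate(classes):
        Y[y == c, j] = 1.0
    return Y


def plsda_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    scaling: str = "unit_variance",
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSDAModel:
    """Fit NIPALS PLS2 on a centered one-hot class response.

    ``n_components`` is truncated with a warning if it exceeds the rank of
    the preprocessed matrix; non-convergence of a component raises
    :class:`ConvergenceError` naming it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(map(str, y)))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    Xt, params = preprocess(X, scaling)
    Y = _dummy_matrix(y.astype(str), classes)
    y_mean = Y.mean(axis=0)
    Yd = Y - y_mean
    Xd = Xt.copy()
    n, p = Xd.shape
    k = len(classes)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((k, n_components))
    T = np.zeros((n, n_components))
    n_fitted = 0
    for a in range(n_components):
        x_norm = np.linalg.norm(Xd)
        if x_norm < 1e-12 or np.linalg.norm(Yd) < 1e-12:
            warnings.warn(
                f"rank exhausted: truncating at {n_fitted} component(s)", stacklevel=2
            )
            break
        u = Yd[:, int(np.argmax(np.sum(Yd**2, axis=0)))]
        t = np.zeros(n)
        converged = False
        for _ in range(max_iter):
            w = Xd.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm < 1e-15:
                raise ConvergenceError(f"component {a + 1}: degenerate weight vector")
            w = w / w_norm
            t_new = Xd @ w
            tt = float(t_new @ t_new)
            if tt < 1e-15:
                raise ConvergenceError(f"component {a + 1}: vanishing score vector")
            q = Yd.T @ t_new / tt
            qq = float(q @ q)
            if qq < 1e-30:
                raise ConvergenceError(f"component {a + 1}: vanishing Y-loading")
            u = Yd @ q / qq
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            raise ConvergenceError(f"component {a + 1}: no convergence in {max_iter} iterations")
        tt = float(t @ t)
        p_vec = Xd.T @ t / tt
        W[:, a] = w
        P[:, a] = p_vec
        Q[:, a] = q
        T[:, a] = t
        Xd = Xd - np.outer(t, p_vec)
        Yd = Yd - np.outer(t, q)
        n_fitted += 1
    if n_fitted == 0:
        raise ValueError("no PLS components could be extracted")
    W, P, Q, T = W[:, :n_fitted], P[:, :n_fitted], Q[:, :n_fitted], T[:, :n_fitted]
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSDAModel(
        classes=classes,
        params=params,
        n_components=n_fitted,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        coefficients=B,
        scores=T,
        y_mean=y_mean,
    )


def plsda_predict(model: PLSDAModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict classes for new rows; returns (labels, class score matrix).

    Class scores are ``X_new_transformed @ B + y_mean``; the label is the
    argmax, with ties broken deterministically toward the alphabetically
    first class (classes are stored sorted).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.params.mean.size:
        raise ValueError(
            f"feature mismatch: expected {model.params.mean.size} columns, "
            f"got {X_new.shape[1] if X_new.ndim == 2 else 'non-2D input'}"
        )
    Xt = apply_preprocess(X_new, model.params)
    scores = Xt @ model.coefficients + model.y_mean
    labels = np.array([model.classes[i] for i in np.argmax(scores, axis=1)])
    return labels, scores


def select_components_q2(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 4,
    scaling: str = "unit_variance",
) -> int:
    """Pick the component count maximizing leave-one-out Q2 on the dummy Y.

    Optional helper; the pipeline default is the fixed two-component model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    classes = sorted(set(y))
    Y = _dummy_matrix(y, classes)
    n = X.shape[0]
    best_k, best_q2 = 1, -np.inf
    press_base = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    for k in range(1, max_components + 1):
        press = 0.0
        try:
            for i in range(n):
                mask = np.arange(n) != i
                model = plsda_fit(X[mask], y[mask], n_components=k, scaling=scaling)
                _, scores = plsda_predict(model, X[i : i + 1])
                press += float(np.sum((Y[i] - scores[0]) ** 2))
        except (ConvergenceError, ValueError):
            break
        q2 = 1.0 - press / press_base
        if q2 > best_q2 + 1e-12:
            best_k, best_q2 = k, q2
    return best_k


# ---------------------------------------------------------------------------
# confusion matrices and performance


@dataclasses.dataclass
class ConfusionMatrix:
    """Aggregated counts; rows are truth, columns are predictions."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be a square classes x classes array")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def collapse(self, positive: set[str]) -> "ConfusionMatrix":
        """Collapse to a 2x2 positive-vs-negative matrix."""
        pos = [i for i, c in enumerate(self.classes) if c in positive]
        neg = [i for i, c in enumerate(self.classes) if c not in positive]
        if not pos or not neg:
            raise ValueError("positive set must split the classes in two")
        c = self.counts
        counts = np.array(
            [
                [c[np.ix_(pos, pos)].sum(), c[np.ix_(pos, neg)].sum()],
                [c[np.ix_(neg, pos)].sum(), c[np.ix_(neg, neg)].sum()],
            ]
        )
        return ConfusionMatrix(classes=["positive", "negative"], counts=counts)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclasses.dataclass
class Performance:
    """Proportions in [0, 1]; ``None`` marks an undefined (0/0) ratio."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def as_percent(self) -> dict[str, int | None]:
        return {
            name: (None if value is None else round_half_away(100.0 * value))
            for name, value in dataclasses.asdict(self).items()
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def performance(cm: ConfusionMatrix, positive: str | set[str]) -> Performance:
    """Se/Sp/PPV/NPV/accuracy with the given class (or class set) positive."""
    if isinstance(positive, str):
        positive = {positive}
    unknown = positive - set(cm.classes)
    if unknown:
        raise ValueError(f"positive classes not in matrix: {sorted(unknown)}")
    two = cm.collapse(positive) if cm.counts.shape != (2, 2) or set(cm.classes) != {
        "positive",
        "negative",
    } else cm
    tp, fn = int(two.counts[0, 0]), int(two.counts[0, 1])
    fp, tn = int(two.counts[1, 0]), int(two.counts[1, 1])
    return Performance(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation


@dataclasses.dataclass(frozen=True)
class MCCVConfig:
    n_iterations: int = 500
    test_fraction: float = 1.0 / 3.0
    n_components: int = 2
    scaling: str = "unit_variance"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclasses.dataclass
class MCCVResult:
    confusion: ConfusionMatrix
    accuracies: np.ndarray  # per-iteration test accuracy
    test_counts: dict[str, int]  # per-class test-set allocation per iteration

    @property
    def pooled_accuracy(self) -> float:
        return self.confusion.accuracy


def mccv(X: np.ndarray, y: np.ndarray, cfg: MCCVConfig | None = None) -> MCCVResult:
    """Pool predictions over repeated stratified random splits.

    Each iteration draws a stratified test set of fixed per-class size,
    preprocesses and fits on the remaining samples only, and accumulates
    test predictions into one aggregated confusion matrix.
    """
    cfg = MCCVConfig() if cfg is None else cfg
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    classes = sorted(set(y))
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    too_small = [c for c, idx in idx_by_class.items() if idx.size < 2]
    if too_small:
        raise ValueError(f"classes too small to stratify: {too_small}")
    n_test = {}
    for c, idx in idx_by_class.items():
        k = max(1, round(cfg.test_fraction * idx.size))
        n_test[c] = min(k, idx.size - 1)  # always leave >= 1 training sample
    rng = np.random.default_rng(cfg.seed)
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    class_index = {c: i for i, c in enumerate(classes)}
    accuracies = np.empty(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        test_idx = np.concatenate(
            [rng.choice(idx_by_class[c], size=n_test[c], replace=False) for c in classes]
        )
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank truncation on tiny splits is expected
            model = plsda_fit(
                X[train_mask], y[train_mask], n_components=cfg.n_components, scaling=cfg.scaling
            )
            pred, _ = plsda_predict(model, X[test_idx])
        truth = y[test_idx]
        for t_lab, p_lab in zip(truth, pred):
            counts[class_index[t_lab], class_index[p_lab]] += 1
        accuracies[it] = float(np.mean(pred == truth))
    return MCCVResult(
        confusion=ConfusionMatrix(classes=classes, counts=counts),
        accuracies=accuracies,
        test_counts=n_test,
    )
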