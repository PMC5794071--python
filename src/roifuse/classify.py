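"""Nested cross-validated SVM classification with permutation testing.

The harness follows a three-role 10-fold design: in each rotation eight
folds train the classifier, one fold selects the kernel and trade-off
parameter C, and the held-out fold is scored.  Feature z-scoring and
two-sample-t feature selection are refitted inside every training
partition, so no statistic of the tuning or test subjects leaks into
training.  The whole rotation is repeated with re-randomised fold
assignments; significance of the mean accuracy comes from re-running the
full procedure on label-permuted data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

DEFAULT_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)
DEFAULT_KERNELS = ("linear", "poly", "rbf")


@dataclass
class ClassifierConfig:
    """Grids and sizes for the nested-CV SVM harness.

    ``n_repeats`` full 10-fold rotations are averaged; ``n_permutations``
    label shuffles build the null accuracy distribution.  The polynomial
    kernel uses degree ``poly_degree`` with scikit-learn's default
    coefficients.
    """

    kernels: tuple[str, ...] = DEFAULT_KERNELS
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    selection_alpha: float = 0.05
    n_folds: int = 10
    n_repeats: int = 100
    n_permutations: int = 100
    poly_degree: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kernels or not self.C_grid:
            raise ValueError("kernel and C grids must be nonempty")
        unknown = set(self.kernels) - {"linear", "poly", "rbf"}
        if unknown:
            raise ValueError(f"unknown kernels: {sorted(unknown)}")
        if not 0 < self.selection_alpha <= 1:
            raise ValueError("selection_alpha must lie in (0, 1]")
        if self.n_folds < 3:
            raise ValueError("nested train/tune/test roles need at least 3 folds")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("C values must be positive")


@dataclass
class ClassificationReport:
    accuracy_mean: float
    accuracy_sd: float
    sensitivity: float
    specificity: float
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    per_repeat_accuracy: np.ndarray  # (n_repeats,)
    oof_predictions: np.ndarray  # (n_repeats, n_subjects)
    oof_scores: np.ndarray  # (n_repeats, n_subjects) decision values
    consensus_prediction: np.ndarray  # (n_subjects,) majority vote over repeats
    selected_feature_frequency: np.ndarray  # (n_features,) selection rate
    best_params: list[tuple[str, float]] = field(repr=False, default_factory=list)
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "permutation_p": self.permutation_p,
            "per_repeat_accuracy": self.per_repeat_accuracy.tolist(),
            "roc": {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist()},
            "consensus_prediction": self.consensus_prediction.tolist(),
            "selected_feature_frequency": self.selected_feature_frequency.tolist(),
        }


# ---------------------------------------------------------------------------
# feature selection


def ttest_select(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Indices of columns whose pooled two-sample t-test has p < alpha.

    Computed on the given (training) subjects only.  If no column passes,
    the single smallest-p column is returned so downstream fitting always
    has at least one feature.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("feature selection needs exactly two classes in training data")
    a, b = X[y == classes[0]], X[y == classes[1]]
    _, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)  # constant columns: t undefined, never selected
    selected = np.flatnonzero(p < alpha)
    if selected.size == 0:
        selected = np.array([int(np.argmin(p))])
    return selected


class TTestSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping :func:`ttest_select`."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        self.selected_ = ttest_select(X, y, self.alpha)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC (fpr, tpr) and its trapezoidal AUC.

    The AUC equals the concordance probability P(score_pos > score_neg)
    with ties counted 1/2 (the Mann-Whitney statistic).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("ROC needs both classes present")
    pos = labels == classes.max()
    n_pos, n_neg = pos.sum(), (~pos).sum()
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    # step through unique thresholds
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), scores.size - 1]
    tps = np.cumsum(sorted_pos)[distinct]
    fps = np.cumsum(~sorted_pos)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# nested cross-validation


def _fit_train_eval(X_tr, y_tr, X_eval, cfg: ClassifierConfig, kernel: str, C: float):
    svc = SVC(kernel=kernel, C=C, degree=cfg.poly_degree, random_state=0)
    svc.fit(X_tr, y_tr)
    return svc.predict(X_eval), svc.decision_function(X_eval)


def _one_repeat(X, y, cfg: ClassifierConfig, rs: int, reducer=None):
    n = y.size
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=rs)
    folds = [test for _, test in skf.split(np.zeros((n, 1)), y)]
    preds = np.empty(n, dtype=y.dtype)
    scores = np.empty(n)
    n_sel = None
    chosen = []
    for f in range(cfg.n_folds):
        test = folds[f]
        tune = folds[(f + 1) % cfg.n_folds]
        train = np.concatenate(
            [folds[j] for j in range(cfg.n_folds) if j not in (f, (f + 1) % cfg.n_folds)]
        )
        if reducer is not None:
            # per-ROI dimension reduction refitted on the training subjects only
            red = clone(reducer).fit(X[train])
            Xtr, Xtu, Xte = (
                red.transform(X[i]).reshape(len(i), -1) for i in (train, tune, test)
            )
        else:
            Xtr, Xtu, Xte = X[train], X[tune], X[test]
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xtu, Xte = (scaler.transform(A) for A in (Xtr, Xtu, Xte))
        sel = ttest_select(Xtr, y[train], cfg.selection_alpha)
        if n_sel is None:
            n_sel = np.zeros(Xtr.shape[1])
        n_sel[sel] += 1
        Xtr, Xtu, Xte = Xtr[:, sel], Xtu[:, sel], Xte[:, sel]
        best = None
        for kernel in cfg.kernels:  # grid order is the deterministic tie-break
            for C in cfg.C_grid:
                pred_tu, _ = _fit_train_eval(Xtr, y[train], Xtu, cfg, kernel, C)
                acc = float(np.mean(pred_tu == y[tune]))
                if best is None or acc > best[0]:
                    best = (acc, kernel, C)
        _, kernel, C = best
        chosen.append((kernel, C))
        preds[test], scores[test] = _fit_train_eval(Xtr, y[train], Xte, cfg, kernel, C)
    return preds, scores, n_sel / cfg.n_folds, chosen


def nested_cv(
    X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig, reducer=None
) -> ClassificationReport:
    """Run the repeated nested 10-fold SVM evaluation.

    Every subject receives one out-of-fold prediction and decision value
    per repeat; accuracy/sensitivity/specificity are means over repeats,
    and the ROC is computed from the per-subject mean decision value.

    ``X`` is subjects x features, or subjects x ROI x features together
    with a ``reducer`` transformer (e.g. :class:`~roifuse.features.ROIBlockPCA`),
    which is then refitted on each training partition before flattening.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 3 and reducer is None:
        X = X.reshape(X.shape[0], -1)
    if X.ndim == 2 and reducer is not None:
        raise ValueError("a reducer needs the subjects x ROI x feature array")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"need at least n_folds={cfg.n_folds} subjects per class for stratification"
        )
    pos, neg = classes.max(), classes.min()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_repeats) % (2**31 - 1)

    oof_pred = np.empty((cfg.n_repeats, y.size), dtype=y.dtype)
    oof_score = np.empty((cfg.n_repeats, y.size))
    sel_freq = None
    acc = np.empty(cfg.n_repeats)
    sens = np.empty(cfg.n_repeats)
    spec = np.empty(cfg.n_repeats)
    best_params: list[tuple[str, float]] = []
    for rep in range(cfg.n_repeats):
        preds, scores, freq, chosen = _one_repeat(X, y, cfg, int(seeds[rep]), reducer)
        if sel_freq is None:
            sel_freq = np.zeros_like(freq)
        oof_pred[rep], oof_score[rep] = preds, scores
        sel_freq += freq
        acc[rep] = np.mean(preds == y)
        sens[rep] = np.mean(preds[y == pos] == pos)
        spec[rep] = np.mean(preds[y == neg] == neg)
        best_params.extend(chosen)

    mean_scores = oof_score.mean(axis=0)
    fpr, tpr, auc = roc_auc(mean_scores, y)
    votes = (oof_pred == pos).mean(axis=0)
    consensus = np.where(votes >= 0.5, pos, neg)  # ties go to the positive class
    return ClassificationReport(
        accuracy_mean=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=1)) if cfg.n_repeats > 1 else 0.0,
        sensitivity=float(sens.mean()),
        specificity=float(spec.mean()),
        auc=auc,
        roc_fpr=fpr,
        roc_tpr=tpr,
        per_repeat_accuracy=acc,
        oof_predictions=oof_pred,
        oof_scores=oof_score,
        consensus_prediction=consensus,
        selected_feature_frequency=sel_freq / cfg.n_repeats,
        best_params=best_params,
    )


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ClassifierConfig,
    observed_accuracy: float,
    n_permutations: int | None = None,
    reducer=None,
) -> float:
    """Permutation p-value for an observed nested-CV accuracy.

    Each permutation shuffles the labels and reruns the full nested CV
    with the same configuration.  p = (1 + #{perm >= observed}) /
    (1 + n_permutations), the add-one Monte-Carlo estimator, so p is never
    exactly zero and 100 permutations bottom out at 1/101 < 0.01.
    """
    n_perm = cfg.n_permutations if n_permutations is None else n_permutations
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    exceed = 0
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        rep = nested_cv(X, y_perm, cfg, reducer=reducer)
        if rep.accuracy_mean >= observed_accuracy:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def compare_accuracy_distributions(
    acc_a: np.ndarray, acc_b: np.ndarray, paired: bool = True
) -> tuple[float, float]:
    """Two-sided t-test between two per-repeat accuracy vectors.

    Paired by default (valid when both runs shared fold seeds); unpaired
    Welch otherwise.
    """
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if paired:
        if acc_a.shape != acc_b.shape:
            raise ValueError("paired comparison needs equal-length accuracy vectors")
        if np.allclose(acc_a, acc_b):
            return 0.0, 1.0
        t, p = stats.ttest_rel(acc_a, acc_b)
    else:
        t, p = stats.ttest_ind(acc_a, acc_b, equal_var=False)
    return float(t), float(p)


class NestedCVSVM(BaseEstimator, ClassifierMixin):
    """Estimator facade over :func:`nested_cv`.

    ``fit`` runs the repeated nested evaluation and stores the report in
    ``report_``; ``predict`` applies the consensus-refit model (scaler +
    t-test selection + SVC with the modal (kernel, C) of the nested runs,
    refitted on all fitted subjects) to new data.
    """

    def __init__(
        self,
        kernels: tuple[str, ...] = DEFAULT_KERNELS,
        C_grid: tuple[float, ...] = DEFAULT_C_GRID,
        selection_alpha: float = 0.05,
        n_folds: int = 10,
        n_repeats: int = 100,
        n_permutations: int = 100,
        poly_degree: int = 3,
        seed: int = 0,
    ):
        self.kernels = kernels
        self.C_grid = C_grid
        self.selection_alpha = selection_alpha
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.n_permutations = n_permutations
        self.poly_degree = poly_degree
        self.seed = seed

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            kernels=tuple(self.kernels),
            C_grid=tuple(self.C_grid),
            selection_alpha=self.selection_alpha,
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            n_permutations=self.n_permutations,
            poly_degree=self.poly_degree,
            seed=self.seed,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        cfg = self._config()
        self.report_ = nested_cv(X, y, cfg)
        self.classes_ = np.unique(y)
        kernel, C = max(
            set(self.report_.best_params), key=self.report_.best_params.count
        )
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.selected_ = ttest_select(Xs, y, cfg.selection_alpha)
        self.svc_ = SVC(kernel=kernel, C=C, degree=cfg.poly_degree, random_state=0)
        self.svc_.fit(Xs[:, self.selected_], y)
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.svc_.predict(Xs[:, self.selected_])

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.svc_.decision_function(Xs[:, self.selected_])
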