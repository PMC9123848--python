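"""Outcome classification: logistic models, ROC/AUC, LOOCV and thresholds.

Feature vectors (global mean / SD of alpha and beta connection z-scores)
are combined by unpenalized maximum-likelihood logistic regression, the
same model family as a binomial GLM.  Discrimination is summarized by the
ROC curve and its trapezoidal AUC (equivalently the Mann-Whitney
concordance statistic with ties counted 1/2), with percentile bootstrap
confidence intervals over subject-level resamples.  Generalization is
probed with leave-one-out cross-validation; the operating threshold is
the candidate maximizing the geometric mean of sensitivity and
specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn import metrics as skm

__all__ = [
    "fit_logistic",
    "roc_and_auc",
    "bootstrap_auc_ci",
    "loocv",
    "optimal_threshold",
    "confusion_metrics",
    "precision_recall",
    "evaluate_model",
    "FEATURE_SETS",
]

#: classifier feature sets, as columns of the per-subject feature matrix
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "alpha_mean": ("alpha_mean",),
    "beta_mean": ("beta_mean",),
    "alpha_sd": ("alpha_sd",),
    "beta_sd": ("beta_sd",),
    "two_feature": ("alpha_mean", "beta_mean"),
    "four_feature": ("alpha_mean", "beta_mean", "alpha_sd", "beta_sd"),
}


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(y) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError(f"feature matrix has {X.shape[0]} rows for {y.size} labels")
    return X, y


@dataclass
class LogisticModel:
    """An unpenalized logistic fit with in-sample predicted probabilities."""

    params: np.ndarray
    fitted: np.ndarray
    converged: bool
    separation: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = np.clip(X @ self.params[1:] + self.params[0], -700, 700)
        return 1.0 / (1.0 + np.exp(-eta))


def _fit_glm(X: np.ndarray, y: np.ndarray) -> LogisticModel:
    """Unchecked binomial-GLM fit shared by the public fit and LOOCV folds."""
    design = np.column_stack([np.ones(len(y)), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
    fitted = np.asarray(res.fittedvalues, dtype=float)
    separation = bool(np.any(fitted > 1 - 1e-8) or np.any(fitted < 1e-8))
    converged = bool(getattr(res, "converged", True)) and not separation
    if separation:
        warnings.warn(
            "possible perfect separation: fitted probabilities saturate at 0/1",
            stacklevel=2,
        )
    return LogisticModel(
        params=np.asarray(res.params, dtype=float),
        fitted=fitted,
        converged=converged,
        separation=separation,
    )


def fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticModel:
    """Maximum-likelihood logistic regression (binomial GLM).

    Requires at least two subjects per class.  Perfect separation is
    flagged (with a warning) rather than raised: the fitted probabilities
    are still returned, saturated at 0/1.
    """
    X, y = _check_xy(X, y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2 or len(np.unique(y)) < 2:
        raise ValueError(
            f"need >= 2 subjects in each class, got counts {counts.tolist()}"
        )
    return _fit_glm(X, y)


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all distinct score thresholds, and AUC.

    The AUC is the trapezoidal area, which equals the Mann-Whitney
    pair-concordance statistic with tied scores counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an ROC curve")
    fpr, tpr, _ = skm.roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(skm.auc(fpr, tpr))


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile (2.5/97.5) bootstrap interval for the AUC.

    Subjects are resampled with replacement; replicates that lose a class
    are redrawn (at most 100 retries each).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if np.bincount(labels, minlength=2).min() < 3:
        warnings.warn(
            "fewer than 3 subjects in a class: bootstrap interval is unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(int(seed) % 2**31)
    n = labels.size
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            if labels[idx].min() != labels[idx].max():
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap replicate")
        aucs[b] = skm.roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class LoocvResult:
    """Held-out scores from n leave-one-out folds (n-1 training samples)."""

    scores: np.ndarray
    flagged_folds: list[int] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return self.scores.size

    @property
    def train_size(self) -> int:
        return self.scores.size - 1


def loocv(X: np.ndarray, y: np.ndarray) -> LoocvResult:
    """Leave-one-out cross-validated prediction scores.

    Each of the n folds trains an unpenalized logistic model on the other
    n-1 subjects and scores the held-out one.  A fold whose training set
    degenerates to a single class is scored by the training prevalence and
    flagged.
    """
    X, y = _check_xy(X, y)
    n = y.size
    if n < 3:
        raise ValueError(f"LOOCV needs n >= 3 subjects, got {n}")
    scores = np.empty(n)
    flagged: list[int] = []
    for i in range(n):
        keep = np.arange(n) != i
        y_tr = y[keep]
        if y_tr.min() == y_tr.max():
            scores[i] = float(y_tr.mean())
            flagged.append(i)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = _fit_glm(X[keep], y_tr)
        scores[i] = float(model.predict(X[i : i + 1])[0])
    return LoocvResult(scores=scores, flagged_folds=flagged)


def optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing the geometric mean of sensitivity and specificity.

    Candidates are the midpoints between adjacent distinct scores plus the
    two trivial classifications (everything positive / negative); a
    prediction is positive when ``score >= threshold``.  Ties are broken
    toward higher specificity, then toward the higher threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], 0.5 * (distinct[:-1] + distinct[1:]), [distinct[-1] + 1.0]]
    )
    pos = labels == 1
    best = (-np.inf, -np.inf, -np.inf)
    best_t = candidates[0]
    for t in candidates:
        pred = scores >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        key = (np.sqrt(sens * spec), spec, t)
        if key > best:
            best, best_t = key, t
    return float(best_t)


@dataclass
class ConfusionMetrics:
    """Confusion counts and the standard ratios, in percent."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {
            k: round(getattr(self, k), ndigits)
            for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
        }


def _ratio_pct(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionMetrics:
    """Accuracy, sensitivity, specificity, PPV and NPV at a threshold.

    Predictions are ``score >= threshold``; undefined ratios (zero
    denominator) are reported as NaN with a warning.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    return ConfusionMetrics(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=_ratio_pct(tp + tn, tp + fn + tn + fp, "accuracy"),
        sensitivity=_ratio_pct(tp, tp + fn, "sensitivity"),
        specificity=_ratio_pct(tn, tn + fp, "specificity"),
        ppv=_ratio_pct(tp, tp + fp, "PPV"),
        npv=_ratio_pct(tn, tn + fn, "NPV"),
    )


def precision_recall(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(recall, precision) operating points, ordered by descending recall.

    Thresholds sweep all distinct score values; where several thresholds
    reach the same recall, the best-precision (highest-threshold) point is
    kept, so a perfectly ranked cohort shows precision 1 at every recall.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if (labels == 1).sum() < 1:
        raise ValueError("precision-recall needs at least one positive subject")
    precision, recall, _ = skm.precision_recall_curve(labels, scores)
    best: dict[float, float] = {}
    for r, p in zip(recall, precision):
        best[r] = max(best.get(r, 0.0), p)
    pts = sorted(best.items(), key=lambda rp: -rp[0])
    return np.asarray(pts, dtype=float)


@dataclass
class CohortEvaluation:
    """Bundle of classification results for one feature set."""

    name: str
    features: tuple[str, ...]
    auc: float
    auc_ci: tuple[float, float]
    roc_points: np.ndarray = field(repr=False)
    loocv_scores: np.ndarray = field(repr=False)
    loocv_auc: float = float("nan")
    threshold: float = float("nan")
    confusion: ConfusionMetrics | None = None
    pr_points: np.ndarray | None = field(default=None, repr=False)
    converged: bool = True

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "features": list(self.features),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "loocv_auc": self.loocv_auc,
            "threshold": self.threshold,
            "converged": self.converged,
            "roc_points": self.roc_points.tolist(),
            "loocv_scores": self.loocv_scores.tolist(),
        }
        if self.confusion is not None:
            d["loocv_metrics"] = self.confusion.rounded()
            d["confusion_counts"] = {
                k: getattr(self.confusion, k) for k in ("tp", "fn", "tn", "fp")
            }
        if self.pr_points is not None:
            d["pr_points"] = self.pr_points.tolist()
        return d


def evaluate_model(
    X: np.ndarray,
    y: np.ndarray,
    name: str = "model",
    features: tuple[str, ...] = (),
    n_boot: int = 1000,
    seed: int = 0,
) -> CohortEvaluation:
    """Full evaluation of one feature set.

    The primary AUC (with bootstrap CI) is computed from the in-sample
    fitted scores; LOOCV held-out scores give a second AUC and drive the
    operating threshold, confusion metrics and precision-recall curve.
    """
    X, y = _check_xy(X, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_logistic(X, y)
    roc_pts, auc = roc_and_auc(model.fitted, y)
    ci = bootstrap_auc_ci(model.fitted, y, n_boot=n_boot, seed=seed)
    cv = loocv(X, y)
    _, cv_auc = roc_and_auc(cv.scores, y)
    thr = optimal_threshold(cv.scores, y)
    conf = confusion_metrics(cv.scores, y, thr)
    pr = precision_recall(cv.scores, y)
    return CohortEvaluation(
        name=name,
        features=tuple(features),
        auc=auc,
        auc_ci=ci,
        roc_points=roc_pts,
        loocv_scores=cv.scores,
        loocv_auc=cv_auc,
        threshold=thr,
        confusion=conf,
        pr_points=pr,
        converged=model.converged,
    )
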