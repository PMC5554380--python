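"""Single-marker biomarker evaluation.

The marker's ΔCt is used to discriminate a positive class (ASD, simulated and
observed at *lower* ΔCt, i.e. upregulated) from a comparison class.  Four
operations cover the evaluation chain:

* :func:`roc_curve` — classical univariate ROC over all distinct ΔCt
  thresholds, with AUC (trapezoid ≡ two-sample rank statistic), a bootstrap
  95% CI, and the maximum-Youden cutoff (J = sensitivity + specificity − 1);
* :func:`fit_logistic` — a one-predictor logistic model with a regularized
  fallback under complete separation;
* :func:`cross_validate` — repeated random sub-sampling cross-validation
  (default 100 repeats, stratified 2/3 train : 1/3 test) of the logistic
  model, reporting the average AUC, a vertically averaged ROC curve, and
  per-sample average predicted probabilities with the 0.5 decision rule;
* :func:`permutation_test` — an AUC permutation null built by re-assigning
  class labels and re-evaluating with a short (default 3-repeat) CV,
  yielding an add-one permutation p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special
from sklearn import metrics
from sklearn.linear_model import LogisticRegression
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger(__name__)

Direction = Literal["lower", "higher"]


def binary_labels(
    groups: Sequence[str], positive: str, negative: str
) -> np.ndarray:
    """Boolean labels (True = positive class) from group names."""
    groups = np.asarray(groups, dtype=object)
    keep = np.isin(groups, [positive, negative])
    if not keep.all():
        raise ValueError("groups contain labels other than the two classes")
    return groups == positive


# ---------------------------------------------------------------------------
# ROC with maximum-Youden cutoff
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """ROC curve over all distinct ΔCt thresholds.

    ``fpr``/``tpr`` trace the curve from (0,0) to (1,1); ``cutoffs`` holds the
    ΔCt decision thresholds on the data scale (positive call at ΔCt ≤ cutoff
    when ``direction="lower"``).  ``cutoff`` is the maximum-Youden threshold
    with its sensitivity/specificity pair.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    direction: Direction

    @property
    def youden_per_threshold(self) -> np.ndarray:
        return self.tpr - self.fpr


def _scores(x: np.ndarray, direction: Direction) -> np.ndarray:
    if direction == "lower":
        return -x
    if direction == "higher":
        return x
    raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")


def roc_curve(
    values: Sequence[float] | pd.Series,
    labels: Sequence[bool],
    *,
    direction: Direction = "lower",
    n_boot: int = 1000,
    seed: int | None = None,
) -> RocCurve:
    """Classical univariate ROC analysis of a single ΔCt marker.

    ``direction="lower"`` means the positive class sits at lower ΔCt (higher
    expression), so a sample is called positive when ΔCt ≤ threshold.  The
    AUC is the trapezoid area, identical to the concordant-pair fraction.
    Youden ties break toward higher specificity, then lower cutoff.  The 95%
    CI is a stratified bootstrap percentile interval.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("values and labels must align")
    mask = ~np.isnan(x)
    x, y = x[mask], y[mask]
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be non-empty")

    s = _scores(x, direction)
    fpr, tpr, thr = metrics.roc_curve(y, s, drop_intermediate=False)
    cutoffs = -thr if direction == "lower" else thr
    auc = float(metrics.auc(fpr, tpr))

    j = tpr - fpr
    finite = np.isfinite(cutoffs)
    # argmax J; ties → higher specificity (lower fpr), then lower ΔCt cutoff
    order = np.lexsort((cutoffs, fpr, -j))
    best = next(i for i in order if finite[i])
    ci = _bootstrap_auc_ci(x, y, direction, n_boot, seed)
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        cutoffs=cutoffs,
        auc=auc,
        auc_ci=ci,
        cutoff=float(cutoffs[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        youden=float(j[best]),
        direction=direction,
    )


def _bootstrap_auc_ci(
    x: np.ndarray,
    y: np.ndarray,
    direction: Direction,
    n_boot: int,
    seed: int | None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    if n_boot <= 0:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    pos, neg = np.where(y)[0], np.where(~y)[0]
    s = _scores(x, direction)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos, size=pos.size, replace=True)
        ni = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([pi, ni])
        aucs[b] = metrics.roc_auc_score(y[idx], s[idx])
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """One-predictor logistic model P(positive | x) = expit(β0 + β1·x)."""

    intercept: float
    slope: float
    regularized: bool = False

    def predict_proba(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return special.expit(self.intercept + self.slope * x)

    def classify(self, x: Sequence[float], threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(x) > threshold


def fit_logistic(
    values: Sequence[float],
    labels: Sequence[bool],
    *,
    fallback: bool = True,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of class on the single ΔCt predictor.

    Under complete separation the MLE diverges; with ``fallback`` a ridge
    (L2) fit takes over with a logged note, otherwise this is an error.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    mask = ~np.isnan(x)
    x, y = x[mask], y[mask]
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be present")
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y.astype(float), design).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e6:
            raise PerfectSeparationError("diverging coefficients")
        return LogisticModel(float(res.params[0]), float(res.params[1]))
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        if not fallback:
            raise
        logger.info("complete separation: falling back to a regularized logistic fit")
        clf = LogisticRegression(C=1.0, solver="lbfgs").fit(x.reshape(-1, 1), y)
        return LogisticModel(
            float(clf.intercept_[0]), float(clf.coef_[0, 0]), regularized=True
        )


# ---------------------------------------------------------------------------
# Repeated random sub-sampling cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvReport:
    """Results of repeated random sub-sampling CV of the logistic model.

    ``average_probability`` averages each sample's predicted positive-class
    probability over exactly the repeats in which it sat in the test split.
    Sensitivity/specificity are read from those averages at the probability
    0.5 rule.
    """

    repeats: int
    train_fraction: float
    test_aucs: np.ndarray
    average_auc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    average_probability: pd.Series
    sensitivity: float
    specificity: float
    misclassified: tuple[str, ...]
    labels: pd.Series


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx = []
    for cls in (True, False):
        idx = np.where(y == cls)[0]
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(rng.choice(idx, size=n_train, replace=False))
    train = np.concatenate(train_idx)
    mask = np.zeros(y.size, dtype=bool)
    mask[train] = True
    return np.where(mask)[0], np.where(~mask)[0]


def cross_validate(
    values: pd.Series | Sequence[float],
    labels: Sequence[bool],
    *,
    repeats: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
    fpr_grid_size: int = 101,
) -> CvReport:
    """Repeated random sub-sampling CV of the one-predictor logistic model.

    Each repeat draws a stratified ``train_fraction`` split (so every test
    fold contains both classes), fits the logistic model on the training
    samples, and scores the test samples.  The average ROC curve is the
    vertical (TPR-at-fixed-FPR) average over repeats on a fixed grid.
    """
    if isinstance(values, pd.Series):
        ids = values.index
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        ids = pd.RangeIndex(x.size)
    y = np.asarray(labels, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("values and labels must align")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs at least two samples")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be ≥ 1")

    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, fpr_grid_size)
    tpr_sum = np.zeros_like(grid)
    prob_sum = np.zeros(x.size)
    prob_count = np.zeros(x.size, dtype=int)
    aucs = np.empty(repeats)
    for rep in range(repeats):
        train, test = _stratified_split(y, train_fraction, rng)
        model = fit_logistic(x[train], y[train])
        p = model.predict_proba(x[test])
        aucs[rep] = metrics.roc_auc_score(y[test], p)
        fpr, tpr, _ = metrics.roc_curve(y[test], p, drop_intermediate=False)
        tpr_sum += np.interp(grid, fpr, tpr)
        prob_sum[test] += p
        prob_count[test] += 1

    with np.errstate(invalid="ignore"):
        avg_prob = np.where(prob_count > 0, prob_sum / np.maximum(prob_count, 1), np.nan)
    avg_prob_series = pd.Series(avg_prob, index=ids)
    label_series = pd.Series(y, index=ids)

    seen = prob_count > 0
    pos, neg = y & seen, (~y) & seen
    sensitivity = float(np.mean(avg_prob[pos] > 0.5)) if pos.any() else float("nan")
    specificity = float(np.mean(avg_prob[neg] < 0.5)) if neg.any() else float("nan")
    wrong = seen & ((y & ~(avg_prob > 0.5)) | (~y & ~(avg_prob < 0.5)))
    return CvReport(
        repeats=repeats,
        train_fraction=train_fraction,
        test_aucs=aucs,
        average_auc=float(aucs.mean()),
        fpr_grid=grid,
        mean_tpr=tpr_sum / repeats,
        average_probability=avg_prob_series,
        sensitivity=sensitivity,
        specificity=specificity,
        misclassified=tuple(str(i) for i in ids[wrong]),
        labels=label_series,
    )


# ---------------------------------------------------------------------------
# Permutation testing on AUC
# ---------------------------------------------------------------------------


@dataclass
class PermutationReport:
    """AUC permutation test: observed CV performance vs a label-shuffled null."""

    observed_auc: float
    null_aucs: np.ndarray
    p_value: float
    n_perm: int
    inner_repeats: int


def permutation_test(
    values: pd.Series | Sequence[float],
    labels: Sequence[bool],
    *,
    n_perm: int = 100,
    inner_repeats: int = 3,
    train_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> PermutationReport:
    """Permutation test on the CV average AUC.

    The observed statistic is the average AUC of an ``inner_repeats``-repeat
    random sub-sampling CV on the true labels; each of the ``n_perm``
    permutations re-assigns class labels at random and is evaluated
    identically.  The p-value uses the add-one rule (b + 1)/(m + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1 (degenerate null otherwise)")
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)

    def _cv_auc(lab: np.ndarray, s: int) -> float:
        return cross_validate(
            x, lab, repeats=inner_repeats, train_fraction=train_fraction, seed=s
        ).average_auc

    observed = _cv_auc(y, int(rng.integers(2**31 - 1)))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _cv_auc(rng.permutation(y), int(rng.integers(2**31 - 1)))
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return PermutationReport(
        observed_auc=float(observed),
        null_aucs=null,
        p_value=p,
        n_perm=n_perm,
        inner_repeats=inner_repeats,
    )
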