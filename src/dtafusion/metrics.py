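"""Evaluation metrics for affinity regression and thresholded classification.

* MSE — mean squared error (the training loss).
* CI — concordance index: the probability that a pair of interactions with
  different true affinities is ranked correctly by the predictions. Pairs
  tied in the true affinity are excluded from the denominator; prediction
  ties score 1/2.
* r_m^2 — external-predictivity metric: r^2 * (1 - sqrt(|r^2 - r0^2|)),
  with r^2 the squared Pearson correlation (with intercept) and r0^2 the
  coefficient of determination of the least-squares fit through the origin
  of predictions on observations.
* AUPR — area under the precision-recall curve via the average-precision
  step summation (no linear interpolation), after binarizing affinities at
  a dataset-specific threshold (7 on pKd, 12.1 on the KIBA score scale).
* McNemar — paired test on two classifiers' discordant error counts, exact
  binomial for small counts and continuity-corrected chi-square otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._util import logger
from .data_io import binarize_affinity


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined for the given inputs."""


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.size}, y_pred has {y_pred.size}"
        )
    if y_true.size == 0:
        raise ValueError("empty input")
    return y_true, y_pred


def mse(y_true, y_pred) -> float:
    """Mean of squared residuals."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.mean((y_true - y_pred) ** 2))


def concordance_index(y_true, y_pred) -> float:
    """Concordance index over pairs with distinct true affinities.

    For all (i, j) with y_true_i > y_true_j: scores 1 if y_pred_i > y_pred_j,
    1/2 on a prediction tie, 0 otherwise; normalized by the pair count.
    Invariant under strictly increasing transforms of the predictions.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 2 or np.all(y_true == y_true[0]):
        raise UndefinedMetricError("concordance index needs two distinct true values")
    order = np.argsort(y_true, kind="mergesort")
    yt, yp = y_true[order], y_pred[order]
    num = 0.0
    den = 0
    # chunked upper-triangle comparison: j ranges over rows strictly above i
    chunk = 256
    n = yt.size
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        for i in range(start, stop):
            hi = yp[i + 1 :][yt[i + 1 :] > yt[i]]
            if hi.size == 0:
                continue
            den += hi.size
            num += float(np.sum(hi > yp[i])) + 0.5 * float(np.sum(hi == yp[i]))
    return num / den


def rm2(y_true, y_pred) -> float:
    """r_m^2 = r^2 * (1 - sqrt(|r^2 - r0^2|)).

    r0^2 is the coefficient of determination of the through-origin
    least-squares fit of predictions on observations. Always <= r^2 and
    equals 1 only for a perfect fit.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 3:
        raise UndefinedMetricError("r_m^2 needs at least 3 observations")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise UndefinedMetricError("r_m^2 undefined for constant sequences")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    r2 = r * r
    k = float(np.dot(y_true, y_pred) / np.dot(y_true, y_true))
    ss_res = float(np.sum((y_pred - k * y_true) ** 2))
    ss_tot = float(np.sum((y_pred - y_pred.mean()) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r02))))


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve by average precision.

    AP = (1/P) * sum over positives, in descending-score order, of the
    precision at each positive hit. Step integration, no interpolation.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise UndefinedMetricError("AUPR needs at least one positive and one negative")
    order = np.argsort(-scores, kind="mergesort")
    hits = labels[order] == 1
    cum_pos = np.cumsum(hits)
    precision = cum_pos / np.arange(1, labels.size + 1)
    return float(precision[hits].sum() / n_pos)


def mcnemar_test(labels, preds_a, preds_b) -> float:
    """Two-sided McNemar p-value for paired classifiers.

    b counts instances A classifies correctly and B incorrectly; c the
    reverse. Exact binomial p = min(1, 2 P(X <= min(b, c) | b+c, 1/2)) when
    b + c < 25, else the continuity-corrected chi-square approximation.
    """
    labels = np.asarray(labels).ravel()
    preds_a = np.asarray(preds_a).ravel()
    preds_b = np.asarray(preds_b).ravel()
    if not labels.shape == preds_a.shape == preds_b.shape:
        raise ValueError("labels, preds_a, preds_b must have equal length")
    for arr, name in ((labels, "labels"), (preds_a, "preds_a"), (preds_b, "preds_b")):
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")
    a_right = preds_a == labels
    b_right = preds_b == labels
    b = int(np.sum(a_right & ~b_right))
    c = int(np.sum(~a_right & b_right))
    if b + c == 0:
        logger.warning("mcnemar_test: no discordant pairs; p = 1.0")
        return 1.0
    if b + c < 25:
        p = 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5)
        return float(min(1.0, p))
    chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class EvaluationReport:
    """Pooled test-set metrics with fold-wise standard deviations."""

    mse: float
    ci: float
    rm2: float
    aupr: float
    std_ci: float = 0.0
    std_rm2: float = 0.0
    std_aupr: float = 0.0
    threshold: float = float("nan")
    n: int = 0

    def __post_init__(self) -> None:
        for name in ("mse", "ci", "rm2", "aupr"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.ci <= 1.0:
            raise ValueError("CI must lie in [0, 1]")
        if not 0.0 <= self.aupr <= 1.0:
            raise ValueError("AUPR must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "mse": self.mse, "ci": self.ci, "rm2": self.rm2, "aupr": self.aupr,
            "std_ci": self.std_ci, "std_rm2": self.std_rm2, "std_aupr": self.std_aupr,
            "threshold": self.threshold, "n": self.n,
        }

    def __str__(self) -> str:
        lines = [
            f"n          {self.n}",
            f"threshold  {self.threshold:g}",
            f"MSE        {self.mse:.4f}",
            f"CI         {self.ci:.4f} (sd {self.std_ci:.4f})",
            f"r_m^2      {self.rm2:.4f} (sd {self.std_rm2:.4f})",
            f"AUPR       {self.aupr:.4f} (sd {self.std_aupr:.4f})",
        ]
        return "\n".join(lines)


def evaluate(
    y_true,
    y_pred,
    threshold: float,
    fold_predictions: Optional[Sequence[Mapping[str, np.ndarray]]] = None,
) -> EvaluationReport:
    """All four metrics on the pooled predictions.

    ``fold_predictions`` — optional per-fold (or per-repeat) dicts with
    ``y_true``/``y_pred`` entries — provide the standard deviations of CI,
    r_m^2 and AUPR; without them the deviations are reported as 0.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    labels = binarize_affinity(y_true, threshold)
    try:
        pooled_aupr = aupr(labels, y_pred)
    except UndefinedMetricError as exc:
        raise UndefinedMetricError(f"aupr: {exc}") from None
    try:
        pooled_ci = concordance_index(y_true, y_pred)
    except UndefinedMetricError as exc:
        raise UndefinedMetricError(f"concordance_index: {exc}") from None
    try:
        pooled_rm2 = rm2(y_true, y_pred)
    except UndefinedMetricError as exc:
        raise UndefinedMetricError(f"rm2: {exc}") from None
    stds = {"ci": 0.0, "rm2": 0.0, "aupr": 0.0}
    if fold_predictions:
        per_fold = {"ci": [], "rm2": [], "aupr": []}
        for fold in fold_predictions:
            ft, fp = np.asarray(fold["y_true"]), np.asarray(fold["y_pred"])
            per_fold["ci"].append(concordance_index(ft, fp))
            per_fold["rm2"].append(rm2(ft, fp))
            per_fold["aupr"].append(aupr(binarize_affinity(ft, threshold), fp))
        stds = {k: float(np.std(v)) for k, v in per_fold.items()}
    return EvaluationReport(
        mse=mse(y_true, y_pred),
        ci=pooled_ci,
        rm2=pooled_rm2,
        aupr=pooled_aupr,
        std_ci=stds["ci"],
        std_rm2=stds["rm2"],
        std_aupr=stds["aupr"],
        threshold=threshold,
        n=int(y_true.size),
    )


def evaluate_predictions_csv(path, threshold: float) -> EvaluationReport:
    """Tool-agnostic entry: a CSV with drug_id,protein_id,y_true,y_pred."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("y_true", "y_pred"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return evaluate(df["y_true"].to_numpy(), df["y_pred"].to_numpy(), threshold)


def paired_bootstrap_pvalue(
    y_true, pred_a, pred_b, metric, n_boot: int = 2000, seed: int = 0
) -> float:
    """Paired-bootstrap two-sided p-value for a continuous metric difference.

    The documented alternative to McNemar for regression metrics: resample
    rows with replacement, recompute metric(A) - metric(B), and report the
    two-sided tail probability of a sign flip relative to the observed
    difference.
    """
    y_true = np.asarray(y_true, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    observed = metric(y_true, pred_a) - metric(y_true, pred_b)
    if observed == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    flips = 0
    for _ in range(n_boot):
        idx = rng.integers(0, y_true.size, y_true.size)
        try:
            diff = metric(y_true[idx], pred_a[idx]) - metric(y_true[idx], pred_b[idx])
        except UndefinedMetricError:
            continue
        if diff * observed <= 0:
            flips += 1
    return float(min(1.0, 2.0 * (flips + 1) / (n_boot + 1)))
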