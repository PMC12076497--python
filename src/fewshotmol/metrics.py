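"""Evaluation metrics for ranked virtual-screening output.

Five metrics: ROC-AUC, ΔAUC-PR (area under the precision–recall curve
minus the positive-class base rate), BEDROC (early-recognition metric,
α = 20 by default), balanced accuracy and Matthews correlation at a 0.5
score threshold — plus the two-sided paired Wilcoxon signed-rank test
used to compare methods across paired benchmark cells.

Conventions:

* ties in scores are handled by average ranks everywhere;
* BEDROC is the rank-exponential sum normalized by its discrete
  min/max, so a perfect ranking scores exactly 1 and the worst exactly 0;
* MCC is 0 when a confusion-matrix denominator factor vanishes;
* the Wilcoxon test drops zero differences, uses the exact conditional
  distribution for n <= 25 (tie-aware, via a subset-sum count over
  doubled average ranks) and the tie-corrected normal approximation
  otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .exceptions import (
    AllZeroDifferences,
    DimensionMismatch,
    OneClassOnly,
    TooFewPairs,
)

METRIC_NAMES = ("auc", "delta_auc_pr", "bedroc", "bacc", "mcc")

DEFAULT_BEDROC_ALPHA = 20.0
DEFAULT_THRESHOLD = 0.5


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise DimensionMismatch("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise OneClassOnly("both classes must be present")
    return scores, labels


def auc(scores, labels) -> float:
    """ROC-AUC = Mann–Whitney concordance probability (ties count 1/2)."""
    scores, labels = _validate(scores, labels)
    return float(roc_auc_score(labels, scores))


def delta_auc_pr(scores, labels) -> float:
    """Step-integrated AUC-PR minus the random-classifier baseline.

    The baseline is the positive fraction among the evaluated queries, so
    a constant scorer gets exactly 0.
    """
    scores, labels = _validate(scores, labels)
    base = labels.mean()
    return float(average_precision_score(labels, scores) - base)


def bedroc(scores, labels, alpha: float = DEFAULT_BEDROC_ALPHA) -> float:
    """Boltzmann-enhanced discrimination of the ROC curve.

    The rank-exponential sum ``S = sum_actives exp(-alpha * r_i / N)``
    (average ranks for ties, rank 1 = highest score) is normalized by its
    discrete extremes, ``(S - S_min) / (S_max - S_min)``, placing BEDROC
    in [0, 1] with exact endpoints for perfect/inverted rankings.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    scores, labels = _validate(scores, labels)
    N = len(scores)
    n = int(labels.sum())
    ranks = rankdata(-scores, method="average")  # 1 = best
    s = np.exp(-alpha * ranks[labels == 1] / N).sum()
    all_ranks = np.arange(1, N + 1, dtype=np.float64)
    s_max = np.exp(-alpha * all_ranks[:n] / N).sum()
    s_min = np.exp(-alpha * all_ranks[N - n :] / N).sum()
    return float((s - s_min) / (s_max - s_min))


def bacc_mcc(scores, labels, threshold: float = DEFAULT_THRESHOLD):
    """Balanced accuracy and MCC at a score threshold (pred = score >= t)."""
    scores, labels = _validate(scores, labels)
    pred = (scores >= threshold).astype(int)
    return (
        float(balanced_accuracy_score(labels, pred)),
        float(matthews_corrcoef(labels, pred)),
    )


def metric_vector(scores, labels, alpha=DEFAULT_BEDROC_ALPHA, threshold=DEFAULT_THRESHOLD):
    """All five metrics plus class counts, as a flat dict."""
    scores, labels = _validate(scores, labels)
    bacc, mcc = bacc_mcc(scores, labels, threshold)
    return {
        "auc": auc(scores, labels),
        "delta_auc_pr": delta_auc_pr(scores, labels),
        "bedroc": bedroc(scores, labels, alpha),
        "bacc": bacc,
        "mcc": mcc,
        "n_pos": int(labels.sum()),
        "n_neg": int((1 - labels).sum()),
    }


def paired_wilcoxon(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for a vs b.

    Zero differences are dropped.  For n <= 25 remaining pairs the exact
    conditional null distribution of the positive rank sum is computed by
    counting sign patterns (a subset-sum recursion over doubled average
    ranks, so ties are handled exactly); beyond that, the tie-corrected
    normal approximation without continuity correction is used.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise DimensionMismatch("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise AllZeroDifferences("all paired differences are zero")
    n = d.size
    if n < 5:
        raise TooFewPairs(f"need >= 5 nonzero paired differences, got {n}")
    ranks = rankdata(np.abs(d), method="average")
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_two_sided_p(ranks, w_pos)
    return _normal_two_sided_p(ranks, w_pos, n)


def _exact_two_sided_p(ranks, w_pos) -> float:
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r].copy()  # copy: overlapping views
    n_patterns = counts.sum()
    w2 = int(np.rint(2.0 * w_pos))
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_two_sided_p(ranks, w_pos, n) -> float:
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mu) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))
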