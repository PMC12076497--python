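"""Metric implementations vs independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon

from fewshotmol import metrics as M
from fewshotmol.exceptions import (
    AllZeroDifferences,
    OneClassOnly,
    TooFewPairs,
)

# ---------------------------------------------------------------------------
# oracles: deliberately naive, loop-based reimplementations
# ---------------------------------------------------------------------------


def auc_oracle(scores, labels):
    """O(n^2) pairwise concordance counting, ties = 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def auc_pr_oracle(scores, labels):
    """Step-wise integration over distinct thresholds (descending)."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # group tied scores
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def bedroc_oracle(scores, labels, alpha):
    """Explicit average-rank computation and discrete min/max scaling."""
    n_total = len(scores)
    order = sorted(range(n_total), key=lambda i: -scores[i])
    ranks = [0.0] * n_total
    i = 0
    while i < n_total:
        j = i
        while j < n_total and scores[order[j]] == scores[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    n_act = int(sum(labels))
    s = sum(
        np.exp(-alpha * ranks[i] / n_total)
        for i in range(n_total)
        if labels[i] == 1
    )
    s_max = sum(np.exp(-alpha * r / n_total) for r in range(1, n_act + 1))
    s_min = sum(
        np.exp(-alpha * r / n_total)
        for r in range(n_total - n_act + 1, n_total + 1)
    )
    return (s - s_min) / (s_max - s_min)


def bacc_mcc_oracle(scores, labels, threshold=0.5):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = 1 if s >= threshold else 0
        if pred == 1 and y == 1:
            tp += 1
        elif pred == 1 and y == 0:
            fp += 1
        elif pred == 0 and y == 0:
            tn += 1
        else:
            fn += 1
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    denom = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return (sens + spec) / 2.0, mcc


def wilcoxon_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all 2^n sign patterns."""
    d = a - b
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    stats = np.asarray(stats)
    tol = 1e-9
    p_le = np.mean(stats <= w_obs + tol)
    p_ge = np.mean(stats >= w_obs - tol)
    return min(1.0, 2.0 * min(p_le, p_ge))


def random_case(rng, max_n=60, ties=True):
    n = int(rng.integers(6, max_n))
    scores = rng.random(n)
    if ties and rng.random() < 0.5:
        scores = np.round(scores, int(rng.integers(1, 3)))
    labels = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels


# ---------------------------------------------------------------------------
# example-based tests
# ---------------------------------------------------------------------------


def test_auc_examples():
    assert M.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert M.auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0
    assert M.auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5


def test_delta_auc_pr_examples():
    # perfect ranking with 2 pos / 2 neg: AUC-PR 1, baseline 0.5
    assert M.delta_auc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(0.5)
    # constant scorer: precision = base rate everywhere
    assert M.delta_auc_pr([0.3] * 6, [1, 0, 0, 1, 0, 0]) == pytest.approx(0.0)


def test_bedroc_endpoints():
    scores = np.linspace(1, 0, 40)
    labels = np.zeros(40, dtype=int)
    labels[:8] = 1  # perfect ranking
    assert M.bedroc(scores, labels) == pytest.approx(1.0, abs=1e-9)
    assert M.bedroc(scores, labels[::-1]) == pytest.approx(0.0, abs=1e-9)


def test_bedroc_matches_rdkit_closed_form_without_ties():
    """Cross-check against the independent rdkit implementation.

    rdkit uses the continuous-normalization closed form, which differs
    from discrete min/max scaling by O(alpha/N); compare loosely at
    large N.
    """
    from rdkit.ML.Scoring.Scoring import CalcBEDROC

    rng = np.random.default_rng(5)
    for _ in range(5):
        n = 500
        scores = rng.normal(size=n)
        labels = (rng.random(n) < 0.1).astype(int)
        labels[0] = 1
        labels[1] = 0
        order = np.argsort(-scores)
        ranked = [(scores[i], labels[i]) for i in order]
        ref = CalcBEDROC(ranked, 1, 20.0)
        assert M.bedroc(scores, labels, 20.0) == pytest.approx(ref, abs=0.01)


def test_bacc_mcc_examples():
    bacc, mcc = M.bacc_mcc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert bacc == 1.0 and mcc == 1.0
    # all predicted positive: degenerate confusion column
    bacc, mcc = M.bacc_mcc([0.9, 0.9, 0.9, 0.9], [1, 1, 0, 0])
    assert bacc == 0.5 and mcc == 0.0


def test_wilcoxon_all_shifted_example():
    # all ten differences positive: only one of the 2^10 sign patterns is
    # as extreme, so the two-sided exact p is 2 * (1/2^10)
    a = np.arange(10, dtype=float)
    assert M.paired_wilcoxon(a + 1.0, a) == pytest.approx(
        0.001953125, abs=1e-15
    )


def test_wilcoxon_error_conditions():
    a = np.arange(10, dtype=float)
    with pytest.raises(AllZeroDifferences):
        M.paired_wilcoxon(a, a)
    with pytest.raises(TooFewPairs):
        M.paired_wilcoxon(a[:4] + 1, a[:4])


def test_one_class_only_raises():
    for fn in (M.auc, M.delta_auc_pr, M.bedroc):
        with pytest.raises(OneClassOnly):
            fn([0.1, 0.9], [1, 1])


# ---------------------------------------------------------------------------
# oracle comparisons and properties (smaller n than the acceptance sweep)
# ---------------------------------------------------------------------------


def test_metrics_match_oracles_on_random_cases():
    rng = np.random.default_rng(77)
    for _ in range(200):
        scores, labels = random_case(rng)
        assert M.auc(scores, labels) == pytest.approx(
            auc_oracle(scores, labels), abs=1e-12
        )
        assert M.delta_auc_pr(scores, labels) == pytest.approx(
            auc_pr_oracle(scores, labels) - labels.mean(), abs=1e-12
        )
        alpha = float(rng.uniform(2, 40))
        assert M.bedroc(scores, labels, alpha) == pytest.approx(
            bedroc_oracle(scores, labels, alpha), abs=1e-10
        )
        bacc, mcc = M.bacc_mcc(scores, labels)
        ob, om = bacc_mcc_oracle(scores, labels)
        assert bacc == pytest.approx(ob, abs=1e-12)
        assert mcc == pytest.approx(om, abs=1e-12)


def test_wilcoxon_exact_matches_enumeration_small_n():
    rng = np.random.default_rng(88)
    for _ in range(60):
        n = int(rng.integers(5, 13))
        a = rng.normal(size=n)
        b = a + rng.normal(scale=0.8, size=n)
        if rng.random() < 0.4:  # force ties in |d|
            b = a + np.round(rng.normal(scale=1.0, size=n), 0)
        if np.all(a - b == 0):
            continue
        if np.sum(a - b != 0) < 5:
            continue
        assert M.paired_wilcoxon(a, b) == pytest.approx(
            wilcoxon_enumeration_oracle(a, b), abs=1e-12
        )


def test_wilcoxon_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(99)
    for _ in range(20):
        n = int(rng.integers(6, 20))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        ours = M.paired_wilcoxon(a, b)
        ref = wilcoxon(a, b, method="exact", alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


def test_auc_complement_and_monotone_invariance():
    rng = np.random.default_rng(11)
    for _ in range(20):
        scores = rng.normal(size=30)  # continuous => no ties
        labels = (rng.random(30) < 0.4).astype(int)
        if labels.min() == labels.max():
            continue
        assert M.auc(scores, labels) + M.auc(-scores, labels) == pytest.approx(1.0)
        # strictly monotone transform leaves ranking metrics unchanged
        t = np.exp(scores / 2.0)
        assert M.auc(t, labels) == pytest.approx(M.auc(scores, labels))
        assert M.delta_auc_pr(t, labels) == pytest.approx(
            M.delta_auc_pr(scores, labels)
        )
        assert M.bedroc(t, labels) == pytest.approx(M.bedroc(scores, labels))


def test_bedroc_approaches_uniform_weighting_at_small_alpha():
    rng = np.random.default_rng(13)
    scores = rng.normal(size=200)
    labels = (rng.random(200) < 0.3).astype(int)
    # at tiny alpha BEDROC and AUC order test cases the same way
    cases = [(rng.normal(size=200), labels) for _ in range(5)]
    aucs = [M.auc(s, l) for s, l in cases]
    beds = [M.bedroc(s, l, alpha=0.01) for s, l in cases]
    assert np.argsort(aucs).tolist() == np.argsort(beds).tolist()
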