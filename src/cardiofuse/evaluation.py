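"""Classification metrics with uncertainty: AUROC (Mann-Whitney form),
confusion-matrix metrics, percentile-bootstrap confidence intervals, the
fast DeLong test for correlated AUROCs, and the Wilcoxon signed-rank test
(exact for small samples).

Conventions: the abnormal class is positive; a score >= 0.5 predicts
abnormal; recall is computed on the abnormal class and specificity on the
normal class. Bootstrap intervals resample at the sample level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.stats import norm, rankdata


@dataclass
class MetricReport:
    accuracy: float
    auroc: float
    precision: float
    recall: float
    specificity: float
    n: int
    positive_class: str = "abnormal"

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "auroc": self.auroc,
                "precision": self.precision, "recall": self.recall,
                "specificity": self.specificity, "n": self.n}


@dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    mean: float
    iterations: int = 100
    level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower CI bound exceeds upper")


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=np.float64).ravel()
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    return y


def auroc(labels, scores) -> float:
    """AUROC as the Mann-Whitney pair statistic:
    (concordant + 0.5 * tied) / (n_pos * n_neg), computed via midranks."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if s.shape != y.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    ranks = rankdata(s)  # midranks handle ties exactly
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metric_report(labels, scores, threshold: float = 0.5) -> MetricReport:
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    pred = (s >= threshold).astype(float)
    tp = float(np.sum((pred == 1) & (y == 1)))
    tn = float(np.sum((pred == 0) & (y == 0)))
    fp = float(np.sum((pred == 1) & (y == 0)))
    fn = float(np.sum((pred == 0) & (y == 1)))
    return MetricReport(
        accuracy=(tp + tn) / y.size,
        auroc=auroc(y, s),
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn),
        specificity=tn / (tn + fp),
        n=int(y.size))


def bootstrap_ci(labels, scores, metric, iterations: int = 100,
                 level: float = 0.95, seed: int = 0,
                 max_redraws: int = 1000) -> BootstrapCI:
    """Percentile bootstrap CI for ``metric(labels, scores)``.

    Resamples indices with replacement; a resample missing one of the
    classes is redrawn. The point estimate is computed on the original
    sample and the reported ``mean`` over bootstrap replicates.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    point = float(metric(y, s))
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(iterations):
        for _ in range(max_redraws):
            idx = rng.integers(0, y.size, y.size)
            if 0 < y[idx].sum() < y.size:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        stats.append(float(metric(y[idx], s[idx])))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return BootstrapCI(point=point, lower=float(lo), upper=float(hi),
                       mean=float(np.mean(stats)), iterations=iterations,
                       level=level, seed=seed)


def _placements(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values via midranks.

    V10[i] = fraction of negatives scored below positive i (ties 0.5);
    V01[j] = fraction of positives scored above negative j (ties 0.5).
    """
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = all_ranks[:m], all_ranks[m:]
    v10 = (pos_ranks - rankdata(pos)) / n
    v01 = 1.0 - (neg_ranks - rankdata(neg)) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def delong_test(labels, scores_a, scores_b) -> DeLongResult:
    """DeLong's test for two correlated AUROCs on paired scores.

    Uses the fast midrank placement-value formulation; the two-sided
    p-value comes from a z-test on the AUC difference. Degenerate zero
    variance with equal AUCs yields p = 1.
    """
    y = _check_binary(labels)
    sa = np.asarray(scores_a, dtype=np.float64).ravel()
    sb = np.asarray(scores_b, dtype=np.float64).ravel()
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValueError("scores must be paired with labels (equal lengths)")
    v10a, v01a, auc_a = _placements(y, sa)
    v10b, v01b, auc_b = _placements(y, sb)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p=float(min(p, 1.0)))


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired observations.

    Zero differences are dropped. With <= 12 non-zero differences the exact
    null distribution is enumerated over all 2^n sign assignments (valid
    under ties); larger samples use the normal approximation with tie
    correction and continuity correction. All differences zero -> p = 1.
    """
    a = np.asarray(paired_a, dtype=np.float64).ravel()
    b = np.asarray(paired_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 12:
        # exact: distribution of W+ over all sign flips of the observed ranks
        total = 2 ** n
        obs_dev = abs(w_plus - n * (n + 1) / 4)
        count = 0
        for signs in product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - n * (n + 1) / 4) >= obs_dev - 1e-12:
                count += 1
        return count / total
    mean = n * (n + 1) / 4.0
    # tie correction on the rank variance
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def significance_stars(p: float) -> str:
    """Star banding: ns, *, **, ***, **** at 5e-2, 1e-2, 1e-3, 1e-4."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"
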