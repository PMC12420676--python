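"""Grade-level statistics: ROC/AUC, Youden cutpoint, one-way ANOVA + Tukey.

AUC is the normalized pairwise concordance P(score_pos > score_neg) +
0.5 P(tie); the Youden threshold maximizes J = sensitivity + specificity - 1
over midpoints of adjacent distinct scores plus the two infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    J: float
    sensitivity: float
    specificity: float
    auc: float

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "J": self.J,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: list  # rows (group_i, group_j, mean_diff, adjusted_p)
    degenerate: bool = False  # all groups constant but means differ

    def as_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
            "degenerate": self.degenerate,
            "tukey": [
                {"group_i": i, "group_j": j, "mean_diff": d, "adjusted_p": p}
                for (i, j, d, p) in self.tukey
            ],
        }


def _as_binary(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype == bool:
        return lab
    if lab.dtype.kind in "iuf":
        return lab != 0
    return lab == "G3"


def roc_auc(scores, binary_labels) -> float:
    """Rank-based AUC with half-credit for ties (Mann-Whitney form)."""
    scores = np.asarray(scores, dtype=float)
    pos = _as_binary(binary_labels)
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_threshold(scores, binary_labels) -> ThresholdResult:
    """Exhaustive Youden-J cutpoint; positive means score > threshold.

    Candidates are -inf, midpoints of adjacent distinct scores, +inf; a J
    tie returns the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _as_binary(binary_labels)
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    u = np.unique(scores)
    cand = np.concatenate(([-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]))
    # counts with score > t, per candidate (scores sorted ascending)
    tp = np.array([(scores[pos] > t).sum() for t in cand], dtype=float)
    fp = np.array([(scores[~pos] > t).sum() for t in cand], dtype=float)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    J = sens + spec - 1.0
    best = int(np.argmax(J > J.max() - 1e-12))  # first (smallest) maximizer
    return ThresholdResult(
        threshold=float(cand[best]),
        J=float(J[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        auc=roc_auc(scores, pos),
    )


def grade_binary_eval(scores, grades, high_grades=(3, 4)) -> ThresholdResult:
    """Low (G1/G2) vs high (G3/G4) discrimination by a profile score."""
    grades = np.asarray(grades, dtype=int)
    if not np.isin(grades, (1, 2, 3, 4)).all():
        raise ValueError("grades must be in {1, 2, 3, 4}")
    high = np.isin(grades, high_grades)
    if high.all() or not high.any():
        raise ValueError("need both low- and high-grade samples")
    return youden_threshold(np.asarray(scores, dtype=float), high)


def bootstrap_auc_se(scores, binary_labels, n_boot: int = 1000, seed: int = 0) -> float:
    """Seeded nonparametric bootstrap standard error of the AUC."""
    scores = np.asarray(scores, dtype=float)
    pos = _as_binary(binary_labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        p = pos[idx]
        if p.all() or not p.any():
            continue
        vals.append(roc_auc(scores[idx], p))
    return float(np.std(vals, ddof=1))


def anova_tukey(values_by_group) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD adjusted pairwise p-values.

    ``values_by_group`` is a sequence of 1-D arrays (>= 2 groups, each with
    n >= 2).  When every group is constant, F is 0/p = 1 if the means agree
    and p = 0 with the ``degenerate`` flag set if they differ.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, N - k
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if ss_within == 0.0:
        if ss_between == 0.0:
            tukey = [(i, j, 0.0, 1.0) for i, j in pairs]
            return AnovaResult(0.0, df_b, df_w, 1.0, tukey)
        tukey = [
            (i, j, float(means[j] - means[i]), 0.0 if means[i] != means[j] else 1.0)
            for i, j in pairs
        ]
        return AnovaResult(float("inf"), df_b, df_w, 0.0, tukey, degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    res = stats.tukey_hsd(*groups)
    tukey = [
        (i, j, float(means[j] - means[i]), float(res.pvalue[i, j])) for i, j in pairs
    ]
    return AnovaResult(float(F), df_b, df_w, p, tukey)


def boxplot_stats(values) -> dict:
    """Numeric boxplot summary (median, quartiles, 5-95 percentiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty values")
    q = np.percentile(v, [5, 25, 50, 75, 95])
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "p5": float(q[0]),
        "q1": float(q[1]),
        "median": float(q[2]),
        "q3": float(q[3]),
        "p95": float(q[4]),
    }
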