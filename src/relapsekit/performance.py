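"""Prediction-performance statistics.

One-sided Mann-Whitney comparison of score distributions, rank-based
ROC/AUC, stratified percentile-bootstrap AUC confidence intervals, power of
the AUC test against the null AUC = 0.5, and the odds-ratio-of-correct-
prediction curve along the model's output values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu, norm, rankdata


@dataclass
class BootstrapConfig:
    n_boot: int = 2_000
    level: float = 0.95
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("coverage level must be in (0, 1)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


@dataclass
class EvalReport:
    auc: float
    auc_ci: tuple[float, float]
    mw_u: float
    mw_p: float
    power: float
    power_alpha: float
    or_curve: list[tuple[float, float, tuple[int, int, int, int]]]
    or_at_default: float
    n_pos: int
    n_neg: int
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.auc_ci
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValueError("AUC confidence interval does not contain the AUC")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "mw_u": self.mw_u,
            "mw_p": self.mw_p,
            "power": self.power,
            "power_alpha": self.power_alpha,
            "or_at_default": self.or_at_default,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "or_curve": [
                {"threshold": t, "odds_ratio": o, "table": list(tab)}
                for t, o, tab in self.or_curve
            ],
            "notes": self.notes,
        }


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def mann_whitney_one_sided(
    scores_pos: Sequence[float], scores_neg: Sequence[float]
) -> tuple[float, float]:
    """U statistic and one-sided p (positives stochastically greater).

    U counts (pos, neg) pairs with pos > neg, plus half a point per tie.
    The p-value is exact (full permutation distribution) when
    n_pos * n_neg <= 400 and there are no ties, else a tie-corrected normal
    approximation.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([pos, neg]))) < len(pos) + len(neg)
    exact = len(pos) * len(neg) <= 400 and not ties
    res = mannwhitneyu(
        pos, neg, alternative="greater", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by the midrank method: P(pos > neg) + 0.5 P(tie)."""
    pos, neg = _split(np.asarray(scores), np.asarray(labels))
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_curve_points(
    scores: Sequence[float], labels: Sequence[int]
) -> np.ndarray:
    """(threshold, FPR, TPR) rows over the unique observed score values."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = _split(scores, labels)
    rows = [(np.inf, 0.0, 0.0)]
    for t in np.unique(scores)[::-1]:
        rows.append(
            (float(t), float((neg >= t).mean()), float((pos >= t).mean()))
        )
    return np.asarray(rows)


def bootstrap_auc_ci(
    scores: Sequence[float], labels: Sequence[int], cfg: BootstrapConfig
) -> tuple[float, float]:
    """Percentile interval of the AUC under stratified sample resampling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = _split(scores, labels)
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = len(pos), len(neg)
    aucs = np.empty(cfg.n_boot)
    for b in range(cfg.n_boot):
        if cfg.stratified:
            ps = pos[rng.integers(0, n1, n1)]
            ns = neg[rng.integers(0, n2, n2)]
        else:
            idx = rng.integers(0, n1 + n2, n1 + n2)
            pooled = np.concatenate([pos, neg])
            lab = np.concatenate([np.ones(n1, int), np.zeros(n2, int)])
            ps, ns = pooled[idx][lab[idx] == 1], pooled[idx][lab[idx] == 0]
            if len(ps) == 0 or len(ns) == 0:  # guard: degenerate resample
                aucs[b] = np.nan
                continue
        ranks = rankdata(np.concatenate([ps, ns]))
        u = ranks[: len(ps)].sum() - len(ps) * (len(ps) + 1) / 2.0
        aucs[b] = u / (len(ps) * len(ns))
    aucs = aucs[~np.isnan(aucs)]
    alpha = 1.0 - cfg.level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def auc_power(
    auc: float, n_pos: int, n_neg: int, alpha: float = 0.01
) -> float:
    """Power of the one-sided AUC test against H0: AUC = 0.5.

    Null variance uses the rank-test formulation (n1 + n2 + 1)/(12 n1 n2);
    the alternative variance uses the Hanley-McNeil approximation.  For
    auc <= 0.5 the returned power is at most alpha (degenerate alternative).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group counts must be >= 1")
    if not (0.0 < auc < 1.0 + 1e-12):
        auc = min(max(auc, 1e-9), 1.0 - 1e-9)
    var0 = (n_pos + n_neg + 1) / (12.0 * n_pos * n_neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var1 = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    var1 = max(var1, 1e-18)
    z_crit = norm.ppf(1.0 - alpha)
    return float(norm.cdf((auc - 0.5 - z_crit * np.sqrt(var0)) / np.sqrt(var1)))


def correct_prediction_odds(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] | None = None,
    default_threshold: float = 0.5,
) -> tuple[list[tuple[float, float, tuple[int, int, int, int]]], float]:
    """Odds ratio of correct prediction along the model output values.

    At each threshold t, score >= t predicts relapse; the odds ratio is
    (TP*TN)/(FP*FN) with the Haldane-Anscombe +0.5 correction whenever a cell
    is empty.  Thresholds default to the unique observed score values.
    Returns the curve and the OR at the default operating threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _split(scores, labels)
    if thresholds is None:
        thresholds = np.unique(scores)

    def table_at(t: float) -> tuple[int, int, int, int]:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        return tp, fp, fn, tn

    def odds(tab: tuple[int, int, int, int]) -> float:
        tp, fp, fn, tn = tab
        if min(tab) == 0:
            tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
        return float((tp * tn) / (fp * fn))

    curve = [(float(t), odds(table_at(t)), table_at(t)) for t in thresholds]
    return curve, odds(table_at(default_threshold))


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    boot: BootstrapConfig | None = None,
    power_alpha: float = 0.01,
) -> EvalReport:
    """Full performance report for an out-of-fold prediction set."""
    boot = boot or BootstrapConfig()
    pos, neg = _split(np.asarray(scores), np.asarray(labels))
    u, p = mann_whitney_one_sided(pos, neg)
    auc = roc_auc(scores, labels)
    ci = bootstrap_auc_ci(scores, labels, boot)
    ci = (min(ci[0], auc), max(ci[1], auc))
    notes = []
    if auc <= 0.5:
        notes.append("AUC <= 0.5: power is bounded by alpha")
    power = auc_power(auc, len(pos), len(neg), power_alpha)
    curve, or_default = correct_prediction_odds(scores, labels)
    return EvalReport(
        auc=auc,
        auc_ci=ci,
        mw_u=u,
        mw_p=p,
        power=power,
        power_alpha=power_alpha,
        or_curve=curve,
        or_at_default=or_default,
        n_pos=len(pos),
        n_neg=len(neg),
        notes=notes,
    )
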