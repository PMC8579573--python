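"""Per-residue and per-peptide evaluation metrics, ROC/AUC, and the
Friedman + Nemenyi multi-method comparison.

Hotspot prediction is evaluated per residue: TP counts hotspot residues
predicted hotspot, FP regular residues predicted hotspot, and so on. The
headline summary is the balanced accuracy Q = (SE + SP)/2, preferred over
ACC because hotspot residues are rare — an all-negative prediction can
beat a good one on ACC but never on Q.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, studentized_range
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ConfusionCounts:
    """A binary confusion table (counts of residues or peptides)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    """ACC, SE, SP, Q = (SE+SP)/2 and MCC, with an optional AUC."""

    acc: float
    se: float
    sp: float
    q: float
    mcc: float
    auc: Optional[float] = None

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Report values rounded half-up to ``ndigits`` decimals.

        Half-up (0.8125 -> 0.813) rather than banker's rounding, matching
        how such tables are conventionally printed.
        """
        out = {k: round3(v, ndigits) for k, v in
               (("acc", self.acc), ("se", self.se), ("sp", self.sp),
                ("q", self.q), ("mcc", self.mcc))}
        if self.auc is not None:
            out["auc"] = round3(self.auc, ndigits)
        return out


def round3(x: float, ndigits: int = 3) -> float:
    """Round half-up to ``ndigits`` decimals."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(exp, rounding=ROUND_HALF_UP))


def _as_mask(predicted, length: int) -> np.ndarray:
    """Accept a 0/1 mask or a list of 1-based inclusive intervals."""
    arr = np.asarray(predicted)
    if arr.ndim == 1 and arr.size == length and set(np.unique(arr)) <= {0, 1}:
        return arr.astype(int)
    mask = np.zeros(length, dtype=int)
    for start, end in predicted:
        if not (1 <= start <= end <= length):
            raise ValueError(f"interval ({start}, {end}) outside [1, {length}]")
        mask[start - 1:end] = 1
    return mask


def residue_confusion(truth, predicted, length: int) -> ConfusionCounts:
    """Per-residue confusion between a truth annotation and a prediction.

    ``truth`` is a :class:`~amyloscan.io.HotspotAnnotation`, a list of
    1-based inclusive intervals, or a 0/1 mask of ``length``; likewise
    ``predicted``.
    """
    if hasattr(truth, "mask"):
        t = np.asarray(truth.mask(length))
    else:
        t = _as_mask(truth, length)
    p = _as_mask(predicted, length)
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """ACC, SE, SP, Q and MCC from a confusion table.

    Conventions for degenerate tables: SE (SP) is 0 when no positives
    (negatives) were evaluated; MCC is 0 when any factor of its
    denominator is 0. An all-zero table is an error.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = (c.tp + c.tn) / c.total
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    q = (se + sp) / 2
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / sqrt(denom) if denom else 0.0
    return MetricsReport(acc=acc, se=se, sp=sp, q=q, mcc=mcc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """AUC (rank/trapezoid with half-credit for ties) plus ROC points.

    Returns ``(auc, points)`` where points is a DataFrame with columns
    fpr, tpr, threshold. Requires both classes.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class RankMatrix:
    """Per-item rankings of competing methods (rank 1 = best; ties mid-ranked)."""

    methods: list[str]
    items: list[str]
    ranks: np.ndarray  # shape (n_methods, n_items)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.shape != (len(self.methods), len(self.items)):
            raise ValueError("ranks shape must be (n_methods, n_items)")


def rank_methods(performance: pd.DataFrame, higher_better: bool = True) -> RankMatrix:
    """Mid-rank methods (rows) per item (columns) from a performance table."""
    scores = performance.to_numpy(dtype=float)
    sign = -1.0 if higher_better else 1.0
    ranks = pd.DataFrame(sign * scores).rank(axis=0, method="average").to_numpy()
    return RankMatrix(methods=list(performance.index),
                      items=[str(c) for c in performance.columns], ranks=ranks)


@dataclass
class FriedmanNemenyiResult:
    statistic: float
    pvalue: float
    rejected: bool
    critical_difference: float
    mean_ranks: pd.Series
    significant: pd.DataFrame  # boolean method x method matrix


def nemenyi_critical_difference(k: int, n: int, alpha: float = 0.1) -> float:
    """Nemenyi CD = q_alpha * sqrt(k(k+1) / (6n)).

    q_alpha is the two-tailed studentized-range critical value at level
    alpha for k groups (infinite df), divided by sqrt(2).
    """
    q_alpha = studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2)
    return float(q_alpha * np.sqrt(k * (k + 1) / (6 * n)))


def friedman_nemenyi(ranks: RankMatrix, alpha: float = 0.1) -> FriedmanNemenyiResult:
    """Friedman test across methods, Nemenyi post hoc on rejection.

    The Friedman chi-square uses tie-corrected mid-ranks. When the null of
    equal performance is rejected at ``alpha``, every method pair whose
    mean-rank difference exceeds the Nemenyi critical difference is
    flagged significant. A degenerate matrix (identical ranks everywhere)
    yields statistic 0 and no rejection.
    """
    k, n = ranks.ranks.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 methods and 2 items")
    # re-rank within each item so arbitrary (but ordered) inputs also work
    r = pd.DataFrame(ranks.ranks).rank(axis=0, method="average").to_numpy()
    mean_ranks = pd.Series(r.mean(axis=1), index=ranks.methods)
    cd = nemenyi_critical_difference(k, n, alpha)
    # tie-corrected Friedman statistic (Conover form):
    #   chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C),
    # A = sum of squared ranks, C = n k (k+1)^2 / 4; equals the classic
    # statistic with the standard tie-correction factor.
    R = r.sum(axis=1)
    A = float((r ** 2).sum())
    C = n * k * (k + 1) ** 2 / 4.0
    if A - C <= 0:  # everything tied: no evidence of any difference
        sig = pd.DataFrame(False, index=ranks.methods, columns=ranks.methods)
        return FriedmanNemenyiResult(0.0, 1.0, False, cd, mean_ranks, sig)
    stat = (k - 1) * float(((R - n * (k + 1) / 2.0) ** 2).sum()) / (A - C)
    pvalue = float(chi2.sf(stat, k - 1))
    rejected = bool(pvalue < alpha)
    diff = np.abs(mean_ranks.to_numpy()[:, None] - mean_ranks.to_numpy()[None, :])
    sig_vals = rejected & (diff > cd)
    np.fill_diagonal(sig_vals, False)
    sig = pd.DataFrame(sig_vals, index=ranks.methods, columns=ranks.methods)
    return FriedmanNemenyiResult(float(stat), pvalue, rejected, cd,
                                 mean_ranks, sig)


def pooled_residue_metrics(truths: dict, predictions: dict,
                           lengths: dict[str, int]) -> MetricsReport:
    """Pool per-residue confusion over many proteins and compute metrics.

    ``truths`` and ``predictions`` map protein id -> intervals/mask;
    proteins present in ``truths`` but missing from ``predictions`` count
    as all-negative predictions.
    """
    missing = set(truths) - set(lengths)
    if missing:
        raise ValueError(f"no length for protein(s): {sorted(missing)}")
    total = ConfusionCounts(0, 0, 0, 0)
    for pid, truth in truths.items():
        pred = predictions.get(pid, [])
        total = total + residue_confusion(truth, pred, lengths[pid])
    return compute_metrics(total)
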