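"""Binomial-distribution ranking and selection of discriminative tripeptides.

For each of the 8000 tripeptides, occurrences are counted over all
overlapping windows of the positive (amyloidogenic) and negative classes.
With N_i the total occurrences of tripeptide i and n_ij its occurrences in
class j, the probability of seeing at least n_ij of N_i trials in class j
under a random split with class token share q_j is the binomial upper tail

    P_ij = sum_{k = n_ij}^{N_i} C(N_i, k) q_j^k (1 - q_j)^(N_i - k),

and the confidence level of the tripeptide is CL_i = max_j (1 - P_ij):
how non-random its class distribution is. Tripeptides are ranked by CL
(descending) and the feature set keeps either all above a CL threshold or
the top k; a small cross-validated search around the threshold picks the
final cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import N_TRIPEPTIDES
from .encoders import (PseAACParams, index_to_tripeptide, tpc_vector,
                       tripeptide_counts, tripeptide_index)
from .io import PeptideRecord
from .scales import PropertyScale, standardize_scale

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Per-class tripeptide occurrence counts and class token shares."""

    counts_pos: np.ndarray  # (8000,) occurrences in class 1
    counts_neg: np.ndarray  # (8000,) occurrences in class 0
    q_pos: float
    q_neg: float

    @property
    def counts_total(self) -> np.ndarray:
        return self.counts_pos + self.counts_neg


@dataclass
class TripeptideStats:
    """Binomial statistics of one tripeptide."""

    tripeptide: str
    count_pos: int
    count_neg: int
    p_pos: float
    p_neg: float

    @property
    def count_total(self) -> int:
        return self.count_pos + self.count_neg

    @property
    def cl(self) -> float:
        """Confidence level: 1 minus the smaller of the two tail probabilities."""
        return 1.0 - min(self.p_pos, self.p_neg)


@dataclass
class FeatureSpec:
    """The frozen feature layout of a trained model.

    PseAAC block first (20 + n_scales*lambda components), then the selected
    tripeptides' TPC components in descending-CL order.
    """

    selected_tripeptides: list[str]
    pseaac_params: PseAACParams = field(default_factory=PseAACParams)

    def __post_init__(self) -> None:
        if len(set(self.selected_tripeptides)) != len(self.selected_tripeptides):
            raise ValueError("selected tripeptides must be duplicate-free")

    @property
    def total_dim(self) -> int:
        return self.pseaac_params.dim + len(self.selected_tripeptides)

    def selected_indices(self) -> np.ndarray:
        return np.array([tripeptide_index(t) for t in self.selected_tripeptides],
                        dtype=np.intp)

    def to_file(self, path: str | Path) -> None:
        from .alphabet import AMINO_ACIDS
        p = self.pseaac_params
        with open(path, "w") as fh:
            fh.write("#amyloscan-feature-spec\tv1\n")
            fh.write(f"lambda\t{p.lambda_rank}\n")
            fh.write(f"weight\t{p.weight!r}\n")
            fh.write(f"count_mode\t{p.count_mode}\n")
            for s in p.scales:
                vals = " ".join(repr(s.raw[aa]) for aa in AMINO_ACIDS)
                fh.write(f"scale\t{s.name}\t{vals}\n")
            for t in self.selected_tripeptides:
                fh.write(f"tripeptide\t{t}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureSpec":
        from .alphabet import AMINO_ACIDS
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#amyloscan-feature-spec"):
            raise ValueError(f"{path}: not a feature-spec file")
        kv: dict[str, str] = {}
        scales: list[PropertyScale] = []
        tripeptides: list[str] = []
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "scale":
                raw = dict(zip(AMINO_ACIDS, map(float, parts[2].split())))
                scales.append(standardize_scale(raw, parts[1]))
            elif parts[0] == "tripeptide":
                tripeptides.append(parts[1])
            else:
                kv[parts[0]] = parts[1]
        params = PseAACParams(
            lambda_rank=int(kv["lambda"]),
            weight=float(kv["weight"]),
            scales=scales,
            count_mode=kv.get("count_mode", "count"),  # type: ignore[arg-type]
        )
        return cls(selected_tripeptides=tripeptides, pseaac_params=params)


def count_tripeptides(dataset: Sequence[PeptideRecord]) -> CountTable:
    """Per-class occurrence counts over all overlapping tripeptide windows.

    ``q_j`` is the ratio of tripeptide tokens in class j to tokens overall.
    Both classes must be present.
    """
    if not dataset:
        raise ValueError("empty dataset")
    counts = {0: np.zeros(N_TRIPEPTIDES), 1: np.zeros(N_TRIPEPTIDES)}
    for rec in dataset:
        if rec.label not in (0, 1):
            raise ValueError(f"record {rec.id!r} has no binary label")
        counts[rec.label] += tripeptide_counts(rec.sequence)
    tokens_pos = counts[1].sum()
    tokens_neg = counts[0].sum()
    if tokens_pos == 0 or tokens_neg == 0:
        raise ValueError("both classes required in the dataset")
    total = tokens_pos + tokens_neg
    return CountTable(counts_pos=counts[1], counts_neg=counts[0],
                      q_pos=tokens_pos / total, q_neg=tokens_neg / total)


def binomial_tail(n: int, N: int, q: float) -> float:
    """Upper binomial tail sum_{k=n}^{N} C(N,k) q^k (1-q)^(N-k)."""
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0,1), got {q}")
    if n < 0 or N < 0 or n > N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    return float(binom.sf(n - 1, N, q))


def confidence_levels(counts: CountTable) -> list[TripeptideStats]:
    """Binomial statistics for all 8000 tripeptides.

    A tripeptide never observed (N_i = 0) carries no evidence and gets
    CL = 0 (its tails are set to 1).
    """
    n_pos = counts.counts_pos.astype(int)
    n_neg = counts.counts_neg.astype(int)
    N = n_pos + n_neg
    p_pos = np.ones(N_TRIPEPTIDES)
    p_neg = np.ones(N_TRIPEPTIDES)
    seen = N > 0
    p_pos[seen] = binom.sf(n_pos[seen] - 1, N[seen], counts.q_pos)
    p_neg[seen] = binom.sf(n_neg[seen] - 1, N[seen], counts.q_neg)
    return [
        TripeptideStats(
            tripeptide=index_to_tripeptide(i),
            count_pos=int(n_pos[i]),
            count_neg=int(n_neg[i]),
            p_pos=float(p_pos[i]),
            p_neg=float(p_neg[i]),
        )
        for i in range(N_TRIPEPTIDES)
    ]


def rank_tripeptides(stats: Iterable[TripeptideStats]) -> list[TripeptideStats]:
    """Deterministic ranking: CL desc, then total count desc, then alphabetical."""
    return sorted(stats, key=lambda s: (-s.cl, -s.count_total, s.tripeptide))


SelectionMode = Literal["threshold", "top_k"]


def rank_and_select(stats: Iterable[TripeptideStats], mode: SelectionMode,
                    value: float | int,
                    pseaac_params: PseAACParams | None = None) -> FeatureSpec:
    """Select the discriminative tripeptide subset.

    ``mode="threshold"`` keeps every tripeptide with CL >= value (the
    headline cutoff is 0.85); ``mode="top_k"`` keeps the first k of the
    ranked list.
    """
    ranked = rank_tripeptides(stats)
    if mode == "threshold":
        if not 0 <= value <= 1:
            raise ValueError(f"threshold must be in [0,1], got {value}")
        chosen = [s for s in ranked if s.cl >= value]
    elif mode == "top_k":
        k = int(value)
        if not 0 <= k <= N_TRIPEPTIDES:
            raise ValueError(f"top_k must be in [0, {N_TRIPEPTIDES}], got {k}")
        chosen = ranked[:k]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return FeatureSpec(
        selected_tripeptides=[s.tripeptide for s in chosen],
        pseaac_params=pseaac_params or PseAACParams(),
    )


def stats_report(stats: Iterable[TripeptideStats]) -> pd.DataFrame:
    """Ranked-feature report: tripeptide, per-class counts, N, CL, rank."""
    ranked = rank_tripeptides(stats)
    return pd.DataFrame(
        {
            "tripeptide": [s.tripeptide for s in ranked],
            "n_pos": [s.count_pos for s in ranked],
            "n_neg": [s.count_neg for s in ranked],
            "N": [s.count_total for s in ranked],
            "CL": [s.cl for s in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )


def class_content(counts: CountTable) -> pd.DataFrame:
    """Per-class tripeptide content: n(t, class) / tripeptide tokens in class."""
    tokens_pos = counts.counts_pos.sum()
    tokens_neg = counts.counts_neg.sum()
    return pd.DataFrame(
        {
            "tripeptide": [index_to_tripeptide(i) for i in range(N_TRIPEPTIDES)],
            "content_pos": counts.counts_pos / tokens_pos,
            "content_neg": counts.counts_neg / tokens_neg,
        }
    )


def candidate_cutoffs(stats: Iterable[TripeptideStats], lo: float = 0.80,
                      hi: float = 0.90, max_candidates: int = 20) -> list[int]:
    """Candidate top-k ranks whose boundary CL falls inside [lo, hi].

    The ranked CL list is scanned for ranks whose CL lies in the band
    around the working threshold; at most ``max_candidates`` evenly spaced
    ranks are returned (always including the band edges).
    """
    ranked = rank_tripeptides(stats)
    in_band = [k for k, s in enumerate(ranked, start=1) if lo <= s.cl <= hi]
    if not in_band:
        # no CL in the band: fall back to the last rank above the band, if any
        above = [k for k, s in enumerate(ranked, start=1) if s.cl > hi]
        return [above[-1]] if above else [min(100, len(ranked))]
    if len(in_band) <= max_candidates:
        return in_band
    picks = np.linspace(0, len(in_band) - 1, max_candidates).round().astype(int)
    return sorted({in_band[i] for i in picks})


def tune_cutoff(candidates: Sequence[int], dataset: Sequence[PeptideRecord],
                stats: Iterable[TripeptideStats],
                pseaac_params: PseAACParams | None = None,
                config=None) -> tuple[int, pd.DataFrame]:
    """Cross-validate candidate top-k cutoffs and return the best rank.

    Each candidate k builds a PseAAC + top-k feature set, runs stratified
    k-fold cross-validation with the configured classifier, and the
    candidate maximising pooled accuracy wins (ties go to the smaller k).
    Returns ``(best_k, table)`` with the full per-candidate metric table.
    """
    from .model import TrainingConfig, cross_validate  # deferred: avoids cycle

    if not candidates:
        raise ValueError("no candidate cutoffs")
    config = config or TrainingConfig()
    if config.folds < 2:
        raise ValueError("folds must be >= 2")
    ranked = rank_tripeptides(stats)
    rows = []
    for k in candidates:
        if not 0 <= k <= len(ranked):
            raise ValueError(f"candidate rank {k} out of range")
        spec = FeatureSpec(
            selected_tripeptides=[s.tripeptide for s in ranked[:k]],
            pseaac_params=pseaac_params or PseAACParams(),
        )
        cv = cross_validate(dataset, spec, config)
        rows.append({"k": k, **{m: cv["pooled"][m] for m in
                                ("acc", "se", "sp", "mcc", "auc")}})
    table = pd.DataFrame(rows)
    best = table.sort_values(["acc", "k"], ascending=[False, True]).iloc[0]
    logger.info("tune_cutoff: best k=%d (ACC=%.3f)", int(best["k"]), best["acc"])
    return int(best["k"]), table


class BinomialTripeptideSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn selector: fit learns the discriminative tripeptides,
    transform maps sequences to the selected TPC columns.

    Parameters mirror :func:`rank_and_select` (``mode`` and ``value``).
    Fitted attributes: ``stats_`` (all 8000 tripeptide statistics),
    ``spec_`` (the resulting :class:`FeatureSpec` with an empty-scales
    PseAAC block ignored), ``selected_tripeptides_``.
    """

    def __init__(self, mode: SelectionMode = "threshold", value: float | int = 0.85):
        self.mode = mode
        self.value = value

    def fit(self, X, y):
        y = np.asarray(y)
        records = [
            x if isinstance(x, PeptideRecord)
            else PeptideRecord(id=f"s{i}", sequence=str(x), label=int(y[i]))
            for i, x in enumerate(X)
        ]
        for rec, label in zip(records, y):
            rec.label = int(label)
        counts = count_tripeptides(records)
        self.stats_ = confidence_levels(counts)
        spec = rank_and_select(self.stats_, self.mode, self.value)
        self.selected_tripeptides_ = spec.selected_tripeptides
        self.selected_indices_ = spec.selected_indices()
        return self

    def transform(self, X) -> np.ndarray:
        seqs = [x.sequence if hasattr(x, "sequence") else str(x) for x in X]
        if not seqs:
            return np.empty((0, len(self.selected_tripeptides_)))
        full = np.stack([tpc_vector(s) for s in seqs])
        return full[:, self.selected_indices_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"tpc_{t}" for t in self.selected_tripeptides_],
                          dtype=object)
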