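"""Hexapeptide-window scanning of proteins into per-residue hotspot calls.

Amyloidogenic regions are at least six residues long, so proteins are
scanned with a length-6 window at step 1. Each window is scored by the
trained classifier; a residue is called hotspot when at least one window
covering it is called positive (union rule — the most permissive mapping,
consistent with predicted regions running longer than the annotated core;
a majority-of-covering-windows rule is available as an option). The
per-residue score is the max (optionally mean) score over covering
windows, and maximal runs of positive residues become the reported
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import PeptideRecord
from .model import TrainedModel

WINDOW = 6

AggregateRule = Literal["union", "majority"]
ScoreRule = Literal["max", "mean"]


@dataclass
class WindowPrediction:
    """One scored hexapeptide window (1-based start)."""

    start: int
    sequence: str
    score: float
    call: int


@dataclass
class RegionPrediction:
    """Per-residue hotspot calls for one protein."""

    protein_id: str
    sequence: str
    residue_mask: np.ndarray  # 0/1, length L
    residue_scores: np.ndarray  # per-residue aggregated window score
    regions: list[tuple[int, int]] = field(default_factory=list)
    window_predictions: list[WindowPrediction] = field(default_factory=list)


def enumerate_windows(protein: PeptideRecord) -> list[tuple[int, str]]:
    """All L-5 hexapeptide windows as (1-based start, sequence)."""
    L = len(protein.sequence)
    if L < WINDOW:
        raise ValueError(
            f"protein {protein.id!r} shorter than window: L={L} < {WINDOW}")
    return [(s + 1, protein.sequence[s:s + WINDOW]) for s in range(L - WINDOW + 1)]


def mask_to_regions(mask: Sequence[int]) -> list[tuple[int, int]]:
    """Maximal runs of 1s as 1-based inclusive intervals."""
    regions: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(mask, start=1):
        if v and start is None:
            start = i
        elif not v and start is not None:
            regions.append((start, i - 1))
            start = None
    if start is not None:
        regions.append((start, len(mask)))
    return regions


class HotspotScanner:
    """Applies a trained classifier window-by-window along proteins.

    Parameters
    ----------
    model : TrainedModel
    threshold : decision threshold for window calls; defaults to the
        model's training threshold.
    aggregate : "union" (any positive covering window) or "majority"
        (more than half of covering windows positive).
    score_rule : per-residue score aggregation, "max" (default) or "mean".
    """

    def __init__(self, model: TrainedModel, threshold: float | None = None,
                 aggregate: AggregateRule = "union", score_rule: ScoreRule = "max"):
        self.model = model
        self.threshold = (model.config.decision_threshold
                          if threshold is None else threshold)
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0,1)")
        self.aggregate = aggregate
        self.score_rule = score_rule

    def scan(self, protein: PeptideRecord) -> RegionPrediction:
        windows = enumerate_windows(protein)
        scores = self.model.predict_proba(
            [PeptideRecord(id=f"{protein.id}:{s}", sequence=w)
             for s, w in windows])
        calls = (scores >= self.threshold).astype(int)
        L = len(protein.sequence)
        mask = np.zeros(L, dtype=int)
        res_scores = np.zeros(L)
        n_cover = np.zeros(L, dtype=int)
        pos_cover = np.zeros(L, dtype=int)
        sum_scores = np.zeros(L)
        max_scores = np.zeros(L)
        for (start, _), score, call in zip(windows, scores, calls):
            sl = slice(start - 1, start - 1 + WINDOW)
            n_cover[sl] += 1
            pos_cover[sl] += call
            sum_scores[sl] += score
            np.maximum(max_scores[sl], score, out=max_scores[sl])
        if self.aggregate == "union":
            mask = (pos_cover > 0).astype(int)
        elif self.aggregate == "majority":
            mask = (pos_cover * 2 > n_cover).astype(int)
        else:
            raise ValueError(f"unknown aggregate rule {self.aggregate!r}")
        res_scores = max_scores if self.score_rule == "max" else sum_scores / n_cover
        return RegionPrediction(
            protein_id=protein.id,
            sequence=protein.sequence,
            residue_mask=mask,
            residue_scores=res_scores,
            regions=mask_to_regions(mask),
            window_predictions=[
                WindowPrediction(start=s, sequence=w, score=float(sc), call=int(c))
                for (s, w), sc, c in zip(windows, scores, calls)
            ],
        )

    def classify_peptide(self, peptide: PeptideRecord) -> tuple[int, WindowPrediction]:
        """Peptide-level call: positive iff at least one window is positive.

        Returns the call and the best-scoring window. Peptides shorter
        than the window are rejected.
        """
        pred = self.scan(peptide)
        best = max(pred.window_predictions, key=lambda w: w.score)
        call = int(any(w.call for w in pred.window_predictions))
        return call, best


def scan_protein(protein: PeptideRecord, model: TrainedModel,
                 threshold: float | None = None,
                 aggregate: AggregateRule = "union",
                 score_rule: ScoreRule = "max") -> RegionPrediction:
    """Scan one protein with a trained model (see :class:`HotspotScanner`)."""
    return HotspotScanner(model, threshold, aggregate, score_rule).scan(protein)


def classify_peptide(peptide: PeptideRecord, model: TrainedModel,
                     threshold: float | None = None) -> tuple[int, WindowPrediction]:
    """Binary peptide call via the at-least-one-positive-window rule."""
    return HotspotScanner(model, threshold).classify_peptide(peptide)
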