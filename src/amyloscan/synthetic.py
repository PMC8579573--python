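"""Synthetic labeled hexapeptides and hotspot-annotated proteins.

The generator emulates the structure of curated amyloid datasets with a
known, tunable signal so every pipeline stage can be exercised end to
end: positive hexapeptides carry planted "amyloidogenic" tripeptides and
a hydrophobic composition tilt (more Val/Ile), negatives carry their own
planted tripeptides and a polar tilt (more Asn/Gly/Gln) — mirroring the
enrichment actually observed between amyloidogenic and non-amyloidogenic
hexapeptides. Proteins are background sequence drawn from the negative
composition with positive-style hotspot hexapeptides embedded at recorded
positions, separated by gaps of at least six residues so annotated
regions are unambiguous maximal runs.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_TO_INDEX, AMINO_ACIDS
from .io import HotspotAnnotation, PeptideRecord

DEFAULT_PLANTED_POS = ("VIV", "IVI", "VVI")
DEFAULT_PLANTED_NEG = ("NGQ", "QNG", "GGN")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic datasets.

    ``plant_rate`` is the probability that a sample carries one of its
    class's planted tripeptides; ``composition_bias`` is the log-odds
    boost of V/I in positives and N/G/Q in negatives (0 = uniform
    background, 1.0 = the default, roughly 2.3x enrichment).
    """

    n_pos: int = 200
    n_neg: int = 200
    planted_tripeptides_pos: tuple[str, ...] = DEFAULT_PLANTED_POS
    planted_tripeptides_neg: tuple[str, ...] = DEFAULT_PLANTED_NEG
    plant_rate: float = 0.8
    composition_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.planted_tripeptides_pos) & set(self.planted_tripeptides_neg):
            raise ValueError("planted tripeptide lists must be disjoint")
        if not 0 <= self.plant_rate <= 1:
            raise ValueError("plant_rate must be in [0,1]")
        if self.composition_bias < 0:
            raise ValueError("composition_bias must be >= 0")


def _class_distribution(bias: float, boosted: str) -> np.ndarray:
    """Softmax over uniform log-odds with ``bias`` added to ``boosted`` residues."""
    logits = np.zeros(20)
    for aa in boosted:
        logits[AA_TO_INDEX[aa]] += bias
    p = np.exp(logits)
    return p / p.sum()


def _positive_distribution(config: SyntheticConfig) -> np.ndarray:
    return _class_distribution(config.composition_bias, "VI")


def _negative_distribution(config: SyntheticConfig) -> np.ndarray:
    return _class_distribution(config.composition_bias, "NGQ")


def _draw_hexapeptide(rng: np.random.Generator, dist: np.ndarray,
                      planted: tuple[str, ...], plant_rate: float) -> str:
    residues = list(rng.choice(list(AMINO_ACIDS), size=6, p=dist))
    if planted and rng.random() < plant_rate:
        tri = planted[rng.integers(len(planted))]
        offset = int(rng.integers(0, 4))  # in-window offset 0..3
        residues[offset:offset + 3] = list(tri)
    return "".join(residues)


def generate_hexapeptides(config: SyntheticConfig) -> list[PeptideRecord]:
    """A labeled hexapeptide dataset with exact class sizes.

    Positives first (label 1), then negatives (label 0); deterministic
    given ``config.seed``.
    """
    if config.n_pos < 1 or config.n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(config.seed)
    pos_dist = _positive_distribution(config)
    neg_dist = _negative_distribution(config)
    records = [
        PeptideRecord(
            id=f"pos{i + 1:04d}",
            sequence=_draw_hexapeptide(rng, pos_dist,
                                       config.planted_tripeptides_pos,
                                       config.plant_rate),
            label=1,
        )
        for i in range(config.n_pos)
    ]
    records += [
        PeptideRecord(
            id=f"neg{i + 1:04d}",
            sequence=_draw_hexapeptide(rng, neg_dist,
                                       config.planted_tripeptides_neg,
                                       config.plant_rate),
            label=0,
        )
        for i in range(config.n_neg)
    ]
    return records


def generate_annotated_proteins(
    n: int,
    length_range: tuple[int, int] = (40, 80),
    hotspots_per_protein: int = 1,
    config: SyntheticConfig | None = None,
) -> tuple[list[PeptideRecord], dict[str, HotspotAnnotation]]:
    """Proteins with planted hotspot hexapeptides and their annotations.

    Background residues come from the negative composition; each hotspot
    is a positive-style hexapeptide placed so consecutive hotspots are
    separated by at least six background residues. Raises when the
    requested hotspots cannot fit at the minimum protein length.
    """
    config = config or SyntheticConfig()
    lo, hi = length_range
    k = hotspots_per_protein
    min_needed = 6 * k + 6 * max(k - 1, 0)
    if lo < 6 or min_needed > lo:
        raise ValueError(
            f"{k} hotspot(s) with >=6-residue gaps need length >= {min_needed}, "
            f"but minimum protein length is {lo}")
    rng = np.random.default_rng(config.seed + 1)
    neg_dist = _negative_distribution(config)
    pos_dist = _positive_distribution(config)
    proteins: list[PeptideRecord] = []
    annotations: dict[str, HotspotAnnotation] = {}
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), size=L, p=neg_dist))
        # place k hotspot starts left to right with >=6 gap between regions
        slack = L - min_needed
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        starts = [int(cuts[j]) + j * 12 for j in range(k)]  # 0-based starts
        regions = []
        for s in starts:
            hot = _draw_hexapeptide(rng, pos_dist,
                                    config.planted_tripeptides_pos,
                                    config.plant_rate)
            seq[s:s + 6] = list(hot)
            regions.append((s + 1, s + 6))  # 1-based inclusive
        pid = f"prot{i + 1:03d}"
        proteins.append(PeptideRecord(id=pid, sequence="".join(seq)))
        annotations[pid] = HotspotAnnotation(protein_id=pid, regions=regions)
    return proteins, annotations
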