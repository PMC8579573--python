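"""Reading and writing sequences, labels, hotspot annotations and predictions.

All external coordinates are 1-based inclusive residue intervals
("residues 15-20" means positions 15..20, both ends included). Internal
half-open conventions are converted at this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, SequenceValidationError

logger = logging.getLogger(__name__)

_VALID = frozenset(AMINO_ACIDS)

Policy = Literal["error", "skip"]


@dataclass
class PeptideRecord:
    """An identified amino-acid sequence with an optional binary amyloid label.

    ``label`` is 1 for amyloidogenic (positive), 0 for non-amyloidogenic,
    ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: Optional[int] = None


@dataclass
class HotspotAnnotation:
    """Known amyloidogenic regions of one protein as 1-based inclusive intervals."""

    protein_id: str
    regions: list[tuple[int, int]] = field(default_factory=list)

    def mask(self, length: int) -> list[int]:
        """Per-residue 0/1 truth mask of the given protein length."""
        m = [0] * length
        for start, end in self.regions:
            if not (1 <= start <= end <= length):
                raise ValueError(
                    f"annotation ({start}, {end}) outside [1, {length}] "
                    f"for protein {self.protein_id!r}"
                )
            for i in range(start - 1, end):
                m[i] = 1
        return m


def validate_sequence(raw: str, policy: Policy = "error") -> Optional[str]:
    """Uppercase ``raw`` and enforce the 20-letter alphabet.

    With ``policy="error"`` a non-standard character (X, B, Z, U, ``*``,
    gaps, ...) raises :class:`SequenceValidationError` naming the first bad
    position (1-based); with ``policy="skip"`` the function logs a warning
    and returns ``None`` so the caller can drop the record.
    """
    if not raw:
        raise SequenceValidationError("empty sequence")
    seq = raw.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in _VALID:
            msg = f"invalid character {ch!r} at position {pos}"
            if policy == "error":
                raise SequenceValidationError(msg)
            logger.warning("sequence rejected: %s", msg)
            return None
    return seq


def read_fasta(path: str | Path, policy: Policy = "skip") -> list[PeptideRecord]:
    """Read a FASTA file into :class:`PeptideRecord` objects.

    The record id is the first whitespace-delimited token of the header and
    sequences are uppercased. Records failing alphabet validation are handled
    per ``policy`` (default: dropped with a warning).
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() == "":
        logger.warning("empty FASTA file: %s", path)
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise ValueError(
                f"malformed FASTA {path}: line {lineno} precedes any '>' header"
            )
        break
    records: list[PeptideRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = validate_sequence(str(rec.seq), policy=policy)
        if seq is None:
            logger.warning("skipping FASTA record %r", rec.id)
            continue
        records.append(PeptideRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records as FASTA; round-trips ids and sequences exactly."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_labeled_dataset(path: str | Path, policy: Policy = "error") -> list[PeptideRecord]:
    """Read a delimited (TSV/CSV) labeled hexapeptide dataset.

    Expected columns: ``sequence, label`` or ``id, sequence, label`` (a
    header row is detected and skipped). Labels must be 0 or 1, 1 meaning
    amyloidogenic. Duplicate sequences are kept; conflicting duplicate labels
    trigger a loud warning — deduplication is the caller's choice.
    """
    import csv as _csv
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                         comment="#", skip_blank_lines=True)
    except (pd.errors.EmptyDataError, _csv.Error):
        raise ValueError(f"no records in {path}") from None
    if df.empty:
        raise ValueError(f"no records in {path}")
    if df.shape[1] == 2:
        df.columns = ["sequence", "label"]
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
        df.columns = ["id", "sequence", "label"]
    else:
        raise ValueError(f"{path}: need columns (sequence, label[, id])")

    first = str(df.iloc[0]["label"]).strip()
    if first not in ("0", "1"):  # header row
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no records in {path}")

    records: list[PeptideRecord] = []
    seen: dict[str, int] = {}
    for i, row in df.iterrows():
        raw_label = str(row["label"]).strip()
        if raw_label not in ("0", "1"):
            raise ValueError(f"{path} row {i + 1}: label {raw_label!r} not in {{0,1}}")
        seq = validate_sequence(str(row["sequence"]).strip(), policy=policy)
        if seq is None:
            continue
        label = int(raw_label)
        if seq in seen and seen[seq] != label:
            logger.warning(
                "duplicate sequence %r with conflicting labels (%d vs %d); both kept",
                seq, seen[seq], label,
            )
        seen.setdefault(seq, label)
        rid = str(row["id"]) if "id" in df.columns else f"pep{i + 1}"
        records.append(PeptideRecord(id=rid, sequence=seq, label=label))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_annotations(path: str | Path) -> dict[str, HotspotAnnotation]:
    """Read a TSV of hotspot annotations (protein_id, start, end).

    Overlapping intervals for the same protein are merged on load (and the
    merge is logged): literature annotations of the same protein frequently
    overlap and the per-residue truth mask is what matters downstream.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                     skip_blank_lines=True)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need columns (protein_id, start, end)")
    df = df.iloc[:, :3]
    df.columns = ["protein_id", "start", "end"]
    if not str(df.iloc[0]["start"]).strip().lstrip("-").isdigit():  # header row
        df = df.iloc[1:]
    out: dict[str, HotspotAnnotation] = {}
    raw: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        pid = str(row["protein_id"]).strip()
        start, end = int(row["start"]), int(row["end"])
        if not (1 <= start <= end):
            raise ValueError(f"{path}: bad interval ({start}, {end}) for {pid!r}")
        raw.setdefault(pid, []).append((start, end))
    for pid, ivs in raw.items():
        merged = merge_intervals(ivs)
        if len(merged) < len(ivs):
            logger.info("merged %d overlapping annotations for %r into %d regions",
                        len(ivs), pid, len(merged))
        out[pid] = HotspotAnnotation(protein_id=pid, regions=merged)
    return out


def write_regions(predictions, path: str | Path,
                  residue_path: str | Path | None = None) -> None:
    """Write region predictions as TSV (protein_id, start, end, max window score).

    ``predictions`` is an iterable of :class:`~amyloscan.scan.RegionPrediction`.
    With ``residue_path`` a per-residue file (protein_id, position, residue,
    call, score) is written as well.
    """
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tscore\n")
        for pred in predictions:
            for start, end in sorted(pred.regions):
                score = max(
                    (w.score for w in pred.window_predictions
                     if w.start <= end and w.start + 5 >= start),
                    default=float("nan"),
                )
                fh.write(f"{pred.protein_id}\t{start}\t{end}\t{score:.6f}\n")
    if residue_path is not None:
        with open(residue_path, "w") as fh:
            fh.write("protein_id\tposition\tresidue\tcall\tscore\n")
            for pred in predictions:
                for pos in range(1, len(pred.residue_mask) + 1):
                    fh.write(
                        f"{pred.protein_id}\t{pos}\t{pred.sequence[pos - 1]}\t"
                        f"{pred.residue_mask[pos - 1]}\t{pred.residue_scores[pos - 1]:.6f}\n"
                    )


def read_regions(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a region-prediction TSV back into intervals per protein."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["protein_id"]), []).append(
            (int(row["start"]), int(row["end"])))
    return out
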