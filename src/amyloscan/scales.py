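"""Physicochemical property scales and their standardization.

The Type 2 (series-correlation) PseAAC encoder uses nine amino-acid
property scales. Six are the classic tables long distributed with PseAAC
tools (hydrophobicity, hydrophilicity, side-chain mass, pK1 of the
alpha-COOH group, pK2 of the NH3 group, isoelectric point at 25 C); the
remaining three capture backbone/side-chain mechanics and evolutionary
conservation: rigidity (Charton steric parameter), flexibility
(Bhaskaran-Ponnuswamy average flexibility index) and irreplaceability
(negated Dayhoff relative mutability — the less mutable a residue, the
harder it is to replace).

Every scale is z-standardized over the 20 amino acids (population
standard deviation, i.e. divide by 20) before use, so the defaults can be
swapped for any other table via :func:`load_scales_tsv` without changing
the encoder contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS

# fmt: off
RAW_SCALES: dict[str, dict[str, float]] = {
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
        "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
        "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
        "W": 0.81, "Y": 0.26,
    },
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
        "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
        "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
        "W": -3.4, "Y": -2.3,
    },
    "mass": {
        "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
        "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
        "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
        "W": 130.0, "Y": 107.0,
    },
    "pK1": {
        "A": 2.35, "C": 1.71, "D": 1.88, "E": 2.19, "F": 2.58, "G": 2.34,
        "H": 1.78, "I": 2.32, "K": 2.20, "L": 2.36, "M": 2.28, "N": 2.18,
        "P": 1.99, "Q": 2.17, "R": 2.17, "S": 2.21, "T": 2.15, "V": 2.29,
        "W": 2.38, "Y": 2.20,
    },
    "pK2": {
        "A": 9.87, "C": 10.78, "D": 9.60, "E": 9.67, "F": 9.24, "G": 9.60,
        "H": 8.97, "I": 9.76, "K": 8.90, "L": 9.60, "M": 9.21, "N": 9.09,
        "P": 10.60, "Q": 9.13, "R": 9.04, "S": 9.15, "T": 9.12, "V": 9.72,
        "W": 9.39, "Y": 9.11,
    },
    "pI": {
        "A": 6.11, "C": 5.02, "D": 2.98, "E": 3.08, "F": 5.91, "G": 6.06,
        "H": 7.64, "I": 6.04, "K": 9.47, "L": 6.04, "M": 5.74, "N": 5.41,
        "P": 6.30, "Q": 5.65, "R": 10.76, "S": 5.68, "T": 5.60, "V": 6.02,
        "W": 5.88, "Y": 5.63,
    },
    "rigidity": {
        "A": 0.52, "C": 0.62, "D": 0.76, "E": 0.68, "F": 0.70, "G": 0.00,
        "H": 0.70, "I": 1.02, "K": 0.68, "L": 0.98, "M": 0.78, "N": 0.76,
        "P": 0.36, "Q": 0.68, "R": 0.68, "S": 0.53, "T": 0.70, "V": 0.76,
        "W": 0.70, "Y": 0.70,
    },
    "flexibility": {
        "A": 0.357, "C": 0.346, "D": 0.511, "E": 0.497, "F": 0.314, "G": 0.544,
        "H": 0.323, "I": 0.462, "K": 0.466, "L": 0.365, "M": 0.295, "N": 0.463,
        "P": 0.509, "Q": 0.493, "R": 0.529, "S": 0.507, "T": 0.444, "V": 0.386,
        "W": 0.305, "Y": 0.420,
    },
    "irreplaceability": {
        "A": -100.0, "C": -20.0, "D": -106.0, "E": -102.0, "F": -41.0,
        "G": -49.0, "H": -66.0, "I": -96.0, "K": -56.0, "L": -40.0,
        "M": -94.0, "N": -134.0, "P": -56.0, "Q": -93.0, "R": -65.0,
        "S": -120.0, "T": -97.0, "V": -74.0, "W": -18.0, "Y": -41.0,
    },
}
# fmt: on

DEFAULT_SCALE_NAMES: tuple[str, ...] = tuple(RAW_SCALES)


@dataclass(frozen=True)
class PropertyScale:
    """One named amino-acid property: raw values and their z-standardized form.

    Standardization subtracts the mean over the 20 amino acids and divides
    by the population standard deviation (ddof=0), so the standardized
    values have mean 0 and sd 1 exactly.
    """

    name: str
    raw: dict[str, float]
    standardized: dict[str, float]

    def standardized_array(self) -> np.ndarray:
        """Standardized values in alphabetical amino-acid order."""
        return np.array([self.standardized[aa] for aa in AMINO_ACIDS])


def standardize_scale(raw: dict[str, float], name: str = "") -> PropertyScale:
    """Z-standardize a 20-value property table (population sd).

    Raises if an amino acid is missing, a value is non-finite, or all
    values are equal (zero variance).
    """
    missing = [aa for aa in AMINO_ACIDS if aa not in raw]
    if missing:
        raise ValueError(f"scale {name!r}: missing amino acid(s) {missing}")
    values = np.array([float(raw[aa]) for aa in AMINO_ACIDS])
    if not np.all(np.isfinite(values)):
        raise ValueError(f"scale {name!r}: non-finite value")
    mean = values.mean()
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError(f"scale {name!r}: zero variance (all values equal)")
    std = (values - mean) / sd
    return PropertyScale(
        name=name,
        raw={aa: float(raw[aa]) for aa in AMINO_ACIDS},
        standardized=dict(zip(AMINO_ACIDS, std.tolist())),
    )


def default_scales() -> list[PropertyScale]:
    """The nine default scales, standardized, in canonical order."""
    return [standardize_scale(RAW_SCALES[name], name) for name in DEFAULT_SCALE_NAMES]


def load_scales_tsv(path: str | Path) -> list[PropertyScale]:
    """Load property scales from a TSV: rows = 20 amino acids, columns = scales.

    The first column must hold the one-letter amino-acid codes; every other
    column is one named scale.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [str(i).upper() for i in df.index]
    return [standardize_scale(df[col].to_dict(), str(col)) for col in df.columns]


def write_scales_tsv(scales: list[PropertyScale], path: str | Path) -> None:
    """Write raw scale values as TSV (inverse of :func:`load_scales_tsv`)."""
    df = pd.DataFrame({s.name: [s.raw[aa] for aa in AMINO_ACIDS] for s in scales},
                      index=list(AMINO_ACIDS))
    df.to_csv(path, sep="\t", index_label="aa")
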