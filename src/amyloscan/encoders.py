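"""Sequence encoders: Type 2 (series-correlation) PseAAC and tripeptide composition.

Two encodings are produced per peptide:

* **PseAAC (Type 2)** — the 20 amino-acid occurrence frequencies f_u
  followed by 9*lambda lag-correlation factors theta_j, where theta for lag d
  and property k averages the product of standardized property values of
  residues d apart: (1/(L-d)) * sum_i h_k(R_i) h_k(R_{i+d}). The whole
  vector is normalised by sum_i f_i + w * sum_j theta_j with weight w
  (default 0.7), giving 20 + 9*lambda components that sum to 1.
* **TPC** — the 8000 overlapping-tripeptide frequencies N_i / (L-2),
  indexed by the alphabetical base-20 code 400*a1 + 20*a2 + a3.

Both are exposed as plain functions and as scikit-learn transformers
operating on iterables of sequences (or :class:`~amyloscan.io.PeptideRecord`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import AA_TO_INDEX, AMINO_ACIDS, N_TRIPEPTIDES
from .scales import PropertyScale, default_scales

DENOM_EPS = 1e-12

CountMode = Literal["frequency", "count"]


@dataclass
class FeatureVector:
    """A named, ordered numeric encoding of one sequence."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class PseAACParams:
    """Parameters of the Type 2 PseAAC encoding.

    ``lambda_rank`` is the maximum correlation lag (default 2, which with
    nine scales gives the 38-component vector); ``weight`` is the factor w
    balancing composition against correlation (default 0.7);
    ``count_mode`` selects whether f_u enters as raw occurrence counts
    (the default: the composition block then sums to L, which keeps the
    normaliser sum(f) + w*sum(theta) away from zero on short peptides,
    where the correlation block is volatile and can be strongly negative)
    or as relative frequencies (counts / L). The encoded vector sums to 1
    in either mode because the normaliser is that same total.
    """

    lambda_rank: int = 2
    weight: float = 0.7
    scales: list[PropertyScale] = field(default_factory=default_scales)
    count_mode: CountMode = "count"

    def __post_init__(self) -> None:
        if self.lambda_rank < 1:
            raise ValueError("lambda_rank must be >= 1")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if not self.scales:
            raise ValueError("at least one property scale required")

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    @property
    def dim(self) -> int:
        return 20 + self.n_scales * self.lambda_rank

    def scale_matrix(self) -> np.ndarray:
        """Standardized property values, shape (n_scales, 20)."""
        return np.stack([s.standardized_array() for s in self.scales])


def _seq_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_TO_INDEX[aa] for aa in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"invalid amino acid {exc.args[0]!r} in sequence") from None


def correlation_factors(sequence: str, params: PseAACParams) -> np.ndarray:
    """The 9*lambda lag-correlation factors theta_1..theta_{9*lambda}.

    Ordered lag-major: the first ``n_scales`` entries are the per-property
    averages at lag 1, the next at lag 2, and so on.
    """
    L = len(sequence)
    if L <= params.lambda_rank:
        raise ValueError(
            f"sequence shorter than correlation rank: L={L} <= lambda={params.lambda_rank}"
        )
    idx = _seq_indices(sequence)
    H = params.scale_matrix()  # (k, 20)
    h = H[:, idx]  # (k, L)
    thetas = [
        (h[:, :-d] * h[:, d:]).mean(axis=1) for d in range(1, params.lambda_rank + 1)
    ]
    return np.concatenate(thetas)


def pseaac_vector(sequence: str, params: PseAACParams) -> np.ndarray:
    """Type 2 PseAAC vector of length ``20 + n_scales * lambda_rank``."""
    L = len(sequence)
    idx = _seq_indices(sequence)
    counts = np.bincount(idx, minlength=20).astype(float)
    f = counts / L if params.count_mode == "frequency" else counts
    theta = correlation_factors(sequence, params)
    denom = f.sum() + params.weight * theta.sum()
    if denom <= DENOM_EPS:
        raise ValueError("degenerate PseAAC normalization (denominator <= 0)")
    return np.concatenate([f, params.weight * theta]) / denom


def pseaac_feature_names(params: PseAACParams) -> list[str]:
    names = [f"pseaac_f_{aa}" for aa in AMINO_ACIDS]
    for d in range(1, params.lambda_rank + 1):
        names += [f"pseaac_theta_lag{d}_{s.name}" for s in params.scales]
    return names


def encode_pseaac(sequence: str, params: PseAACParams | None = None) -> FeatureVector:
    """PseAAC encoding with feature names attached."""
    params = params or PseAACParams()
    return FeatureVector(pseaac_feature_names(params), pseaac_vector(sequence, params))


def tripeptide_index(tripeptide: str) -> int:
    """Alphabetical base-20 code of a tripeptide: 400*a1 + 20*a2 + a3 in [0, 7999]."""
    if len(tripeptide) != 3:
        raise ValueError(f"not a tripeptide: {tripeptide!r}")
    try:
        a, b, c = (AA_TO_INDEX[ch] for ch in tripeptide)
    except KeyError as exc:
        raise ValueError(f"invalid amino acid {exc.args[0]!r} in tripeptide") from None
    return 400 * a + 20 * b + c


def index_to_tripeptide(index: int) -> str:
    """Inverse of :func:`tripeptide_index`."""
    if not 0 <= index < N_TRIPEPTIDES:
        raise ValueError(f"tripeptide index out of range: {index}")
    a, rem = divmod(index, 400)
    b, c = divmod(rem, 20)
    return AMINO_ACIDS[a] + AMINO_ACIDS[b] + AMINO_ACIDS[c]


def all_tripeptides() -> list[str]:
    """All 8000 tripeptides in index order."""
    return [index_to_tripeptide(i) for i in range(N_TRIPEPTIDES)]


def tripeptide_counts(sequence: str) -> np.ndarray:
    """Occurrence counts of the L-2 overlapping tripeptide windows (length 8000)."""
    L = len(sequence)
    if L < 3:
        raise ValueError(f"sequence too short for tripeptides: L={L}")
    idx = _seq_indices(sequence)
    codes = 400 * idx[:-2] + 20 * idx[1:-1] + idx[2:]
    return np.bincount(codes, minlength=N_TRIPEPTIDES).astype(float)


def tpc_vector(sequence: str) -> np.ndarray:
    """Tripeptide-composition vector: counts over L-2 windows, normalised by L-2."""
    counts = tripeptide_counts(sequence)
    return counts / (len(sequence) - 2)


def encode_tpc(sequence: str) -> FeatureVector:
    """TPC encoding with tripeptide names attached (8000 components)."""
    return FeatureVector([f"tpc_{t}" for t in all_tripeptides()], tpc_vector(sequence))


def _as_sequences(X: Iterable) -> list[str]:
    out = []
    for x in X:
        out.append(x.sequence if hasattr(x, "sequence") else str(x))
    return out


class PseAACEncoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer computing Type 2 PseAAC vectors.

    ``X`` is an iterable of amino-acid sequences (strings or
    ``PeptideRecord``); output shape is ``(n_samples, 20 + 9*lambda_rank)``
    with the default nine scales.
    """

    def __init__(self, lambda_rank: int = 2, weight: float = 0.7,
                 scales: list[PropertyScale] | None = None,
                 count_mode: CountMode = "count"):
        self.lambda_rank = lambda_rank
        self.weight = weight
        self.scales = scales
        self.count_mode = count_mode

    def _params(self) -> PseAACParams:
        return PseAACParams(
            lambda_rank=self.lambda_rank,
            weight=self.weight,
            scales=list(self.scales) if self.scales is not None else default_scales(),
            count_mode=self.count_mode,
        )

    def fit(self, X, y=None):
        self.params_ = self._params()
        self.n_features_out_ = self.params_.dim
        return self

    def transform(self, X) -> np.ndarray:
        params = getattr(self, "params_", None) or self._params()
        seqs = _as_sequences(X)
        return np.stack([pseaac_vector(s, params) for s in seqs]) if seqs else \
            np.empty((0, params.dim))

    def get_feature_names_out(self, input_features=None):
        params = getattr(self, "params_", None) or self._params()
        return np.asarray(pseaac_feature_names(params), dtype=object)


class TripeptideCompositionEncoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer computing 8000-dimensional TPC vectors."""

    def fit(self, X, y=None):
        self.n_features_out_ = N_TRIPEPTIDES
        return self

    def transform(self, X) -> np.ndarray:
        seqs = _as_sequences(X)
        return np.stack([tpc_vector(s) for s in seqs]) if seqs else \
            np.empty((0, N_TRIPEPTIDES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"tpc_{t}" for t in all_tripeptides()], dtype=object)
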