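"""The 20-letter amino-acid alphabet used throughout the package.

Amino acids are kept in alphabetical one-letter order; every encoder,
index and property table relies on this ordering.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_TRIPEPTIDES: int = 20 ** 3


class SequenceValidationError(ValueError):
    """A sequence contains a character outside the 20-letter alphabet."""
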