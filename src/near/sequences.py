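"""Protein sequence container and the residue alphabet.

The model consumes sequences over the 20 canonical amino acids plus a single
unknown token. Ambiguity codes (X, B, Z, J) and the rare residues U and O are
retained in the sequence string but collapsed onto the unknown token when
encoded for the network. Case is preserved on input because lowercase letters
carry the soft-masking signal used by :mod:`near.masking`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZJUO"
UNKNOWN_TOKEN = len(CANONICAL_AA)  # index 20
ALPHABET_SIZE = len(CANONICAL_AA) + 1  # 20 canonical + 1 unknown

_TOKEN_OF = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass
class ProteinSequence:
    """A named amino-acid sequence; the unit of embedding and search.

    ``residues`` keeps the original case so that lowercase (soft-masked)
    letters remain visible to the masking stage.
    """

    id: str
    residues: str
    ambiguous_positions: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = sorted(
            {c for c in self.residues.upper() if not c.isalpha()}
        )
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-letter characters: {bad}"
            )
        self.ambiguous_positions = tuple(
            i
            for i, c in enumerate(self.residues.upper())
            if c not in _TOKEN_OF
        )

    def __len__(self) -> int:
        return len(self.residues)

    def tokens(self) -> np.ndarray:
        """Integer token ids (length n); non-canonical letters -> unknown."""
        up = self.residues.upper()
        return np.array(
            [_TOKEN_OF.get(c, UNKNOWN_TOKEN) for c in up], dtype=np.int64
        )

    def upper(self) -> str:
        return self.residues.upper()


def tokens_from_string(residues: str) -> np.ndarray:
    return ProteinSequence(id="_", residues=residues).tokens()
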