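"""Amino-acid alphabet and integer encoding.

The model vocabulary has 22 tokens: the 20 standard amino acids, one
"unknown" token collecting the non-canonical one-letter codes that occur in
real epitope data (B, J, O, U, X, Z), and one padding token used only for
flank/batch padding. The padding token's embedding is frozen at zero so that
padded positions are information-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical one-letter codes, alphabetical (defines indices 0..19).
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Non-canonical codes mapped to the unknown token.
NONCANONICAL_AA = "BJOUXZ"


@dataclass(frozen=True)
class Alphabet:
    """Token inventory for peptides and MHC-II pseudo sequences.

    Indices 0..19 are the canonical residues in :data:`CANONICAL_AA` order,
    index 20 is the unknown token and index 21 the padding token.
    """

    canonical_tokens: str = CANONICAL_AA
    unknown_token: str = "X"
    pad_token: str = "-"
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.canonical_tokens)) != 20:
            raise ValueError("alphabet requires 20 distinct canonical tokens")
        idx = {aa: i for i, aa in enumerate(self.canonical_tokens)}
        object.__setattr__(self, "_index", idx)

    @property
    def size(self) -> int:
        return 22

    @property
    def unknown_index(self) -> int:
        return 20

    @property
    def pad_index(self) -> int:
        return 21

    def encode(self, sequence: str) -> np.ndarray:
        """Encode a residue string as an int64 array of token indices.

        Canonical residues map to their fixed index, any other letter to the
        unknown token. Lowercase input is accepted and upper-cased.
        """
        ids = np.empty(len(sequence), dtype=np.int64)
        index = self._index
        for i, ch in enumerate(sequence.upper()):
            ids[i] = index.get(ch, self.unknown_index)
        return ids

    def decode(self, ids: np.ndarray) -> str:
        """Inverse of :meth:`encode` on canonical tokens."""
        out = []
        for i in np.asarray(ids, dtype=np.int64):
            if i < 20:
                out.append(self.canonical_tokens[i])
            elif i == self.unknown_index:
                out.append(self.unknown_token)
            elif i == self.pad_index:
                out.append(self.pad_token)
            else:
                raise ValueError(f"token index {i} outside alphabet")
        return "".join(out)

    def is_encodable(self, sequence: str) -> bool:
        """True if every character is a letter (canonical or unknown-mapped)."""
        return all(ch.isalpha() for ch in sequence)


#: Module-level default alphabet; the encoding is fixed, so sharing is safe.
DEFAULT_ALPHABET = Alphabet()
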