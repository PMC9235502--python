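"""Affinity tables, allele registries, IC50 normalization and encoding.

File dialects (all UTF-8, tab-separated):

* affinity table: ``peptide<TAB>value<TAB>allele[<TAB>fold]``, optional
  header auto-detected by a non-numeric second column;
* allele registry: ``allele_name<TAB>pseudo_sequence`` with 34-residue
  pseudo sequences;
* peptide lists: one peptide per line, or FASTA (auto-detected by ``>``).

Quantitative binding data is stored as IC50 (nM) in public releases and
normalized to [0, 1] by ``1 - log(IC50) / log(50000)`` before modeling;
lower IC50 (stronger binding) maps to higher normalized affinity.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .alphabet import DEFAULT_ALPHABET, Alphabet

#: IC50 (nM) at which the normalized affinity reaches 0.
IC50_MAX_NM = 50000.0

#: Core length: the MHC-II groove has nine pockets.
CORE_LENGTH = 9

#: Length of the pan-specific MHC-II pseudo sequence (15 α + 19 β contact residues).
PSEUDO_LENGTH = 34


def transform_ic50(ic50_nm, clamp: bool = True):
    """Normalize an IC50 (nM) to the [0, 1] affinity scale.

    ``affinity = 1 - log(ic50) / log(50000)``. The transform is strictly
    decreasing; 500 nM (the conventional binder threshold) maps to 0.426.
    With ``clamp`` (default), values outside [0, 1] — IC50 above 50 000 nM
    or below 1 nM — are clamped to the boundary.
    """
    ic50_nm = np.asarray(ic50_nm, dtype=float)
    if np.any(ic50_nm <= 0):
        raise ValueError("IC50 must be positive (nM)")
    aff = 1.0 - np.log(ic50_nm) / math.log(IC50_MAX_NM)
    if clamp:
        aff = np.clip(aff, 0.0, 1.0)
    return float(aff) if aff.ndim == 0 else aff


def inverse_transform(affinity):
    """Map a normalized affinity in [0, 1] back to IC50 (nM)."""
    affinity = np.asarray(affinity, dtype=float)
    if np.any((affinity < 0) | (affinity > 1)):
        raise ValueError("affinity must lie in [0, 1]")
    ic50 = IC50_MAX_NM ** (1.0 - affinity)
    return float(ic50) if ic50.ndim == 0 else ic50


@dataclass
class AffinityRecord:
    """One peptide–allele pair with a normalized affinity target."""

    peptide: str
    allele_name: str
    affinity: float
    fold: int | None = None
    binder: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.affinity <= 1.0:
            raise ValueError(
                f"affinity {self.affinity} outside [0, 1] for {self.peptide}"
            )
        if not DEFAULT_ALPHABET.is_encodable(self.peptide):
            raise ValueError(f"peptide {self.peptide!r} contains non-letter characters")

    def __len__(self) -> int:
        return len(self.peptide)


class UnknownAlleleError(KeyError):
    """Raised when an allele name is not present in the registry."""

    def __init__(self, allele_name: str):
        super().__init__(allele_name)
        self.allele_name = allele_name

    def __str__(self) -> str:  # KeyError quotes repr by default
        return f"allele {self.allele_name!r} is not in the registry"


class AlleleRegistry(Mapping[str, str]):
    """Mapping from allele name to its 34-residue pseudo sequence.

    Lookup of an unregistered allele raises :class:`UnknownAlleleError`;
    there is deliberately no silent default.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        if mapping:
            for name, pseudo in mapping.items():
                self.add(name, pseudo)

    def add(self, allele_name: str, pseudo_sequence: str) -> None:
        pseudo_sequence = pseudo_sequence.strip().upper()
        if len(pseudo_sequence) != PSEUDO_LENGTH:
            raise ValueError(
                f"pseudo sequence for {allele_name!r} has length "
                f"{len(pseudo_sequence)}, expected {PSEUDO_LENGTH}"
            )
        self._map[allele_name] = pseudo_sequence

    def __getitem__(self, allele_name: str) -> str:
        try:
            return self._map[allele_name]
        except KeyError:
            raise UnknownAlleleError(allele_name) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path) -> "AlleleRegistry":
        reg = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
                reg.add(parts[0], parts[1])
        return reg

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, pseudo in self._map.items():
                fh.write(f"{name}\t{pseudo}\n")


@dataclass
class RejectedLine:
    """A parseable line skipped for a semantic reason (e.g. unknown allele)."""

    lineno: int
    line: str
    reason: str


class AffinityTableError(ValueError):
    """Malformed affinity-table line; carries the line number."""


def _looks_like_header(parts: list[str]) -> bool:
    if len(parts) < 3:
        return False
    try:
        float(parts[1])
    except ValueError:
        return True
    return False


def read_affinity_table(
    path,
    registry: AlleleRegistry | None = None,
    ic50_mode: bool = False,
    clamp: bool = True,
) -> tuple[list[AffinityRecord], list[RejectedLine]]:
    """Read a tab-separated affinity table.

    Returns ``(records, rejected)``. Records whose allele is missing from
    ``registry`` (when one is given) are collected in ``rejected`` rather
    than silently dropped. In ``ic50_mode`` the value column is raw IC50 in
    nM and is passed through :func:`transform_ic50`. A malformed line raises
    :class:`AffinityTableError` naming the line number.
    """
    records: list[AffinityRecord] = []
    rejected: list[RejectedLine] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and _looks_like_header(parts):
                continue
            if len(parts) not in (3, 4):
                raise AffinityTableError(
                    f"{path}:{lineno}: expected 3 or 4 tab-separated columns, got {len(parts)}"
                )
            peptide, value_s, allele = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                value = float(value_s)
            except ValueError:
                raise AffinityTableError(
                    f"{path}:{lineno}: value column {value_s!r} is not numeric"
                ) from None
            fold = None
            if len(parts) == 4 and parts[3].strip():
                try:
                    fold = int(parts[3])
                except ValueError:
                    raise AffinityTableError(
                        f"{path}:{lineno}: fold column {parts[3]!r} is not an integer"
                    ) from None
            if registry is not None and allele not in registry:
                rejected.append(RejectedLine(lineno, line, f"unknown allele {allele!r}"))
                continue
            affinity = transform_ic50(value, clamp=clamp) if ic50_mode else value
            try:
                records.append(AffinityRecord(peptide, allele, affinity, fold=fold))
            except ValueError as exc:
                raise AffinityTableError(f"{path}:{lineno}: {exc}") from None
    return records, rejected


def write_affinity_table(path, records: Iterable[AffinityRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            cols = [rec.peptide, format(rec.affinity, ".6g"), rec.allele_name]
            if rec.fold is not None:
                cols.append(str(rec.fold))
            fh.write("\t".join(cols) + "\n")


def read_peptides(path) -> list[str]:
    """Read a peptide list: FASTA or one-peptide-per-line, auto-detected."""
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith(">"):
        return [str(rec.seq).upper() for rec in SeqIO.parse(io.StringIO(text), "fasta")]
    return [line.strip().upper() for line in text.splitlines() if line.strip()]


@dataclass
class EncodedPair:
    """Integer-encoded peptide / pseudo-sequence pair ready for the model."""

    peptide_ids: np.ndarray
    pseudo_ids: np.ndarray
    peptide_length: int
    target: float | None = None


def encode_pair(
    record: AffinityRecord,
    registry: AlleleRegistry,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> EncodedPair:
    """Encode a record as token ids; peptides must span at least one 9-mer core."""
    if len(record.peptide) < CORE_LENGTH:
        raise ValueError(
            f"peptide {record.peptide!r} shorter than the {CORE_LENGTH}-residue binding core"
        )
    pseudo = registry[record.allele_name]
    return EncodedPair(
        peptide_ids=alphabet.encode(record.peptide),
        pseudo_ids=alphabet.encode(pseudo),
        peptide_length=len(record.peptide),
        target=record.affinity,
    )
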