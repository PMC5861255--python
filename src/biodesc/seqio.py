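"""Sequence input, validation and synthetic fixtures.

Proteins are strings over the 20 canonical one-letter amino acids and DNAs
are strings over {A,C,G,T}.  The validators follow a "length or zero"
contract: a clean sequence validates to its length, anything containing a
character outside the canonical alphabet (ambiguity codes, gaps, RNA's U,
digits, …) validates to 0.  Whitespace is stripped and case is folded
before checking, so wrapped FASTA bodies pass through unchanged.
"""

from __future__ import annotations

import dataclasses
import random
from pathlib import Path
from typing import Iterable, Literal

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "AMINO_ACIDS",
    "DNA_BASES",
    "FastaRecord",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "validate_protein",
    "validate_dna",
    "random_sequences",
]

#: The 20 canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
#: DNA bases in alphabetical order.
DNA_BASES: str = "ACGT"

_AA_SET = frozenset(AMINO_ACIDS)
_DNA_SET = frozenset(DNA_BASES)


class FastaFormatError(ValueError):
    """Raised when a FASTA file is malformed (e.g. text before '>')."""


@dataclasses.dataclass(frozen=True)
class FastaRecord:
    """One FASTA entry: identifier, optional description, raw body."""

    identifier: str
    description: str
    raw_sequence: str

    def __post_init__(self) -> None:
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise ValueError(f"invalid FASTA identifier: {self.identifier!r}")
        if not self.raw_sequence:
            raise ValueError(f"empty sequence for record {self.identifier!r}")


def _strip(raw: str) -> str:
    return "".join(raw.split()).upper()


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read all records of a FASTA file, preserving order.

    Sequence lines are concatenated and whitespace inside them removed;
    the sequence body itself is kept verbatim otherwise (no validation —
    use :func:`validate_protein` / :func:`validate_dna` downstream).
    """
    path = Path(path)
    with open(path) as fh:
        # SimpleFastaParser silently skips leading junk; enforce the header.
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: text before first '>' header"
                    )
                break
    records = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            if not parts:
                raise FastaFormatError(f"{path}: empty FASTA header")
            ident = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            records.append(
                FastaRecord(ident, desc, "".join(seq.split()))
            )
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path, width: int = 60) -> None:
    """Write records in wrapped FASTA; inverse of :func:`read_fasta`."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.identifier
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n")
            body = rec.raw_sequence
            for i in range(0, len(body), width):
                fh.write(body[i : i + width] + "\n")


def validate_protein(raw: str) -> int:
    """Length of the cleaned sequence if purely canonical amino acids, else 0.

    Ambiguity codes (B, Z, X), selenocysteine/pyrrolysine (U, O), gaps and
    any non-letter characters all fail validation.  Never raises for
    ordinary strings; the failure signal is the 0 return value.
    """
    cleaned = _strip(raw)
    if cleaned and set(cleaned) <= _AA_SET:
        return len(cleaned)
    return 0


def validate_dna(raw: str) -> int:
    """Length of the cleaned sequence if purely A/C/G/T, else 0.

    RNA input (containing U) is rejected rather than transliterated;
    callers must pre-convert.
    """
    cleaned = _strip(raw)
    if cleaned and set(cleaned) <= _DNA_SET:
        return len(cleaned)
    return 0


def clean_protein(raw: str) -> str:
    """Cleaned canonical protein string; raises if validation fails."""
    if not validate_protein(raw):
        raise ValueError(f"not a canonical protein sequence: {raw[:30]!r}…")
    return _strip(raw)


def clean_dna(raw: str) -> str:
    """Cleaned canonical DNA string; raises if validation fails."""
    if not validate_dna(raw):
        raise ValueError(f"not a canonical DNA sequence: {raw[:30]!r}…")
    return _strip(raw)


def random_sequences(
    kind: Literal["protein", "dna"],
    n: int,
    length: int,
    seed: int,
) -> list[str]:
    """Deterministic i.i.d.-uniform random sequences over an alphabet.

    The generator is the package's fixture source: given equal arguments it
    always returns the same list, and every output passes the matching
    validator by construction.
    """
    if kind == "protein":
        alphabet = AMINO_ACIDS
    elif kind == "dna":
        alphabet = DNA_BASES
    else:
        raise ValueError(f"kind must be 'protein' or 'dna', got {kind!r}")
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    rng = random.Random(seed)
    return [
        "".join(rng.choices(alphabet, k=length)) for _ in range(n)
    ]
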