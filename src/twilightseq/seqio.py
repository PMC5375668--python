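"""Sequence records, FASTA input/output and dataset manifests.

Two alphabets are supported. ``amino`` covers the 20 standard residues plus
the ambiguity codes X, B, Z and selenocysteine U (scored as X where a matrix
has no U row). ``nucleotide`` covers ACGT plus the IUPAC ambiguity letters,
which the identity model scores as mismatches.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List

AMINO = "amino"
NUCLEOTIDE = "nucleotide"

AMINO_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMINO_AMBIGUOUS = "XBZU"
NUC_RESIDUES = "ACGT"
NUC_AMBIGUOUS = "RYSWKMBDHVN"

ALPHABETS = {
    AMINO: set(AMINO_RESIDUES + AMINO_AMBIGUOUS),
    NUCLEOTIDE: set(NUC_RESIDUES + NUC_AMBIGUOUS),
}


class FastaParseError(ValueError):
    """Malformed FASTA input (reports the offending line number)."""


class AlphabetError(ValueError):
    """A residue outside the declared alphabet (reports id and character)."""


@dataclass(frozen=True)
class Sequence:
    """A named residue string over a declared alphabet."""

    id: str
    residues: str
    alphabet: str = AMINO

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        # empty residue strings are permitted so boundary alignments
        # (all-gap rows) are expressible; file readers reject empty records
        allowed = ALPHABETS[self.alphabet]
        for ch in self.residues:
            if ch not in allowed:
                raise AlphabetError(
                    f"sequence {self.id!r}: residue {ch!r} not in {self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


def _normalize(residues: str, alphabet: str) -> str:
    residues = residues.upper()
    if alphabet == AMINO:
        # strip terminal stop symbols; internal stops are left to validation
        residues = residues.rstrip("*")
    elif alphabet == NUCLEOTIDE:
        residues = residues.replace("U", "T")
    return residues


def read_fasta(path: str | os.PathLike, alphabet: str) -> List[Sequence]:
    """Read a multi-record FASTA file into validated :class:`Sequence` objects.

    Residues are uppercased; in amino mode terminal ``*`` stop symbols are
    stripped; duplicate record ids are rejected.
    """
    if alphabet not in ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: List[Sequence] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: List[str] = []
    start_line = 0

    def flush() -> None:
        if current_id is None:
            return
        residues = _normalize("".join(chunks), alphabet)
        if not residues:
            raise FastaParseError(f"record {current_id!r} (line {start_line}) has no residues")
        records.append(Sequence(id=current_id, residues=residues, alphabet=alphabet))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FastaParseError(f"empty record header at line {lineno}")
                if current_id in seen:
                    raise FastaParseError(f"duplicate id {current_id!r} at line {lineno}")
                seen.add(current_id)
                chunks = []
                start_line = lineno
            else:
                if current_id is None:
                    raise FastaParseError(f"sequence data before any header at line {lineno}")
                chunks.append(line)
    flush()
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Iterable[Sequence], path: str | os.PathLike, width: int = 60) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def write_manifest(sequences: List[Sequence], path: str | os.PathLike) -> None:
    """Write a TSV manifest (id, alphabet, length) for a dataset."""
    if not sequences:
        raise ValueError("cannot write a manifest for an empty sequence list")
    with open(path, "w") as fh:
        fh.write("id\talphabet\tlength\n")
        for seq in sequences:
            fh.write(f"{seq.id}\t{seq.alphabet}\t{len(seq)}\n")


def read_manifest(path: str | os.PathLike) -> List[dict]:
    """Read a manifest written by :func:`write_manifest`."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            row["length"] = int(row["length"])
            rows.append(row)
    return rows
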