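"""Substitution models: parsed NCBI-format matrices and the nucleotide identity model.

Amino acid comparisons use BLOSUM45 and PAM250 with gap penalty 6; nucleotide
(coding sequence) comparisons use the identity matrix (match 1, mismatch 0)
with gap penalty 1. The matrices are bundled as plain-text files in the
whitespace-delimited square layout NCBI distributes them in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .seqio import AMINO, NUCLEOTIDE, NUC_AMBIGUOUS, NUC_RESIDUES, Sequence

DEFAULT_AMINO_GAP = 6
DEFAULT_NUC_GAP = 1


class MatrixFormatError(ValueError):
    """Matrix file is non-square, asymmetric or missing residues."""


@dataclass(frozen=True, eq=False)
class SubstitutionModel:
    """A symmetric residue-pair score table plus a positive linear gap penalty."""

    name: str
    alphabet: str
    residues: str                       # matrix row/column order
    matrix: np.ndarray = field(repr=False)  # integer scores, shape (n, n)
    gap_penalty: int = DEFAULT_AMINO_GAP

    def __post_init__(self) -> None:
        if self.gap_penalty <= 0:
            raise ValueError("gap penalty must be a positive integer")
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.residues):
            raise MatrixFormatError(f"{self.name}: matrix shape {m.shape} does not match residues")
        if not np.array_equal(m, m.T):
            raise MatrixFormatError(f"{self.name}: matrix is not symmetric")
        object.__setattr__(self, "_index", {r: i for i, r in enumerate(self.residues)})

    def entry(self, a: str, b: str) -> int:
        """Score for aligning residue ``a`` against residue ``b``."""
        idx = self._index
        return int(self.matrix[idx[self._map(a)], idx[self._map(b)]])

    def _map(self, residue: str) -> str:
        if residue in self._index:
            return residue
        if self.alphabet == AMINO and residue == "U" and "X" in self._index:
            return "X"  # selenocysteine scored as the unknown residue
        raise KeyError(f"residue {residue!r} has no row in matrix {self.name}")

    def encode(self, seq: Sequence) -> np.ndarray:
        """Encode a sequence as matrix row indices (int64) for the DP kernels."""
        if seq.alphabet != self.alphabet:
            raise ValueError(
                f"sequence {seq.id!r} is {seq.alphabet}, model {self.name!r} is {self.alphabet}"
            )
        idx = self._index
        return np.array([idx[self._map(ch)] for ch in seq.residues], dtype=np.int64)


def load_matrix(path: str | os.PathLike, gap_penalty: int,
                alphabet: str = AMINO, name: str | None = None) -> SubstitutionModel:
    """Parse an NCBI-style whitespace-delimited substitution matrix file.

    The file has an optional ``#`` comment block, a header row of residues and
    one labelled row per residue. Symmetry is verified on load.
    """
    with open(path) as fh:
        lines = [ln for ln in (raw.strip() for raw in fh) if ln and not ln.startswith("#")]
    if not lines:
        raise MatrixFormatError(f"{path}: no matrix content")
    header = lines[0].split()
    n = len(header)
    rows: dict[str, list[int]] = {}
    for ln in lines[1:]:
        fields = ln.split()
        if len(fields) != n + 1:
            raise MatrixFormatError(
                f"{path}: row {fields[0] if fields else '?'!r} has {len(fields) - 1} entries, expected {n}"
            )
        rows[fields[0]] = [int(x) for x in fields[1:]]
    missing = [r for r in header if r not in rows]
    if missing:
        raise MatrixFormatError(f"{path}: header residues {missing} have no rows")
    if len(rows) != n:
        raise MatrixFormatError(f"{path}: {len(rows)} rows for {n} header residues")
    matrix = np.array([rows[r] for r in header], dtype=np.int64)
    if not np.array_equal(matrix, matrix.T):
        bad = np.argwhere(matrix != matrix.T)[0]
        raise MatrixFormatError(
            f"{path}: asymmetric entries for ({header[bad[0]]}, {header[bad[1]]})"
        )
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return SubstitutionModel(name=name, alphabet=alphabet, residues="".join(header),
                             matrix=matrix, gap_penalty=gap_penalty)


def bundled_matrix(name: str, gap_penalty: int = DEFAULT_AMINO_GAP) -> SubstitutionModel:
    """Load one of the bundled amino acid matrices (``BLOSUM45`` or ``PAM250``)."""
    ref = resources.files("twilightseq.data").joinpath(f"{name}.txt")
    with resources.as_file(ref) as path:
        return load_matrix(path, gap_penalty, alphabet=AMINO, name=name)


def default_amino_models(gap_penalty: int = DEFAULT_AMINO_GAP) -> list[SubstitutionModel]:
    """The default pair of amino acid models (BLOSUM45 and PAM250, g=6)."""
    return [bundled_matrix("BLOSUM45", gap_penalty), bundled_matrix("PAM250", gap_penalty)]


def identity_model(gap_penalty: int = DEFAULT_NUC_GAP) -> SubstitutionModel:
    """Nucleotide identity model: match 1, mismatch 0; ambiguity codes always mismatch."""
    residues = NUC_RESIDUES + NUC_AMBIGUOUS
    matrix = np.zeros((len(residues), len(residues)), dtype=np.int64)
    for i in range(len(NUC_RESIDUES)):
        matrix[i, i] = 1
    return SubstitutionModel(name="identity", alphabet=NUCLEOTIDE, residues=residues,
                             matrix=matrix, gap_penalty=gap_penalty)
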