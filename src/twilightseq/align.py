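"""Optimal global alignment of two or three sequences by dynamic programming.

The gap model is linear: every column containing a gap pays a fixed penalty
(per gap in the column), end gaps included. For pairs a gapped column scores
-g; for triplets a one-gap column scores the pair entry of its two residues
minus g and a two-gap column scores -2g. A column never consists of gaps only.

Ties among optimal tracebacks are broken by a fixed move preference: the
fullest advance first (all sequences consume a residue), then one-gap moves
in sequence order, then single-sequence advances. The optimal score is
unaffected by the tie rule; column-level quantities such as percent identity
can depend on it, so it is fixed and documented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence as TypingSequence, Tuple

from . import _dp
from .scoring import SubstitutionModel
from .seqio import Sequence

GAP = "-"


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal global alignment: total score plus the witness columns."""

    score: int
    columns: Tuple[Tuple[str, ...], ...]
    matrix_name: str
    n_rows: int = 2

    @property
    def rows(self) -> Tuple[str, ...]:
        """Aligned rows (gapped strings), one per input sequence."""
        return tuple("".join(col[r] for col in self.columns) for r in range(self.n_rows))


def _column_score_pair(col: Tuple[str, str], model: SubstitutionModel) -> int:
    if GAP in col:
        return -model.gap_penalty
    return model.entry(col[0], col[1])


def _column_score_triplet(col: Tuple[str, str, str], model: SubstitutionModel) -> int:
    gaps = col.count(GAP)
    if gaps == 0:
        return (model.entry(col[0], col[1]) + model.entry(col[0], col[2])
                + model.entry(col[1], col[2]))
    if gaps == 1:
        res = [ch for ch in col if ch != GAP]
        return model.entry(res[0], res[1]) - model.gap_penalty
    return -2 * model.gap_penalty


def column_score(col: TypingSequence[str], model: SubstitutionModel) -> int:
    """Score of a single alignment column under the pair/triplet rules."""
    col = tuple(col)
    if len(col) == 2:
        return _column_score_pair(col, model)  # type: ignore[arg-type]
    if len(col) == 3:
        return _column_score_triplet(col, model)  # type: ignore[arg-type]
    raise ValueError("columns hold two or three symbols")


def align_pair(s1: Sequence, s2: Sequence, model: SubstitutionModel,
               traceback: bool = True) -> AlignmentResult:
    """Optimal global alignment of two sequences.

    With ``traceback=False`` only the score is computed (rolling-row DP),
    which is what the significance engine uses for scrambled replicas.
    """
    a, b = model.encode(s1), model.encode(s2)
    g = model.gap_penalty
    if not traceback:
        score = int(_dp.pair_score(a, b, model.matrix, g))
        return AlignmentResult(score=score, columns=(), matrix_name=model.name, n_rows=2)
    H = _dp.pair_table(a, b, model.matrix, g)
    i, j = len(a), len(b)
    S = model.matrix
    cols: List[Tuple[str, str]] = []
    r1, r2 = s1.residues, s2.residues
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]:
            cols.append((r1[i - 1], r2[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and h == H[i - 1, j] - g:
            cols.append((r1[i - 1], GAP))
            i -= 1
        else:
            cols.append((GAP, r2[j - 1]))
            j -= 1
    cols.reverse()
    return AlignmentResult(score=int(H[len(a), len(b)]), columns=tuple(cols),
                           matrix_name=model.name, n_rows=2)


_TRIPLET_MOVES = (
    (1, 1, 1),
    (1, 1, 0), (1, 0, 1), (0, 1, 1),
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
)


def align_triplet(s1: Sequence, s2: Sequence, s3: Sequence, model: SubstitutionModel,
                  traceback: bool = True) -> AlignmentResult:
    """Optimal global alignment of three sequences (sum-of-pairs column score).

    Realized by three-dimensional DP over the seven non-empty advance
    patterns per cell.
    """
    a, b, c = model.encode(s1), model.encode(s2), model.encode(s3)
    g = model.gap_penalty
    if not traceback:
        score = int(_dp.triplet_score(a, b, c, model.matrix, g))
        return AlignmentResult(score=score, columns=(), matrix_name=model.name, n_rows=3)
    E = _dp.triplet_table(a, b, c, model.matrix, g)
    S = model.matrix
    enc = (a, b, c)
    res = (s1.residues, s2.residues, s3.residues)
    pos = [len(a), len(b), len(c)]
    cols: List[Tuple[str, str, str]] = []
    while any(pos):
        e = E[pos[0], pos[1], pos[2]]
        for move in _TRIPLET_MOVES:
            if any(m > p for m, p in zip(move, pos)):
                continue
            prev = tuple(p - m for p, m in zip(pos, move))
            consumed = [enc[r][pos[r] - 1] for r in range(3) if move[r]]
            if len(consumed) == 3:
                step = (S[consumed[0], consumed[1]] + S[consumed[0], consumed[2]]
                        + S[consumed[1], consumed[2]])
            elif len(consumed) == 2:
                step = S[consumed[0], consumed[1]] - g
            else:
                step = -2 * g
            if e == E[prev[0], prev[1], prev[2]] + step:
                cols.append(tuple(
                    res[r][pos[r] - 1] if move[r] else GAP for r in range(3)
                ))  # type: ignore[arg-type]
                pos = list(prev)
                break
        else:  # pragma: no cover - DP guarantees a predecessor
            raise RuntimeError("traceback failed to find a predecessor cell")
    cols.reverse()
    return AlignmentResult(score=int(E[len(a), len(b), len(c)]), columns=tuple(cols),
                           matrix_name=model.name, n_rows=3)


def percent_identity(s1: Sequence, s2: Sequence,
                     models: TypingSequence[SubstitutionModel]) -> float:
    """Percent identity averaged over the optimal tracebacks under each model.

    For each model, identity is 100 x (identical residue-residue columns) /
    (total alignment columns); the result is the arithmetic mean over models.
    """
    if not models:
        raise ValueError("percent_identity requires at least one substitution model")
    values = []
    for model in models:
        aln = align_pair(s1, s2, model, traceback=True)
        identical = sum(1 for x, y in aln.columns if x == y and x != GAP)
        values.append(100.0 * identical / len(aln.columns))
    return float(sum(values) / len(values))
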