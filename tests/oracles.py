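"""Independent test oracles: exhaustive enumeration of global alignments.

These deliberately avoid dynamic-programming tables: plain recursion over
alignment moves enumerates every global alignment of the inputs, so the
result is an independently computed maximum. Only usable for tiny inputs.
"""

from __future__ import annotations

from twilightseq.scoring import SubstitutionModel


def brute_pair_score(r1: str, r2: str, model: SubstitutionModel) -> int:
    g = model.gap_penalty

    def rec(i: int, j: int) -> int:
        if i == len(r1) and j == len(r2):
            return 0
        best = None
        if i < len(r1) and j < len(r2):
            best = model.entry(r1[i], r2[j]) + rec(i + 1, j + 1)
        if i < len(r1):
            v = -g + rec(i + 1, j)
            best = v if best is None or v > best else best
        if j < len(r2):
            v = -g + rec(i, j + 1)
            best = v if best is None or v > best else best
        return best

    return rec(0, 0)


def brute_triplet_score(r1: str, r2: str, r3: str, model: SubstitutionModel) -> int:
    g = model.gap_penalty
    lens = (len(r1), len(r2), len(r3))
    seqs = (r1, r2, r3)
    moves = ((1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 1))

    def rec(i: int, j: int, k: int) -> int:
        pos = (i, j, k)
        if pos == lens:
            return 0
        best = None
        for move in moves:
            if any(p + m > L for p, m, L in zip(pos, move, lens)):
                continue
            consumed = [seqs[r][pos[r]] for r in range(3) if move[r]]
            if len(consumed) == 3:
                step = (model.entry(consumed[0], consumed[1])
                        + model.entry(consumed[0], consumed[2])
                        + model.entry(consumed[1], consumed[2]))
            elif len(consumed) == 2:
                step = model.entry(consumed[0], consumed[1]) - g
            else:
                step = -2 * g
            v = step + rec(i + move[0], j + move[1], k + move[2])
            best = v if best is None or v > best else best
        return best

    return rec(0, 0, 0)
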