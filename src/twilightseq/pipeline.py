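"""Orchestration: evaluate enumerated comparisons under one or more matrices.

Each comparison is independent given its derived RNG stream, so results do
not depend on execution order, and interrupted runs can resume from the
checkpoint log: records already present in the log are not recomputed.

When a fixed significance threshold is the only consumer of the values
(link building at a given threshold), the second matrix can be skipped as
soon as the first matrix's dissimilarity exceeds ``prune_above``: the
combined value is a max, so it can only be at least as large. Pruned records
are flagged; full evaluation is required wherever values above the cutoff
matter (threshold sweeps, embeddings).
"""

from __future__ import annotations

import itertools
import os
from typing import Dict, Iterable, List, Sequence as TypingSequence, Tuple

from .significance import (
    ComparisonRecord,
    ScrambleSchedule,
    combined_dissimilarity,
    format_record,
    pair_dissimilarity,
    read_records,
    triplet_dissimilarity,
    _COLUMNS,
)
from .scoring import SubstitutionModel
from .seqio import Sequence


def evaluate_comparison(sequences: Dict[str, Sequence], members: Tuple[str, ...],
                        models: TypingSequence[SubstitutionModel],
                        schedule: ScrambleSchedule,
                        prune_above: float | None = None,
                        ) -> Tuple[List[ComparisonRecord], ComparisonRecord]:
    """Per-matrix records plus the combined (max) record for one comparison."""
    seqs = [sequences[m] for m in members]
    per_matrix: List[ComparisonRecord] = []
    pruned = False
    for model in models:
        if len(seqs) == 2:
            rec = pair_dissimilarity(seqs[0], seqs[1], model, schedule)
        else:
            rec = triplet_dissimilarity(seqs[0], seqs[1], seqs[2], model, schedule)
        per_matrix.append(rec)
        if (prune_above is not None and rec.diss > prune_above
                and model is not models[-1]):
            pruned = True
            break
    combined = combined_dissimilarity(per_matrix)
    if pruned:
        from dataclasses import replace

        combined = replace(combined, pruned=True)
    return per_matrix, combined


def enumerate_members(sequences: TypingSequence[Sequence], mode: str,
                      ) -> List[Tuple[str, ...]]:
    ids = sorted(s.id for s in sequences)
    out: List[Tuple[str, ...]] = []
    if mode in ("pairs", "both"):
        out.extend(itertools.combinations(ids, 2))
    if mode in ("triplets", "both"):
        out.extend(itertools.combinations(ids, 3))
    if mode not in ("pairs", "triplets", "both"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    return out


def run_comparisons(sequences: TypingSequence[Sequence], mode: str,
                    models: TypingSequence[SubstitutionModel],
                    schedule: ScrambleSchedule,
                    prune_above: float | None = None,
                    checkpoint: str | os.PathLike | None = None,
                    progress: bool = False,
                    ) -> Tuple[List[ComparisonRecord], List[ComparisonRecord]]:
    """Evaluate all pairs and/or triplets; returns (per-matrix, combined) records.

    With ``checkpoint`` set, every record is appended to a TSV log as soon as
    it is computed and comparisons whose combined record is already in the
    log are skipped on re-runs.
    """
    seq_map = {s.id: s for s in sequences}
    if len(seq_map) != len(sequences):
        raise ValueError("duplicate sequence ids")
    members_list = enumerate_members(sequences, mode)

    done: Dict[Tuple[str, ...], ComparisonRecord] = {}
    per_matrix_done: Dict[Tuple[str, ...], List[ComparisonRecord]] = {}
    fh = None
    if checkpoint is not None:
        if os.path.exists(checkpoint):
            for rec in read_records(checkpoint):
                if rec.matrix_name == "combined":
                    done[rec.key] = rec
                else:
                    per_matrix_done.setdefault(rec.key, []).append(rec)
        else:
            with open(checkpoint, "w") as new:
                new.write("\t".join(_COLUMNS) + "\n")
        fh = open(checkpoint, "a")

    per_matrix_records: List[ComparisonRecord] = []
    combined_records: List[ComparisonRecord] = []
    iterator: Iterable[Tuple[str, ...]] = members_list
    if progress:
        import click

        iterator = click.progressbar(members_list, label=f"{mode} comparisons")
        iterator.__enter__()
    try:
        for members in iterator:
            if members in done:
                combined_records.append(done[members])
                per_matrix_records.extend(per_matrix_done.get(members, []))
                continue
            per_matrix, combined = evaluate_comparison(
                seq_map, members, models, schedule, prune_above=prune_above)
            per_matrix_records.extend(per_matrix)
            combined_records.append(combined)
            if fh is not None:
                for rec in per_matrix:
                    fh.write(format_record(rec) + "\n")
                fh.write(format_record(combined) + "\n")
                fh.flush()
    finally:
        if progress:
            iterator.__exit__(None, None, None)
        if fh is not None:
            fh.close()
    return per_matrix_records, combined_records
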