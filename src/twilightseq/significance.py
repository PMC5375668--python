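"""Staged residue-scrambling significance engine.

The dissimilarity of a pair (or triplet) is an empirical tail probability:
the fraction of alignments of residue-scrambled replicas that score at least
as well as the authentic alignment, maximized over the scrambled members
(ties count against significance). Scrambling preserves length and exact
residue composition, so composition bias alone cannot create significance.

Stages are adaptive. Pairs: 10 scrambles per member (stop if any count > 6),
then 100 fresh scrambles (stop if any count > 20), then 1,000; results close
to the decision threshold escalate to 10,000 and 200,000. Triplets: 10, then
100 only if every member's count is below 7, then - after a Z-score screen -
1,000, with 3,000/10,000/30,000 reserved for borderline cases. A final
dissimilarity of exactly zero is replaced by a normal-CDF (Z-score) estimate
from the longest run, so downstream users never see an exact zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, List, Sequence as TypingSequence, Tuple

import numpy as np
from scipy.stats import norm

from . import _dp
from .scoring import SubstitutionModel
from .seqio import Sequence

COMBINED = "combined"

DEFAULT_PAIR_STAGES: Tuple[Tuple[int, int | None], ...] = ((10, 6), (100, 20), (1000, None))
DEFAULT_PAIR_ESCALATIONS: Tuple[int, ...] = (10_000, 200_000)
DEFAULT_TRIPLET_STAGES: Tuple[Tuple[int, int | None], ...] = ((10, 6), (100, None))
DEFAULT_TRIPLET_ESCALATIONS: Tuple[int, ...] = (1_000, 3_000, 10_000, 30_000)


@dataclass(frozen=True)
class ScrambleSchedule:
    """Stage sizes, stop counts, escalation ladder and RNG root seed.

    ``escalation_window`` is the multiplicative width of the "close to the
    threshold" band: a final-stage dissimilarity within a factor of this
    window of ``threshold`` triggers the next escalation size.
    ``zscreen_factor`` scales the threshold for the triplet Z-score screen
    that gates the expensive escalation runs.
    """

    pair_stages: Tuple[Tuple[int, int | None], ...] = DEFAULT_PAIR_STAGES
    pair_escalations: Tuple[int, ...] = DEFAULT_PAIR_ESCALATIONS
    triplet_stages: Tuple[Tuple[int, int | None], ...] = DEFAULT_TRIPLET_STAGES
    triplet_escalations: Tuple[int, ...] = DEFAULT_TRIPLET_ESCALATIONS
    threshold: float = 0.0025
    escalation_window: float = 4.0
    zscreen_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for stages, escalations, label in (
            (self.pair_stages, self.pair_escalations, "pair"),
            (self.triplet_stages, self.triplet_escalations, "triplet"),
        ):
            if not stages:
                raise ValueError(f"{label} schedule needs at least one stage")
            sizes = [size for size, _ in stages] + list(escalations)
            if any(s2 <= s1 for s1, s2 in zip(sizes, sizes[1:])):
                raise ValueError(f"{label} stage sizes must be strictly increasing: {sizes}")
            for size, stop in stages:
                if stop is not None and not (0 <= stop < size):
                    raise ValueError(f"{label} stop count {stop} must be below stage size {size}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.escalation_window < 1.0:
            raise ValueError("escalation window factor must be >= 1")

    def in_escalation_window(self, diss: float) -> bool:
        """Whether a dissimilarity is close enough to the threshold to escalate."""
        w = self.escalation_window
        return self.threshold / w <= diss <= self.threshold * w


@dataclass(frozen=True)
class ComparisonRecord:
    """One pair or triplet evaluated under one matrix (or the combined max)."""

    members: Tuple[str, ...]
    matrix_name: str
    authentic_score: int
    counts: Tuple[int, ...]
    stage_size: int
    diss: float
    z_estimated: bool = False
    seed_used: int = 0
    pruned: bool = False

    def __post_init__(self) -> None:
        if len(self.members) not in (2, 3):
            raise ValueError("a comparison holds two or three members")
        if not (0.0 <= self.diss <= 1.0):
            raise ValueError(f"dissimilarity {self.diss} outside [0, 1]")

    @property
    def key(self) -> Tuple[str, ...]:
        return tuple(sorted(self.members))


def scramble(s: Sequence, rng: np.random.Generator) -> Sequence:
    """A uniform random permutation of the residues (length and composition kept)."""
    chars = np.array(list(s.residues))
    permuted = "".join(chars[rng.permutation(len(chars))])
    return Sequence(id=f"{s.id}|scrambled", residues=permuted, alphabet=s.alphabet)


def derive_rng(root_seed: int, members: Iterable[str], matrix_name: str,
               stage: str) -> np.random.Generator:
    """Deterministic per-(comparison, matrix, stage) RNG stream.

    Streams are derived by hashing the sorted member ids together with the
    matrix and stage labels, so runs are reproducible and independent of the
    order in which comparisons are executed.
    """
    token = "|".join(sorted(members)) + f"|{matrix_name}|{stage}"
    digest = hashlib.sha256(token.encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, *words]))


def z_fallback(authentic_score: float, scrambled_scores: TypingSequence[float]) -> float:
    """Normal-CDF estimate of the upper-tail probability of the authentic score.

    Z = (authentic - mean) / sd of the scrambled scores; the returned value is
    1 - Phi(Z). Applied per scrambled member and combined by max upstream.
    """
    scores = np.asarray(scrambled_scores, dtype=float)
    if scores.size < 30:
        raise ValueError(f"Z fallback needs >= 30 scrambled scores, got {scores.size}")
    sd = scores.std()
    if sd == 0:
        raise ValueError("Z fallback undefined for a degenerate (zero variance) score set")
    z = (authentic_score - scores.mean()) / sd
    return float(norm.sf(z))


def _member_tail_probs(authentic: int, per_member_scores: List[np.ndarray]) -> List[float]:
    """Z-based upper-tail probability per scrambled member (1.0 when degenerate)."""
    probs = []
    for scores in per_member_scores:
        sd = scores.std()
        if sd == 0:
            probs.append(0.0 if authentic > scores[0] else 1.0)
        else:
            probs.append(float(norm.sf((authentic - scores.mean()) / sd)))
    return probs


class _Comparison:
    """Shared staging machinery for pair and triplet dissimilarities."""

    def __init__(self, sequences: TypingSequence[Sequence], model: SubstitutionModel,
                 schedule: ScrambleSchedule):
        self.sequences = sequences
        self.model = model
        self.schedule = schedule
        self.encoded = [model.encode(s) for s in sequences]
        self.ids = tuple(s.id for s in sequences)

    def _score_with(self, member_index: int, permuted: np.ndarray) -> int:
        parts = list(self.encoded)
        parts[member_index] = permuted
        if len(parts) == 2:
            return int(_dp.pair_score(parts[0], parts[1], self.model.matrix,
                                      self.model.gap_penalty))
        return int(_dp.triplet_score(parts[0], parts[1], parts[2], self.model.matrix,
                                     self.model.gap_penalty))

    def authentic(self) -> int:
        if len(self.encoded) == 2:
            return int(_dp.pair_score(self.encoded[0], self.encoded[1], self.model.matrix,
                                      self.model.gap_penalty))
        return int(_dp.triplet_score(self.encoded[0], self.encoded[1], self.encoded[2],
                                     self.model.matrix, self.model.gap_penalty))

    def run_stage(self, size: int, authentic: int,
                  stage_label: str) -> Tuple[List[int], List[np.ndarray]]:
        """Fresh scrambles: ``size`` per member, each aligned against the
        authentic versions of the other members."""
        counts: List[int] = []
        score_sets: List[np.ndarray] = []
        for m in range(len(self.encoded)):
            rng = derive_rng(self.schedule.seed, self.ids, self.model.name,
                             f"{stage_label}:{self.ids[m]}")
            member = self.encoded[m]
            scores = np.empty(size, dtype=np.int64)
            for r in range(size):
                scores[r] = self._score_with(m, member[rng.permutation(member.shape[0])])
            counts.append(int(np.count_nonzero(scores >= authentic)))
            score_sets.append(scores)
        return counts, score_sets

    def finalize(self, authentic: int, counts: List[int], size: int,
                 score_sets: List[np.ndarray]) -> ComparisonRecord:
        diss = max(counts) / size
        z_estimated = False
        if diss == 0.0:
            feasible = size >= 30 and all(s.std() > 0 for s in score_sets)
            if feasible:
                diss = max(z_fallback(authentic, s) for s in score_sets)
                z_estimated = True
        return ComparisonRecord(
            members=self.ids, matrix_name=self.model.name, authentic_score=authentic,
            counts=tuple(counts), stage_size=size, diss=min(diss, 1.0),
            z_estimated=z_estimated, seed_used=self.schedule.seed,
        )


def pair_dissimilarity(s1: Sequence, s2: Sequence, model: SubstitutionModel,
                       schedule: ScrambleSchedule) -> ComparisonRecord:
    """Staged scrambling dissimilarity for a pair under one substitution model."""
    cmp = _Comparison([s1, s2], model, schedule)
    authentic = cmp.authentic()
    counts: List[int] = []
    score_sets: List[np.ndarray] = []
    size = 0
    for size, stop in schedule.pair_stages:
        counts, score_sets = cmp.run_stage(size, authentic, f"stage{size}")
        if stop is not None and max(counts) > stop:
            return cmp.finalize(authentic, counts, size, score_sets)
    diss = max(counts) / size
    for esize in schedule.pair_escalations:
        if not schedule.in_escalation_window(diss):
            break
        counts, score_sets = cmp.run_stage(esize, authentic, f"stage{esize}")
        size = esize
        diss = max(counts) / size
    return cmp.finalize(authentic, counts, size, score_sets)


def triplet_dissimilarity(s1: Sequence, s2: Sequence, s3: Sequence,
                          model: SubstitutionModel,
                          schedule: ScrambleSchedule) -> ComparisonRecord:
    """Staged scrambling dissimilarity for a triplet under one substitution model.

    After the 100-scramble stage a Z-score screen decides whether the triplet
    is possibly significant; only then are the 1,000+ escalation runs spent.
    """
    cmp = _Comparison([s1, s2, s3], model, schedule)
    authentic = cmp.authentic()
    counts: List[int] = []
    score_sets: List[np.ndarray] = []
    size = 0
    for size, stop in schedule.triplet_stages:
        counts, score_sets = cmp.run_stage(size, authentic, f"stage{size}")
        if stop is not None and max(counts) > stop:
            return cmp.finalize(authentic, counts, size, score_sets)
    # Z screen on the last base stage: proceed only if every member looks
    # possibly significant.
    probs = _member_tail_probs(authentic, score_sets)
    screen_level = schedule.zscreen_factor * schedule.threshold
    if all(p <= screen_level for p in probs) and schedule.triplet_escalations:
        diss = max(counts) / size
        for i, esize in enumerate(schedule.triplet_escalations):
            if i > 0 and not schedule.in_escalation_window(diss):
                break
            counts, score_sets = cmp.run_stage(esize, authentic, f"stage{esize}")
            size = esize
            diss = max(counts) / size
    return cmp.finalize(authentic, counts, size, score_sets)


def combined_dissimilarity(records: TypingSequence[ComparisonRecord],
                           required_matrices: TypingSequence[str] | None = None,
                           ) -> ComparisonRecord:
    """Combine per-matrix records for one comparison by taking the max diss.

    A comparison is therefore significant only if it passes under every
    matrix. A single record (nucleotide identity mode) passes through.
    """
    if not records:
        raise ValueError("no per-matrix records to combine")
    keys = {r.key for r in records}
    if len(keys) != 1:
        raise ValueError(f"records describe different comparisons: {sorted(keys)}")
    names = {r.matrix_name for r in records}
    if len(names) != len(records):
        raise ValueError("duplicate matrix records for one comparison")
    if required_matrices is not None and set(required_matrices) != names:
        raise ValueError(f"expected records for matrices {sorted(required_matrices)}, got {sorted(names)}")
    worst = max(records, key=lambda r: r.diss)
    return replace(worst, matrix_name=COMBINED, pruned=any(r.pruned for r in records))


# ---------------------------------------------------------------------------
# TSV log round-trip

_COLUMNS = ["members", "matrix", "authentic_score", "counts", "stage_size",
            "diss", "z_estimated", "seed", "pruned"]


def write_records(records: Iterable[ComparisonRecord], path) -> None:
    """Write comparison records as a TSV log."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in records:
            fh.write(format_record(r) + "\n")


def format_record(r: ComparisonRecord) -> str:
    return "\t".join([
        ",".join(r.members), r.matrix_name, str(r.authentic_score),
        ",".join(map(str, r.counts)), str(r.stage_size), repr(r.diss),
        str(int(r.z_estimated)), str(r.seed_used), str(int(r.pruned)),
    ])


def read_records(path) -> List[ComparisonRecord]:
    """Read a TSV log written by :func:`write_records`."""
    out: List[ComparisonRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise ValueError(f"{path}: unexpected record log header {header}")
        for line in fh:
            if not line.strip():
                continue
            f = dict(zip(_COLUMNS, line.rstrip("\n").split("\t")))
            out.append(ComparisonRecord(
                members=tuple(f["members"].split(",")), matrix_name=f["matrix"],
                authentic_score=int(f["authentic_score"]),
                counts=tuple(int(x) for x in f["counts"].split(",")),
                stage_size=int(f["stage_size"]), diss=float(f["diss"]),
                z_estimated=bool(int(f["z_estimated"])), seed_used=int(f["seed"]),
                pruned=bool(int(f["pruned"])),
            ))
    return out
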