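"""Similarity networks from significant comparisons.

A comparison (pair or triplet) is significant when its combined dissimilarity
is at or below the threshold (default 0.0025). Every significant comparison
credits each unordered pair of its members - a triplet supports three pairs.
A link is drawn only for pairs supported by two or more significant
comparisons, and the dissimilarity reported for a link is the second smallest
among its significant comparisons, so a single false positive can neither
create a link nor set its weight.

The threshold itself is chosen by the N3/N4 sweep: the ratio of pairs
significant in at least three versus at least four comparisons jumps upward
once the threshold admits a proliferation of weakly supported pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence as TypingSequence, Tuple

import networkx as nx
import pandas as pd

from .significance import ComparisonRecord, ScrambleSchedule
from .seqio import Sequence

DEFAULT_THRESHOLD = 0.0025

Pair = FrozenSet[str]


def enumerate_comparisons(sequences: TypingSequence[Sequence] | TypingSequence[str],
                          mode: str) -> List[Tuple[str, ...]]:
    """All unordered pairs and/or triplets of sequence ids, members sorted.

    ``mode`` is one of ``pairs``, ``triplets`` or ``both``.
    """
    ids = sorted(s.id if isinstance(s, Sequence) else s for s in sequences)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if mode not in ("pairs", "triplets", "both"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    out: List[Tuple[str, ...]] = []
    if mode in ("pairs", "both"):
        if len(ids) < 2:
            raise ValueError("pair enumeration needs at least 2 sequences")
        out.extend(itertools.combinations(ids, 2))
    if mode in ("triplets", "both"):
        if len(ids) < 3:
            raise ValueError("triplet enumeration needs at least 3 sequences")
        out.extend(itertools.combinations(ids, 3))
    return out


@dataclass
class SimilarityNetwork:
    """Nodes, per-pair support counts, >= 2-support links and reported diss."""

    nodes: Tuple[str, ...]
    pair_support: Dict[Pair, int]
    links: Tuple[Pair, ...]
    reported_diss: Dict[Pair, float]
    threshold: float = DEFAULT_THRESHOLD

    def to_graph(self) -> nx.Graph:
        """Export as a networkx graph; edge weight = reported (second-smallest)
        dissimilarity, edge attribute ``support`` = comparison count."""
        g = nx.Graph(threshold=self.threshold)
        g.add_nodes_from(self.nodes)
        for pair in self.links:
            a, b = sorted(pair)
            g.add_edge(a, b, weight=self.reported_diss[pair],
                       support=self.pair_support[pair])
        return g

    def edge_table(self) -> pd.DataFrame:
        """Significant-pairs table: both ids, support, second-smallest diss."""
        rows = [
            {"id1": min(p), "id2": max(p), "support": self.pair_support[p],
             "diss": self.reported_diss[p]}
            for p in self.links
        ]
        return pd.DataFrame(rows, columns=["id1", "id2", "support", "diss"]).sort_values(
            ["diss", "id1", "id2"], ignore_index=True)


def _support_and_diss(records: Iterable[ComparisonRecord], threshold: float,
                      ) -> Tuple[Dict[Pair, int], Dict[Pair, List[float]]]:
    support: Dict[Pair, int] = {}
    diss_lists: Dict[Pair, List[float]] = {}
    for rec in records:
        if rec.diss > threshold:
            continue
        for a, b in itertools.combinations(sorted(set(rec.members)), 2):
            pair = frozenset((a, b))
            support[pair] = support.get(pair, 0) + 1
            diss_lists.setdefault(pair, []).append(rec.diss)
    return support, diss_lists


def build_network(records: TypingSequence[ComparisonRecord],
                  threshold: float = DEFAULT_THRESHOLD) -> SimilarityNetwork:
    """Apply the threshold and the >= 2-comparison link rule to combined records."""
    nodes = sorted({m for rec in records for m in rec.members})
    support, diss_lists = _support_and_diss(records, threshold)
    links = tuple(sorted((p for p, s in support.items() if s >= 2), key=sorted))
    reported = {p: sorted(diss_lists[p])[1] for p in links}
    return SimilarityNetwork(nodes=tuple(nodes), pair_support=support, links=links,
                             reported_diss=reported, threshold=threshold)


def threshold_sweep(records: TypingSequence[ComparisonRecord],
                    grid: TypingSequence[float]) -> pd.DataFrame:
    """N3/N4 table over candidate thresholds.

    N3 (N4) is the number of pairs significant in at least three (four)
    comparisons; the ratio column is NaN where N4 = 0.
    """
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    grid = list(grid)
    if any(not (0.0 < t <= 1.0) for t in grid):
        raise ValueError("grid thresholds must lie in (0, 1]")
    if any(t2 <= t1 for t1, t2 in zip(grid, grid[1:])):
        raise ValueError("grid thresholds must be ascending")
    rows = []
    for t in grid:
        support, _ = _support_and_diss(records, t)
        n3 = sum(1 for s in support.values() if s >= 3)
        n4 = sum(1 for s in support.values() if s >= 4)
        rows.append({"threshold": t, "N3": n3, "N4": n4,
                     "ratio": (n3 / n4) if n4 > 0 else float("nan")})
    return pd.DataFrame(rows, columns=["threshold", "N3", "N4", "ratio"])


def scan_one_vs_many(query_set: TypingSequence[Sequence],
                     references: TypingSequence[Sequence],
                     models, schedule: ScrambleSchedule,
                     threshold: float = DEFAULT_THRESHOLD,
                     progress: bool = False) -> pd.DataFrame:
    """Screen each query against every reference (pairwise combined diss).

    Returns a table of (query, reference, diss, significant), with queries
    ranked by number of significant hits, then by their smallest diss. Used
    for one-vs-many ORF screens against a panel of known capsid proteins.
    """
    from .pipeline import evaluate_comparison  # local import to avoid a cycle

    if not query_set or not references:
        raise ValueError("scan requires non-empty query and reference sets")
    seqs = {s.id: s for s in list(query_set) + list(references)}
    if len(seqs) != len(query_set) + len(references):
        raise ValueError("duplicate ids between queries and references")
    rows = []
    for q in query_set:
        for ref in references:
            _, combined = evaluate_comparison(seqs, (q.id, ref.id), models, schedule)
            rows.append({"query": q.id, "reference": ref.id, "diss": combined.diss,
                         "significant": combined.diss <= threshold})
    df = pd.DataFrame(rows, columns=["query", "reference", "diss", "significant"])
    hits = df.groupby("query")["significant"].sum()
    best = df.groupby("query")["diss"].min()
    df["_hits"] = df["query"].map(hits)
    df["_best"] = df["query"].map(best)
    df = df.sort_values(["_hits", "_best", "query", "diss", "reference"],
                        ascending=[False, True, True, True, True], ignore_index=True)
    return df.drop(columns=["_hits", "_best"])


def write_graphml(network: SimilarityNetwork, path) -> None:
    nx.write_graphml(network.to_graph(), path)
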