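"""Synthetic ancestor-derived sequence families for controlled experiments.

Each family is built from a random ancestor; members are derived by
independent per-site substitution with retention probability
``target_identity`` (substitutions drawn from the composition excluding the
current residue), so the realized member-ancestor identity is binomially
distributed around the target and analytically checkable. Two members of the
same family therefore share roughly ``target_identity**2`` of their sites
plus a small coincidence term - at a target of 0.35 the member-member
identity sits near 13-16%, i.e. beyond the twilight zone, which is exactly
the regime the permutation test is meant to probe.

Indels are off by default (so identity stays analytic); when enabled,
geometric length-1..indel_max insertions/deletions are applied per site.

A coding-sequence mode back-translates protein families with biased codon
choice, emulating conservation of codon choice alongside protein structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .seqio import AMINO, AMINO_RESIDUES, NUC_RESIDUES, NUCLEOTIDE, Sequence

# standard genetic code, amino acid -> codons (stop codons unused)
_CODONS: Dict[str, Tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family dataset."""

    n_families: int = 2
    members_per_family: int = 4
    ancestor_length: int = 300
    target_identity: float = 0.35
    alphabet: str = AMINO
    composition: Dict[str, float] | None = None
    seed: int = 0
    indel_rate: float = 0.0
    indel_max: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target_identity must lie in (0, 1]")
        if self.ancestor_length < 1 or self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("counts and lengths must be positive")
        if self.alphabet not in (AMINO, NUCLEOTIDE):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must lie in [0, 1)")


def _composition_arrays(spec_alphabet: str, composition: Dict[str, float] | None,
                        ) -> Tuple[np.ndarray, np.ndarray]:
    base = AMINO_RESIDUES if spec_alphabet == AMINO else NUC_RESIDUES
    letters = np.array(list(base))
    if composition is None:
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        probs = np.array([composition.get(ch, 0.0) for ch in base], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("composition assigns no mass to the alphabet")
        probs = probs / probs.sum()
    return letters, probs


def _mutate(ancestor: np.ndarray, letters: np.ndarray, probs: np.ndarray,
            retention: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at rate 1 - retention, drawing replacements from
    the composition excluding the current residue."""
    member = ancestor.copy()
    mutate = rng.random(len(member)) >= retention
    for pos in np.nonzero(mutate)[0]:
        cur = member[pos]
        mask = letters != cur
        p = probs[mask]
        member[pos] = rng.choice(letters[mask], p=p / p.sum())
    return member


def _apply_indels(member: np.ndarray, letters: np.ndarray, probs: np.ndarray,
                  rate: float, max_len: int, rng: np.random.Generator) -> np.ndarray:
    out: List[str] = []
    for ch in member:
        r = rng.random()
        if r < rate / 2:  # deletion
            continue
        out.append(ch)
        if r >= rate / 2 and r < rate:  # insertion after this site
            length = min(1 + rng.geometric(0.5) - 1, max_len)
            out.extend(rng.choice(letters, p=probs, size=length))
    if not out:
        out = [rng.choice(letters, p=probs)]
    return np.array(out)


def generate_families(spec: FamilySpec) -> Tuple[List[Sequence], pd.DataFrame]:
    """Generate ancestor-derived families plus a truth table.

    The truth table records each member's family label and realized identity
    to its (unreported) ancestor.
    """
    rng = np.random.default_rng(spec.seed)
    letters, probs = _composition_arrays(spec.alphabet, spec.composition)
    sequences: List[Sequence] = []
    rows = []
    for f in range(spec.n_families):
        ancestor = rng.choice(letters, p=probs, size=spec.ancestor_length)
        for m in range(spec.members_per_family):
            member = _mutate(ancestor, letters, probs, spec.target_identity, rng)
            identity = float((member == ancestor).mean())
            if spec.indel_rate > 0:
                member = _apply_indels(member, letters, probs, spec.indel_rate,
                                       spec.indel_max, rng)
            name = f"fam{f}_m{m}"
            sequences.append(Sequence(id=name, residues="".join(member),
                                      alphabet=spec.alphabet))
            rows.append({"id": name, "family": f"fam{f}",
                         "identity_to_ancestor": identity})
    truth = pd.DataFrame(rows, columns=["id", "family", "identity_to_ancestor"])
    return sequences, truth


def generate_coding_families(spec: FamilySpec, codon_bias: float = 0.8,
                             ) -> Tuple[List[Sequence], pd.DataFrame]:
    """Nucleotide families obtained by back-translating protein families.

    Each family fixes a preferred codon per amino acid; members use the
    preferred codon with probability ``codon_bias`` and a uniform synonymous
    codon otherwise, so codon choice is conserved within a family.
    """
    if spec.alphabet != AMINO:
        raise ValueError("coding mode back-translates amino acid families")
    proteins, truth = generate_families(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0xC0D0]))
    out: List[Sequence] = []
    per_family_pref: Dict[str, Dict[str, str]] = {}
    for seq, fam in zip(proteins, truth["family"]):
        pref = per_family_pref.setdefault(
            fam, {aa: cods[rng.integers(len(cods))] for aa, cods in _CODONS.items()})
        codons = []
        for aa in seq.residues:
            cods = _CODONS[aa]
            if rng.random() < codon_bias:
                codons.append(pref[aa])
            else:
                codons.append(cods[rng.integers(len(cods))])
        out.append(Sequence(id=f"{seq.id}_cds", residues="".join(codons),
                            alphabet=NUCLEOTIDE))
    truth = truth.assign(id=[f"{i}_cds" for i in truth["id"]])
    return out, truth


def generate_null_set(n: int, length: int, alphabet: str = AMINO, seed: int = 0,
                      composition: Dict[str, float] | None = None) -> List[Sequence]:
    """Mutually independent random sequences (non-associating controls)."""
    if n < 2:
        raise ValueError("a null set needs at least 2 sequences")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x11]))
    letters, probs = _composition_arrays(alphabet, composition)
    return [
        Sequence(id=f"null_{i}", residues="".join(rng.choice(letters, p=probs, size=length)),
                 alphabet=alphabet)
        for i in range(n)
    ]
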