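# twilightseq

Permutation-test detection of protein and coding-sequence similarity beyond
the twilight zone, with similarity networks and annealed 2D/3D embeddings.

## The problem

Major capsid proteins of icosahedral viruses preserve their fold across
billions of years while their sequences diverge past the point (roughly
10–25% pairwise identity, the "twilight zone") where BLAST-style tools can
separate homology from chance. `twilightseq` is for researchers who want to
squeeze the last drops of signal out of such sequences by brute force: it
computes optimal *global* alignments of two and three sequences at a time
and calibrates their significance empirically, by realigning thousands of
residue-scrambled replicas of the same sequences.

## The statistic

For sequences `s1, s2`, matrix `M` and linear gap penalty `g` (every gap
column costs `−g`; triplet columns score the sum of their pairwise entries,
minus `g` per gap), let `sc12 = score₂(s1, s2, M, g)` be the optimal global
alignment score. With `nᵢ` of `N` scrambled-member-`i` alignments scoring
`≥ sc12`,

    diss(s1, s2, M, g) = max(n₁/N, n₂/N)

is an empirical tail probability: small only if *neither* side's composition
can reproduce the authentic score by chance. Amino acid data must pass under
both BLOSUM45 and PAM250 (`g = 6`): `diss = max(diss_B45, diss_PAM250)`;
nucleotide (coding) data use the identity matrix with `g = 1`. `N` grows
adaptively (10 → 100 → 1000, escalating to 200,000 for borderline cases;
triplets gate the expensive stages behind a Z-score screen), and exact zeros
are replaced by a normal-CDF tail estimate. A comparison is significant at
the default threshold 0.0025; a network link requires a pair to appear in
**two or more** significant comparisons (pairwise or triplet), and the
reported link dissimilarity is the *second smallest* — so no single false
positive can create or weight a link. For figures, dissimilarities map to
display distances via `d = 1/(−ln(0.990049833749168·diss))` (diss = 1 ↦ 100)
and coordinates are fitted by simulated annealing.

## Worked example

Simulate one protein family of 3 members (ancestor length 60, per-site
retention 0.6 — member–member identity ≈ 38%) plus 3 unrelated controls,
evaluate all pairs and triplets under both matrices, and build the network:

```bash
twilightseq simulate --families 1 --members 3 --length 60 --identity 0.6 \
    --nulls 3 --seed 17 --out demo/sim
twilightseq pairs    --input demo/sim/sequences.fasta --seed 19 --max-stage 1000 --out demo/pairs
twilightseq triplets --input demo/sim/sequences.fasta --seed 19 --max-stage 1000 --prune --out demo/triplets
twilightseq network  --records demo/pairs/combined.tsv \
    --extra-records demo/triplets/combined.tsv --out demo/net
cat demo/net/edges.tsv
```

which prints:

```
15 pairs evaluated (3 significant at 0.0025)
20 triplets evaluated (1 significant at 0.0025)
3 links among 6 sequences
id1      id2      support  diss
fam0_m0  fam0_m2  2        2.3507158729470274e-15
fam0_m1  fam0_m2  2        9.384933938051377e-14
fam0_m0  fam0_m1  2        4.194153333358773e-12
```

All three within-family pairs are linked — each supported by its own
significant pairwise comparison *and* the significant family triplet
(support 2) — and none of the 12 comparisons involving a control produced a
link. The reported `diss` values are second-smallest, Z-estimated tail
probabilities (the scrambles themselves never reached the authentic scores).
`twilightseq embed --records demo/pairs/combined.tsv --seed 5 --out demo/embed`
then writes annealed 2D coordinates (`coordinates.tsv`) for plotting.

Runs are deterministic given `--seed`, checkpointed per comparison, and
resumable with `--resume`. `twilightseq scan` screens a query set (e.g. all
annotated ORFs of a genome) one-vs-many against reference capsid proteins;
`twilightseq sweep` tabulates the N3/N4 ratio used to locate the largest
safe significance threshold.

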