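# Methods

## The problem

Capsid proteins of icosahedral viruses fall into a small number of
structure-based lineages (e.g. the vertical double beta-barrel fold of the
PRD1-adenovirus lineage and the HK97 fold), yet their sequences are so
divergent — often 10–25% pairwise identity or less, the "twilight zone" —
that standard tools such as BLAST cannot distinguish homology from chance.
`twilightseq` implements a brute-force permutation-test approach that trades
CPU time for sensitivity: optimal global alignments whose significance is
calibrated empirically against residue-scrambled replicas of the very
sequences being compared.

## Alignment model

Pairs and triplets are aligned globally by dynamic programming under a
linear, per-column gap cost with end gaps penalized:

* pair column with two residues: substitution-matrix entry `M(a,b)`;
  pair column with a gap: `−g`;
* triplet column with three residues: sum of the three pairwise entries
  (sum-of-pairs score); one gap: `M(a,b) − g`; two gaps: `−2g`;
* no column consists only of gaps.

There is no gap-open/extension distinction: each gap column is priced
independently, so the recurrence has 3 (pairs) or 7 (triplets) advance
patterns per cell. Defaults: BLOSUM45 and PAM250 with `g = 6` for amino
acid sequences; the identity matrix (match 1, mismatch 0) with `g = 1` for
nucleotide (coding) sequences. Matrices ship as plain-text files in the
standard NCBI layout and are verified symmetric on load.

Ties among optimal tracebacks are broken by a fixed move preference
(fullest advance first, then one-gap moves in sequence order, then single
advances). The optimal *score* is tie-free; column-level quantities such as
percent identity (identical columns / total columns, averaged over the
optimal tracebacks under each matrix) can depend on the tie rule, which is
why it is fixed and documented. Whether terminal gap columns should be
discounted is not determined by the scoring rules alone; this implementation
penalizes them like internal gaps (true global alignment), consistent with
the empty-prefix recurrences.

The score-only kernels (rolling row/plane, numba-compiled) run at roughly
3×10⁸ DP cells per second on one core; the full-table variants retain the
traceback and are used only where columns are needed.

## Significance: staged scrambling

For a pair `(s1, s2)` under matrix `M`, the authentic score `sc12` is
compared against alignments in which one member is replaced by a uniform
random permutation of its residues (`scramble`), preserving length and exact
composition. With `n_i` the number of scrambled-member-`i` scores `≥ sc12`
(ties count against significance) out of `N` per member, the dissimilarity
is `diss = max(n1/N, n2/N)` — an empirical tail probability maximized over
the scrambled sides, and over matrices for amino acid data
(`diss = max(diss_BLOSUM45, diss_PAM250)`, so significance requires passing
under both).

Stages are adaptive so that obvious non-matches are cheap:

* pairs: `N = 10` (stop if any `n_i > 6`), else fresh `N = 100` (stop if
  any `n_i > 20`), else fresh `N = 1000`; a result within a factor of 4 of
  the decision threshold (the *escalation window*) is redone at `N = 10000`
  and, if still borderline, `N = 200000`, reporting the longest run;
* triplets: `N = 10`, continued to `N = 100` only if all three counts are
  below 7; a Z-score screen on the 100-stage scores (all three upper-tail
  estimates ≤ 10× threshold) gates escalation to `N = 1000`, with
  3000/10000/30000 attempted in increasing order only while the result
  remains inside the escalation window.

Counts are over the current stage's fresh scrambles only, never cumulative.
If the final stage yields exactly zero counts, the dissimilarity is
estimated per member from the normal CDF of the Z-score of the authentic
score against that member's scrambled scores (`1 − Φ(Z)`, combined by max)
and flagged `z_estimated`, so downstream consumers never see an exact zero.

Randomness is fully reproducible: each (comparison, matrix, stage, member)
tuple derives its own RNG stream by hashing the sorted member ids, so
results are independent of execution order and worker scheduling, and
interrupted runs resume from the checkpoint log.

### Calibration properties — what holds and what does not

Under the null (unrelated sequences of matched composition), each side's
tail probability is marginally uniform, but `diss` is the **max** of two
imperfectly correlated estimates and is therefore *stochastically larger
than uniform*: a valid, conservative p-value-like quantity rather than an
exactly uniform one. Measured on 1000 unrelated length-100 nucleotide pairs,
`P(diss ≤ 0.5) ≈ 0.36` and `P(diss ≤ 0.25) ≈ 0.16`; the low tail
(`α ≤ 0.1`), which is all that matters at the 0.0025 decision threshold,
agrees with uniform within Monte-Carlo error. Early stopping adds further
conservative bias mid-range (a stage-1 stop can only record `diss ≥ 0.7`).
This behaviour is a structural property of the max rule, insensitive to
sequence length (50–200) and alphabet, and the test suite asserts the
conservative direction rather than exact uniformity.

## Network construction

A comparison is significant iff its combined dissimilarity is ≤ the
threshold (inclusive; default 0.0025). Each significant comparison credits
every unordered pair of its members — a triplet supports three pairs. Links
require support ≥ 2, and the dissimilarity reported for a link is the
*second smallest* among its significant comparisons; both rules ensure a
single false positive can neither create a link nor set its weight. The
threshold itself is located by the N3/N4 sweep: the ratio of pairs
significant in ≥ 3 versus ≥ 4 comparisons is flat near 1 while supports are
genuine and jumps upward once the threshold admits a proliferation of
weakly supported (likely false) pairs.

The one-vs-many scan mode evaluates every query × reference pair and ranks
queries by number of significant hits, then smallest dissimilarity — the
workflow used to screen annotated ORFs of a genome against a panel of known
capsid proteins.

## Embedding

For display, dissimilarities pass through the monotone map
`d = 1/(−ln(c·diss))` with `c = 0.990049833749168 = exp(−0.01)`, which
sends the maximal dissimilarity 1 to 100 and spreads near-zero values on a
log scale. Pairs missing from the input map get the maximal distance (100);
dissimilarities are floored at 10⁻⁶ before the transform as a safety net
(the Z fallback should make exact zeros impossible upstream).

Coordinates in 2D/3D minimize the squared-residual stress
`Σ_{i<j} (‖x_i − x_j‖ − d_ij)²` by simulated annealing: Gaussian
single-point perturbations whose scale decays geometrically from half the
mean target distance to ~10⁻⁴ of it, Metropolis acceptance with a geometric
temperature schedule (`T ← 0.95·T` per sweep, initial temperature 5% of the
initial stress per node), and a final zero-temperature quench during which
stress is non-increasing. The stress functional, cooling rate, move
distribution, and iteration budget are this package's own choices (the
procedure is only constrained to be an annealed stress minimization); all
are exposed as `layout(...)` parameters. On exactly embeddable inputs the
default budget recovers planar configurations' distances to well within 2%.

## Synthetic data

`generate_families` draws a random ancestor per family and derives members
by independent per-site substitution with retention probability
`target_identity` (replacements drawn from the composition excluding the
current residue), so member–ancestor identity is binomial around the target
and member–member identity is ≈ `target_identity² + (1 − target_identity²)/19`
for uniform protein composition. Indels are off by default to keep identity
analytic; optional geometric length-1–3 indels can be enabled. A coding
mode back-translates protein families with per-family preferred codons
(bias 0.8 by default), emulating codon-choice conservation. Defaults
(2 families × 4 members, ancestor length 300, retention 0.35, uniform
composition) mirror a small twilight-zone family study; `generate_null_set`
provides unrelated controls.

What the generator does *not* emulate: phylogenetic tree structure within
families, site-rate heterogeneity, realistic residue composition bias, or
domain architecture. Passing the end-to-end tests therefore demonstrates
the pipeline's bookkeeping, calibration, and specificity on idealized
divergence, not performance on real viral sequence data.

### Problem sizes used in the test suite

The published analyses at this method's native scale cost CPU-years; the
test suite uses deliberately small instances chosen to exercise every code
path: oracle equivalence on sequences of total length ≤ 9 (where exhaustive
enumeration is feasible), null calibration on 200 length-100 nucleotide
pairs, and end-to-end family recovery on 2 × 4 members of length 60 plus 4
controls with escalation capped at 1000 scrambles, over 10 seeded
replicates. At ancestor retention 0.35 the member–member identity (~13–16%)
is beyond the twilight zone, and at these short lengths the expected
permutation Z of related pairs is ~1–3: the end-to-end test therefore
asserts *specificity* (no cross-family or control links). Sensitivity is
demonstrated separately at moderate divergence (retention 0.6, member–member
~38% identity), where all within-family links are recovered.

## Known limitations

* The dissimilarity is conservative, not uniform, under the null (above);
  it is a decision statistic for a fixed low threshold, not a calibrated
  p-value across its whole range.
* Triplet alignment is O(L³) per evaluation; deep escalation stages on
  long sequences are the dominant cost, exactly as in the original
  CPU-year-scale analyses.
* Linear (non-affine) gap costs and strictly global alignment are inherent
  to the scoring definition; local similarity embedded in long unrelated
  flanks will be diluted.
* The annealed layout is a heuristic; for four or more mutually equidistant
  points in 2D (and in general for non-Euclidean dissimilarity patterns) a
  strictly positive stress is unavoidable and distances are approximations.
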