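import numpy as np
import pytest
from scipy.stats import chisquare

from twilightseq.seqio import Sequence
from twilightseq.significance import (
    ComparisonRecord,
    ScrambleSchedule,
    combined_dissimilarity,
    pair_dissimilarity,
    read_records,
    scramble,
    triplet_dissimilarity,
    write_records,
    z_fallback,
)


def nseq(ident, residues):
    return Sequence(ident, residues, "nucleotide")


def aseq(ident, residues):
    return Sequence(ident, residues, "amino")


def random_seq(rng, length, alphabet="ACGT", ident="s", tag="nucleotide"):
    return Sequence(ident, "".join(rng.choice(list(alphabet), length)), tag)


class TestScramble:
    def test_single_symbol_sequence_is_fixed(self):
        rng = np.random.default_rng(0)
        assert scramble(nseq("a", "AAAA"), rng).residues == "AAAA"

    def test_composition_preserved(self):
        rng = np.random.default_rng(1)
        s = nseq("a", "ACGTACGGG")
        out = scramble(s, rng)
        assert sorted(out.residues) == sorted(s.residues)
        assert len(out.residues) == len(s.residues)
        assert "scrambled" in out.id

    def test_permutations_uniform_chi_square(self):
        """Each of the 24 permutations of ACGT appears ~1/24 of the time."""
        rng = np.random.default_rng(2)
        s = nseq("a", "ACGT")
        counts = {}
        n = 10_000
        for _ in range(n):
            counts[scramble(s, rng).residues] = counts.get(scramble(s, rng).residues, 0) + 1
        assert len(counts) == 24
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-3


class TestZFallback:
    def test_three_sigma(self):
        scores = [8, 12] * 20  # mean 10, population sd 2
        assert z_fallback(16, scores) == pytest.approx(0.00135, abs=2e-5)

    def test_at_the_mean(self):
        assert z_fallback(10, [8, 12] * 20) == pytest.approx(0.5)

    def test_two_sigma_below(self):
        assert z_fallback(6, [8, 12] * 20) == pytest.approx(0.97725, abs=1e-5)

    def test_requires_30_scores(self):
        with pytest.raises(ValueError):
            z_fallback(5, [1, 2, 3])

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            z_fallback(5, [4] * 40)


class TestSchedule:
    def test_defaults_match_staging_rules(self):
        s = ScrambleSchedule()
        assert s.pair_stages == ((10, 6), (100, 20), (1000, None))
        assert s.pair_escalations == (10_000, 200_000)
        assert s.triplet_stages == ((10, 6), (100, None))
        assert s.triplet_escalations == (1_000, 3_000, 10_000, 30_000)
        assert s.threshold == 0.0025

    def test_stage_sizes_must_increase(self):
        with pytest.raises(ValueError):
            ScrambleSchedule(pair_stages=((100, 6), (10, None)))

    def test_stop_count_below_stage_size(self):
        with pytest.raises(ValueError):
            ScrambleSchedule(pair_stages=((10, 12), (100, None)))


class TestPairDissimilarity:
    def test_identical_long_proteins_highly_significant(self, blosum45):
        rng = np.random.default_rng(3)
        res = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
        sched = ScrambleSchedule(seed=1, pair_escalations=())
        rec = pair_dissimilarity(aseq("a", res), aseq("b", res), blosum45, sched)
        assert rec.diss <= 0.001
        assert rec.z_estimated  # no scramble beats a self-alignment; Z fallback kicks in
        assert rec.stage_size == 1000

    def test_single_symbol_pair_is_maximally_dissimilar(self, nuc_identity):
        # every scramble ties the authentic score, ties count against significance
        sched = ScrambleSchedule(seed=2)
        rec = pair_dissimilarity(nseq("a", "AAAA"), nseq("b", "AAAA"), nuc_identity, sched)
        assert rec.diss == 1.0
        assert rec.stage_size == 10  # stopped at the first stage

    def test_early_stop_bounds(self, nuc_identity):
        """Stage-1 stops force diss >= 0.7; stage-2 stops force diss >= 0.21."""
        rng = np.random.default_rng(4)
        sched = ScrambleSchedule(seed=3, pair_escalations=())
        seen_sizes = set()
        for i in range(30):
            s1 = random_seq(rng, 50, ident=f"x{i}")
            s2 = random_seq(rng, 50, ident=f"y{i}")
            rec = pair_dissimilarity(s1, s2, nuc_identity, sched)
            seen_sizes.add(rec.stage_size)
            if rec.stage_size == 10:
                assert rec.diss >= 0.7
            elif rec.stage_size == 100:
                assert rec.diss >= 0.21
        assert 10 in seen_sizes  # random pairs do hit the early stop

    def test_determinism_bitwise(self, nuc_identity):
        rng = np.random.default_rng(5)
        s1, s2 = random_seq(rng, 60, ident="a"), random_seq(rng, 60, ident="b")
        sched = ScrambleSchedule(seed=42)
        assert (pair_dissimilarity(s1, s2, nuc_identity, sched)
                == pair_dissimilarity(s1, s2, nuc_identity, sched))

    def test_member_order_does_not_change_diss(self, nuc_identity):
        rng = np.random.default_rng(6)
        s1, s2 = random_seq(rng, 40, ident="a"), random_seq(rng, 40, ident="b")
        sched = ScrambleSchedule(seed=7)
        r_ab = pair_dissimilarity(s1, s2, nuc_identity, sched)
        r_ba = pair_dissimilarity(s2, s1, nuc_identity, sched)
        assert r_ab.diss == r_ba.diss  # per-member RNG streams hash sorted ids


class TestTripletDissimilarity:
    def test_three_identical_proteins_highly_significant(self, blosum45):
        rng = np.random.default_rng(8)
        res = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
        sched = ScrambleSchedule(seed=9, triplet_escalations=(1000,))
        rec = triplet_dissimilarity(aseq("a", res), aseq("b", res), aseq("c", res),
                                    blosum45, sched)
        assert rec.diss <= 0.001
        assert rec.stage_size == 1000  # passed the Z screen and escalated

    def test_random_triplets_stop_early_unless_all_counts_small(self, nuc_identity):
        """Continuation past stage 1 requires every member count < 7."""
        rng = np.random.default_rng(10)
        sched = ScrambleSchedule(seed=11, triplet_escalations=())
        for i in range(10):
            seqs = [random_seq(rng, 40, ident=f"s{i}{j}") for j in range(3)]
            rec = triplet_dissimilarity(*seqs, nuc_identity, sched)
            if rec.stage_size == 10:
                assert max(rec.counts) > 6
            else:
                # reached stage 2, so stage 1 counts were all < 7; final record
                # reports the 100-scramble stage
                assert rec.stage_size == 100

    def test_max_rule_over_three_counts(self):
        rec = ComparisonRecord(members=("a", "b", "c"), matrix_name="identity",
                               authentic_score=5, counts=(2, 9, 0), stage_size=10,
                               diss=0.9)
        assert rec.diss == max(rec.counts) / rec.stage_size


class TestCombined:
    def rec(self, diss, matrix, members=("a", "b")):
        return ComparisonRecord(members=members, matrix_name=matrix, authentic_score=10,
                                counts=(1, 1), stage_size=1000, diss=diss)

    def test_max_over_matrices(self):
        combined = combined_dissimilarity(
            [self.rec(0.001, "BLOSUM45"), self.rec(0.004, "PAM250")],
            required_matrices=("BLOSUM45", "PAM250"))
        assert combined.diss == 0.004
        assert combined.matrix_name == "combined"

    def test_equal_components(self):
        combined = combined_dissimilarity(
            [self.rec(0.002, "BLOSUM45"), self.rec(0.002, "PAM250")])
        assert combined.diss == 0.002

    def test_single_record_passthrough(self):
        combined = combined_dissimilarity([self.rec(0.003, "identity")])
        assert combined.diss == 0.003

    def test_missing_matrix_is_usage_error(self):
        with pytest.raises(ValueError):
            combined_dissimilarity([self.rec(0.001, "BLOSUM45")],
                                   required_matrices=("BLOSUM45", "PAM250"))

    def test_combined_at_least_each_component(self):
        recs = [self.rec(d, m) for d, m in [(0.01, "BLOSUM45"), (0.002, "PAM250")]]
        combined = combined_dissimilarity(recs)
        assert all(combined.diss >= r.diss for r in recs)


def test_record_log_roundtrip(tmp_path):
    recs = [
        ComparisonRecord(members=("a", "b"), matrix_name="BLOSUM45", authentic_score=-3,
                         counts=(0, 2), stage_size=1000, diss=0.002, z_estimated=False,
                         seed_used=5),
        ComparisonRecord(members=("a", "b", "c"), matrix_name="combined",
                         authentic_score=12, counts=(0, 0, 0), stage_size=1000,
                         diss=1.2e-7, z_estimated=True, seed_used=5, pruned=True),
    ]
    path = tmp_path / "records.tsv"
    write_records(recs, path)
    assert read_records(path) == recs


class TestNullCalibration:
    def test_null_dissimilarity_is_a_valid_conservative_p_value(self, nuc_identity):
        """Under the null, diss is stochastically >= uniform (never anti-
        conservative), and agrees with uniform in the low tail. The max over
        the two scrambled members makes mid-range values conservative by
        construction."""
        import math

        rng = np.random.default_rng(314)
        sched = ScrambleSchedule(seed=15, pair_escalations=())
        n = 100
        diss = np.empty(n)
        for i in range(n):
            s1 = random_seq(rng, 100, ident=f"a{i}")
            s2 = random_seq(rng, 100, ident=f"b{i}")
            diss[i] = pair_dissimilarity(s1, s2, nuc_identity, sched).diss
        for alpha in (0.1, 0.25, 0.5):
            se = math.sqrt(alpha * (1 - alpha) / n)
            assert (diss <= alpha).mean() <= alpha + 3 * se
        se = math.sqrt(0.1 * 0.9 / n)
        assert abs((diss <= 0.1).mean() - 0.1) <= 3 * se
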