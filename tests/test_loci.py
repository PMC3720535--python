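import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exsirna import loci
from exsirna.annotation import Annotation
from conftest import alignment_frame


def simple_annotation():
    feats = pd.DataFrame(
        [("chr1", "exon", 250, 400, "+", "gene1"),
         ("chr1", "transposon", 100, 300, "-", "tp1"),
         ("chr1", "transposon", 5000, 5600, "+", "tp2")],
        columns=["scaffold", "type", "start", "end", "strand", "feature_id"])
    return Annotation(feats, {"chr1": 10_000})


class TestClustering:
    def test_gap_rule_merges_and_splits(self):
        # gaps of 176 (merge) and 276 (split) around the 200 bp threshold
        df = alignment_frame([("c", 100, 124, "+", 1.0),
                              ("c", 300, 324, "+", 1.0),
                              ("c", 600, 624, "+", 1.0)])
        env = loci.locus_envelopes(loci.cluster_alignments(df, 200))
        assert [(r.start, r.end) for r in env.itertuples()] == [
            (100, 324), (600, 624)]

    def test_single_alignment_single_locus(self):
        df = alignment_frame([("c", 50, 74, "+", 1.0)])
        env = loci.locus_envelopes(loci.cluster_alignments(df))
        assert [(r.start, r.end) for r in env.itertuples()] == [(50, 74)]

    def test_opposite_strands_pooled(self):
        df = alignment_frame([("c", 100, 124, "+", 1.0),
                              ("c", 110, 134, "-", 1.0)])
        clustered = loci.cluster_alignments(df)
        assert clustered["locus"].nunique() == 1

    def test_input_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [("c", int(s), int(s) + 24, "+", 1.0)
                for s in rng.integers(0, 5000, size=80)]
        a = loci.locus_envelopes(loci.cluster_alignments(alignment_frame(rows)))
        b = loci.locus_envelopes(loci.cluster_alignments(
            alignment_frame(rows[::-1])))
        pd.testing.assert_frame_equal(a, b)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(starts=st.lists(st.integers(0, 3000), min_size=1, max_size=60),
           gap=st.sampled_from([0, 50, 200]))
    def test_matches_transitive_closure_oracle(self, starts, gap):
        intervals = [(s, s + 24) for s in starts]
        df = alignment_frame([("c", s, e, "+", 1.0) for s, e in intervals])
        clustered = loci.cluster_alignments(df, gap)
        got = {}
        for row in clustered.itertuples():
            got.setdefault(row.locus, set()).add((row.start, row.end))
        expected = [{intervals[i] for i in grp}
                    for grp in loci.naive_cluster(intervals, gap)]
        assert sorted(map(sorted, got.values())) == sorted(
            map(sorted, expected))


class TestCategory:
    def test_exon_overlap_wins(self):
        # locus overlaps the exon by 50 bp and the transposon by 200 bp
        assert loci.assign_category("chr1", 100, 300,
                                    simple_annotation()) == ("exon", "+")

    def test_transposon_when_no_exon(self):
        assert loci.assign_category("chr1", 5100, 5200,
                                    simple_annotation()) == ("transposon", "+")

    def test_intergenic_default_plus_reference(self):
        assert loci.assign_category("chr1", 9000, 9100,
                                    simple_annotation()) == ("intergenic", "+")

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(KeyError, match="unknown scaffold"):
            loci.assign_category("chrX", 0, 100, simple_annotation())


class TestStrandBias:
    def test_all_sense_is_one(self):
        assert loci.strand_bias(10.0, 0.0) == 1.0

    def test_balanced_is_zero(self):
        assert loci.strand_bias(5.0, 5.0) == 0.0

    def test_weighted_example(self):
        assert loci.strand_bias(30.0, 10.0) == pytest.approx(0.5)

    def test_empty_is_missing(self):
        assert np.isnan(loci.strand_bias(0.0, 0.0))

    def test_swapping_strands_negates(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s, a = rng.random(2) * 100
            assert loci.strand_bias(s, a) == pytest.approx(
                -loci.strand_bias(a, s))


class TestSizeDistribution:
    def test_point_mass(self):
        hist = loci.size_distribution(np.full(10, 24), np.full(10, 0.1))
        assert hist[24] == pytest.approx(1.0)
        assert hist.drop(24).sum() == 0

    def test_empty_is_all_zero(self):
        assert loci.size_distribution(np.array([]), np.array([])).sum() == 0

    def test_out_of_range_pooled_into_edges(self):
        hist = loci.size_distribution(np.array([16, 30]), np.array([1.0, 2.0]))
        assert hist[18] == 1.0 and hist[25] == 2.0

    def test_uniform_class_iii_profile_is_flat(self):
        rng = np.random.default_rng(6)
        lengths = rng.integers(18, 26, size=10_000)
        hist = loci.size_distribution(lengths, np.ones(10_000))
        assert (hist <= 2 * hist.sum() / 8).all()


class TestFivePrime:
    def test_weighted_counting(self):
        comp = loci.five_prime_composition(["TGCA", "AGCA"], [3, 1])
        assert comp == {"A": 0.25, "C": 0.0, "G": 0.0, "U": 0.75}

    def test_single_base(self):
        comp = loci.five_prime_composition(["ACGT", "AAAA"])
        assert comp["A"] == 1.0

    def test_empty_is_missing(self):
        assert loci.five_prime_composition([]) == {}

    def test_recovers_planted_u_bias(self):
        rng = np.random.default_rng(7)
        n = 4000
        firsts = rng.choice(list("TACG"), p=[0.8, 0.1, 0.05, 0.05], size=n)
        seqs = [f + "CGT" for f in firsts]
        comp = loci.five_prime_composition(seqs)
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(comp["U"] - 0.8) < 3 * se
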