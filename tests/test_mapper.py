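import numpy as np
import pytest

from exsirna import mapper
from exsirna.libio import Library


def random_genome(rng, sizes):
    return {f"s{i}": "".join(rng.choice(list("ACGT"), n))
            for i, n in enumerate(sizes)}


class TestIndex:
    def test_kmer_positions_enumerated(self):
        index = mapper.build_index({"s": "ACGTACGT"}, k=4)
        assert set(index.lookup("ACGT")) == {("s", 0), ("s", 4)}

    def test_empty_scaffold_gives_empty_index(self):
        index = mapper.build_index({"s": ""}, k=4)
        assert index.lookup("ACGT") == []

    def test_seed_too_short_rejected(self):
        with pytest.raises(ValueError, match="seed too short"):
            mapper.build_index({"s": "ACGT"}, k=3)

    def test_kmers_do_not_cross_scaffold_boundary(self):
        # concatenation junction AC|GT must not produce a phantom "CGTA" hit
        index = mapper.build_index({"a": "AAAC", "b": "GTAA"}, k=4)
        assert index.lookup("ACGT") == []


class TestMapRead:
    def test_both_strand_hits(self):
        # revcomp(CGTA) = TACG occurs at 3 in ACGTACGT
        index = mapper.build_index({"s": "ACGTACGT"}, k=4)
        alns = mapper.map_read("CGTA", index)
        assert [(a.start, a.end, a.strand) for a in alns] == [
            (1, 5, "+"), (3, 7, "-")]
        assert all(a.n_hits == 2 for a in alns)

    def test_full_scaffold_single_hit(self):
        seq = "ACGTTGCATTGG"  # not its own reverse complement
        index = mapper.build_index({"s": seq}, k=4)
        alns = mapper.map_read(seq, index)
        assert [(a.start, a.end, a.strand) for a in alns] == [(0, 12, "+")]

    def test_palindromic_read_hits_both_strands(self):
        seq = "ACGTTGCAACGT"  # equal to its reverse complement
        index = mapper.build_index({"s": seq}, k=4)
        alns = mapper.map_read(seq, index)
        assert [(a.start, a.end, a.strand) for a in alns] == [
            (0, 12, "+"), (0, 12, "-")]

    def test_no_occurrence_is_empty(self):
        index = mapper.build_index({"s": "CCCCCCCC"}, k=4)
        assert mapper.map_read("AAAA", index) == []

    def test_read_shorter_than_seed_rejected(self):
        index = mapper.build_index({"s": "ACGTACGTACGT"}, k=8)
        with pytest.raises(ValueError, match="shorter than seed"):
            mapper.map_read("ACGT", index)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        genome = random_genome(rng, [400])
        index = mapper.build_index(genome, k=6)
        for _ in range(25):
            start = rng.integers(0, 380)
            read = genome["s0"][start:start + 20]
            fwd = mapper.map_read(read, index)
            rev = mapper.map_read(mapper.revcomp(read), index)
            flipped = sorted((a.scaffold, a.start, a.end,
                              "-" if a.strand == "+" else "+") for a in rev)
            assert sorted((a.scaffold, a.start, a.end, a.strand)
                          for a in fwd) == flipped

    def test_index_matches_naive_scan(self):
        rng = np.random.default_rng(4)
        genome = random_genome(rng, [3000, 2000])
        index = mapper.build_index(genome, k=8)
        for _ in range(100):
            scaffold = "s0" if rng.random() < 0.5 else "s1"
            start = rng.integers(0, len(genome[scaffold]) - 25)
            read = genome[scaffold][start:start + int(rng.integers(18, 26))]
            if rng.random() < 0.5:
                read = mapper.revcomp(read)
            assert mapper.map_read(read, index) == mapper.naive_map_read(
                read, genome)


class TestMapLibrary:
    def test_multi_hit_weight_split(self):
        block = "ACGTTACGGATCCTAGGCAT"
        genome = {"s": block + "TT" + block}
        index = mapper.build_index(genome, k=6)
        lib = Library("x", reads={block: 10})
        table = mapper.map_library(lib, index)
        assert len(table) == 2
        assert list(table["weight"]) == [5.0, 5.0]
        assert lib.total_mapped == 10

    def test_unmappable_read_excluded_from_total(self):
        genome = {"s": "ACGTTACGGATCCTAGGCAT"}
        index = mapper.build_index(genome, k=6)
        lib = Library("x", reads={"ACGTTACGGATCC": 4, "G" * 15: 9})
        mapper.map_library(lib, index)
        assert lib.total_mapped == 4

    def test_unique_policy_drops_multimappers(self):
        block = "ACGTTACGGATCCTAGGCAT"
        genome = {"s": block + "TT" + block}
        index = mapper.build_index(genome, k=6)
        lib = Library("x", reads={block: 10, "ACGTTACGGATCCTA" + "GGCATTT": 1})
        table = mapper.map_library(lib, index, multi="unique")
        assert (table["n_hits"] == 1).all()
        # multimapper still counts toward the mapped total
        assert lib.total_mapped == 11

    def test_simulated_reads_all_map(self, default_panel):
        sim, _res = default_panel
        lib = sim.libraries["wt"]
        assert lib.total_mapped == lib.total_raw
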