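import numpy as np
import pandas as pd
import pytest

from exsirna import simdata
from exsirna.mapper import revcomp
from exsirna.simdata import SimConfig, generate_genome, simulate_libraries
from conftest import small_config


class TestGenerateGenome:
    def test_degenerate_config_empty_outputs(self):
        cfg = small_config(loci_per_class={"I": 0, "II": 0, "III": 0, "IV": 0})
        genome, annotation, truth = generate_genome(cfg)
        assert len(truth) == 0
        assert len(annotation.features) == 0
        assert len(genome) == cfg.n_scaffolds

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=1)
        g1, _a1, t1 = generate_genome(cfg)
        g2, _a2, t2 = generate_genome(small_config(seed=1))
        assert g1 == g2
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_different_genome(self):
        g1, _, _ = generate_genome(small_config(seed=1))
        g2, _, _ = generate_genome(small_config(seed=2))
        assert g1 != g2

    def test_planted_loci_never_overlap(self):
        # all-pairs interval scan over the truth table
        _g, _a, truth = generate_genome(SimConfig(seed=1))
        rows = list(truth.itertuples(index=False))
        for i, a in enumerate(rows):
            for b in rows[i + 1:]:
                if a.scaffold == b.scaffold:
                    assert a.end <= b.start or b.end <= a.start

    def test_one_exon_feature_per_locus(self):
        _g, annotation, truth = generate_genome(small_config())
        assert len(annotation.features) == len(truth)
        assert (annotation.features["type"] == "exon").all()

    def test_impossible_demand_names_constraint(self):
        cfg = small_config(loci_per_class={"I": 500, "II": 0, "III": 0,
                                           "IV": 0})
        with pytest.raises(ValueError, match="do not fit"):
            generate_genome(cfg)


class TestExpectations:
    def test_null_down_factor_equalises_genotypes(self):
        cfg = small_config(down_factor=1.0)
        _g, _a, truth = generate_genome(cfg)
        for lib in simdata.GENOTYPE_LIBRARIES:
            assert np.allclose(truth[f"exp_{lib}"], truth["exp_wt"])

    def test_dependency_patterns_follow_class_table(self):
        _g, _a, truth = generate_genome(small_config())
        for _, row in truth.iterrows():
            for lib in simdata.GENOTYPE_LIBRARIES[1:]:
                expected = (row["base_reads"] * 0.05
                            if lib in simdata.DOWN_IN[row["class"]]
                            else row["base_reads"])
                assert row[f"exp_{lib}"] == pytest.approx(expected)

    def test_ip_enrichment_ratio(self):
        _g, _a, truth = generate_genome(small_config())
        ratio = truth["exp_ip_wt"] / truth["exp_ip_ago1"]
        enriched = truth["class"].isin(["I", "II"])
        assert np.allclose(ratio[enriched], 16.0)
        assert np.allclose(ratio[~enriched], 1.0)


class TestSimulateLibraries:
    def test_all_panel_libraries_present(self):
        cfg = small_config()
        genome, _a, truth = generate_genome(cfg)
        libs = simulate_libraries(genome, truth, cfg)
        assert set(libs) == set(simdata.ALL_LIBRARIES)

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=3)
        genome, _a, truth = generate_genome(cfg)
        a = simulate_libraries(genome, truth, cfg)
        b = simulate_libraries(genome, truth, cfg)
        assert all(a[k].reads == b[k].reads for k in a)

    def test_every_read_is_exact_genomic_substring(self):
        # brute-force scan of both strands of the whole genome
        cfg = small_config()
        genome, _a, truth = generate_genome(cfg)
        libs = simulate_libraries(genome, truth, cfg)
        haystacks = list(genome.values())
        for lib in libs.values():
            for seq in lib.reads:
                rc = revcomp(seq)
                assert any(seq in h or rc in h for h in haystacks)

    def test_library_totals_conserve_expectations(self):
        # totals across seeds stay within Poisson bounds of expectation
        devs = []
        for seed in range(10):
            cfg = small_config(seed=seed)
            genome, _a, truth = generate_genome(cfg)
            libs = simulate_libraries(genome, truth, cfg)
            expected = (truth["exp_wt"].sum()
                        + simdata.expected_background(truth, cfg, "wt"))
            devs.append((libs["wt"].total_raw - expected) / np.sqrt(expected))
        assert np.mean(np.abs(devs)) < 3

    def test_class_iii_reads_exclusively_sense(self):
        cfg = small_config(
            loci_per_class={"I": 0, "II": 0, "III": 4, "IV": 0},
            background_fraction=0.0, ip_carryover_loci=0)
        genome, _a, truth = generate_genome(cfg)
        libs = simulate_libraries(genome, truth, cfg)
        sense_seqs = []
        for row in truth.itertuples(index=False):
            segment = genome[row.scaffold][row.start:row.end]
            sense_seqs.append(segment if row.strand == "+"
                              else revcomp(segment))
        for seq in libs["wt"].reads:
            assert any(seq in s for s in sense_seqs)

    def test_unsatisfiable_profile_names_locus(self):
        # a poly-A locus on the sense strand has no 5'-U windows
        genome = {"s": "A" * 2000}
        truth = pd.DataFrame([{
            "locus_id": "planted_0000", "scaffold": "s", "start": 500,
            "end": 900, "class": "II", "strand": "+", "sense_fraction": 1.0,
            "fp_A": 0.07, "fp_C": 0.07, "fp_G": 0.07, "fp_T": 0.79,
            "base_reads": 100.0}])
        cfg = small_config(background_fraction=0.0, ip_carryover_loci=0)
        cfg.strand_profile["II"] = 1.0
        truth = simdata._add_expectations(truth, cfg)
        with pytest.raises(ValueError, match="planted_0000"):
            simulate_libraries(genome, truth, cfg)

    def test_mean_wt_to_dcl2_ratio_recovers_down_factor(self):
        # class-I-only panel: WT/dcl-2 library totals estimate 1/down_factor
        ratios = []
        for seed in range(50):
            cfg = small_config(
                seed=seed,
                loci_per_class={"I": 3, "II": 0, "III": 0, "IV": 0},
                background_fraction=0.0, ip_carryover_loci=0)
            genome, _a, truth = generate_genome(cfg)
            libs = simulate_libraries(genome, truth, cfg)
            ratios.append(libs["wt"].total_raw / libs["dcl2"].total_raw)
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - 1 / 0.05) < 3 * se + 1e-9


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"down_factor": 0.0},
        {"down_factor": 1.5},
        {"background_fraction": 1.0},
        {"noise_dispersion": -0.1},
        {"loci_per_class": {"I": -1}},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()

    def test_profiles_must_sum_to_one(self):
        cfg = SimConfig()
        cfg.fp_profile["I"]["A"] = 0.5
        with pytest.raises(ValueError, match="fp_profile"):
            cfg.validate()
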