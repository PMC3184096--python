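"""The synthetic study generator: determinism, conservation, calibration."""

import numpy as np
import pytest

from xenomir.config import PipelineConfig, METASTATIC, NON_METASTATIC
from xenomir.novel import nussinov_fold
from xenomir.simulate import (
    build_sim_truth,
    generate_hairpin_reference,
    generate_transcript_and_utr_sets,
    revcomp,
    simulate_libraries,
    simulate_microarray,
)


@pytest.fixture(scope="module")
def small_sim():
    return generate_hairpin_reference(12, seed=5, n_novel=2)


@pytest.fixture(scope="module")
def small_truth(small_sim):
    return build_sim_truth(small_sim, seed=6, n_fold_up=2, n_fold_down=2)


class TestHairpinGeneration:
    def test_same_seed_identical_output(self):
        a = generate_hairpin_reference(8, seed=3, n_novel=2)
        b = generate_hairpin_reference(8, seed=3, n_novel=2)
        assert a.reference.records == b.reference.records
        assert a.genome == b.genome
        assert a.novel == b.novel

    def test_perfect_stem_reaches_arm_length_pairs(self):
        sim = generate_hairpin_reference(4, seed=9, mutation_rate=0.0)
        for seq in sim.reference.records.values():
            assert nussinov_fold(seq).pair_count >= 22

    def test_all_single_mature_means_no_star_annotation(self):
        sim = generate_hairpin_reference(10, seed=4, frac_single_mature=1.0)
        for hid in sim.reference.records:
            anns = sim.reference.matures_of(hid)
            assert len(anns) == 1
            assert not anns[0].name.endswith("*")

    def test_hairpins_embedded_at_recorded_genome_offsets(self, small_sim):
        genome = small_sim.genome["chr_sim"]
        for hid, off in small_sim.hairpin_offsets.items():
            seq = small_sim.reference.records[hid]
            assert genome[off:off + len(seq)] == seq
        for nid, info in small_sim.novel.items():
            assert genome[info["offset"]:info["offset"] + len(info["sequence"])] \
                == info["sequence"]

    def test_tiny_loop_rejected(self):
        with pytest.raises(ValueError):
            generate_hairpin_reference(2, loop_len=2, seed=0)


class TestLibrarySimulation:
    def test_read_count_is_exactly_twice_depth(self, small_sim, small_truth, config):
        reads = simulate_libraries(small_sim.reference, small_truth, 2000, 0.001, 8)
        assert len(reads) == 4000

    def test_same_seed_identical_reads(self, small_sim, small_truth):
        a = simulate_libraries(small_sim.reference, small_truth, 500, 0.01, 3)
        assert a == simulate_libraries(small_sim.reference, small_truth, 500, 0.01, 3)

    def test_error_free_fixed_offset_reads_are_hairpin_substrings(
            self, small_sim, small_truth, config):
        reads = simulate_libraries(
            small_sim.reference, small_truth, 1000, 0.0, 4,
            offset_law={0: 1.0})
        sources = list(small_sim.reference.records.values())
        sources += [i["sequence"] for i in small_sim.novel.values()]
        k = len(config.adapter3)
        for rid, seq in reads:
            if ":deg:" in rid:
                continue
            insert = seq[7:-k]
            assert any(insert in s for s in sources), rid

    def test_null_fold_ratio_within_three_sigma(self, small_sim):
        truth = build_sim_truth(small_sim, seed=6, n_fold_up=0, n_fold_down=0)
        depth = 20_000
        reads = simulate_libraries(small_sim.reference, truth, depth, 0.0, 9)
        per_lib = {METASTATIC: {}, NON_METASTATIC: {}}
        for rid, _ in reads:
            _, lib, unit, _ = rid.split(":", 3)
            per_lib[lib][unit] = per_lib[lib].get(unit, 0) + 1
        for unit, p in truth.abundance.items():
            if p * depth < 200:
                continue
            k1 = per_lib[METASTATIC].get(unit, 0)
            k2 = per_lib[NON_METASTATIC].get(unit, 0)
            sigma = np.sqrt(2 * depth * p * (1 - p))
            assert abs(k1 - k2) <= 3 * sigma + 1

    def test_planted_tenfold_recovered_within_three_sigma(self, small_sim):
        truth = build_sim_truth(small_sim, seed=6, n_fold_up=1, n_fold_down=0,
                                planted_fold=10.0)
        (feature,) = truth.fold_changes
        depth = 100_000
        reads = simulate_libraries(small_sim.reference, truth, depth, 0.0, 10)
        k = {METASTATIC: 0, NON_METASTATIC: 0}
        for rid, _ in reads:
            _, lib, unit, _ = rid.split(":", 3)
            if unit == feature:
                k[lib] += 1
        p = truth.abundance[feature]
        z = 1.0 + 9.0 * p          # metastatic renormalization constant
        expect_met = depth * 10 * p / z
        expect_non = depth * p
        # binomial-oracle bound on each library count, then on the ratio
        assert abs(k[METASTATIC] - expect_met) <= 3 * np.sqrt(expect_met)
        assert abs(k[NON_METASTATIC] - expect_non) <= 3 * np.sqrt(expect_non)

    def test_unnormalizable_abundance_rejected(self, small_sim, small_truth):
        import dataclasses

        broken = dataclasses.replace(
            small_truth, abundance={k: 0.0 for k in small_truth.abundance})
        with pytest.raises(ValueError):
            simulate_libraries(small_sim.reference, broken, 100, 0.0, 1)


class TestMicroarray:
    def test_null_call_rate_matches_normal_tail(self):
        from xenomir.integration import z_ratio

        # closed form: P(|z| > 1.96) = 0.05 for a standard normal
        n_genes, reps = 800, 6
        calls = total = 0
        for seed in range(reps):
            df, _ = simulate_microarray(n_genes, 0, seed=seed, flag_fraction=0.0)
            recs = z_ratio(df)
            calls += sum(r.status in ("up", "down") for r in recs)
            total += n_genes
        rate = calls / total
        sigma = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) <= 3 * sigma

    def test_identical_arrays_zero_numerators_and_degenerate_ratio(self):
        import pandas as pd

        from xenomir.integration import z_ratio

        df, _ = simulate_microarray(50, 0, seed=1, noise_sd=0.2, flag_fraction=0.0)
        df = pd.DataFrame({
            "gene": df["gene"],
            "array_metastatic": df["array_metastatic"],
            "array_non_metastatic": df["array_metastatic"],
        })
        with pytest.raises(ValueError, match="degenerate"):
            z_ratio(df, flag_cols=None)

    def test_same_seed_identical_table(self):
        a, ta = simulate_microarray(100, 10, seed=5)
        b, tb = simulate_microarray(100, 10, seed=5)
        assert a.equals(b) and ta == tb

    def test_planted_effects_called_in_direction(self):
        from xenomir.integration import z_ratio

        df, truth = simulate_microarray(500, 20, effect_sd_units=6.0, seed=2)
        recs = {r.gene: r for r in z_ratio(df)}
        hits = sum(recs[g].status == d for g, d in truth.items())
        assert hits / len(truth) >= 0.9


class TestTranscriptAndUtrSets:
    def test_planted_site_classes_and_clean_background(self, small_sim):
        from xenomir.integration import predict_targets_seed, predicted_target_genes
        from xenomir.simulate import _mature_sequences

        mirnas = _mature_sequences(small_sim.reference)
        names = sorted(mirnas)[:3]
        planted = {
            (names[0], "gene-0000"): "8mer",
            (names[1], "gene-0001"): "7mer-m8",
            (names[2], "gene-0002"): "6mer",
        }
        _, utrs = generate_transcript_and_utr_sets(
            small_sim.reference, 2, 6, planted, seed=4,
            mirna_names=names)
        preds = predict_targets_seed({n: mirnas[n] for n in names}, utrs)
        targets = predicted_target_genes(preds)
        assert "gene-0000" in targets[names[0]]
        assert "gene-0001" in targets[names[1]]
        # a 6mer-only site stays below the prediction threshold
        assert "gene-0002" not in targets.get(names[2], set())
        # unplanted pairs carry no 7mer-or-better site
        assert "gene-0003" not in set().union(*targets.values())

    def test_same_seed_identical_sequences(self, small_sim):
        a = generate_transcript_and_utr_sets(small_sim.reference, 3, 4, {}, seed=9)
        b = generate_transcript_and_utr_sets(small_sim.reference, 3, 4, {}, seed=9)
        assert a == b

    def test_degradation_reads_absorbed_by_transcripts(self, small_sim):
        tx, _ = generate_transcript_and_utr_sets(small_sim.reference, 3, 2, {}, seed=2)
        truth = build_sim_truth(small_sim, seed=6, transcripts=tx)
        assert any(k.startswith("deg:") for k in truth.abundance)
        reads = simulate_libraries(small_sim.reference, truth, 3000, 0.0, 5)
        deg = [seq for rid, seq in reads if ":deg:" in rid]
        assert deg, "degradation channel produced no reads at this depth"
        for seq in deg[:50]:
            insert = seq[7:seq.find("TCGTATG", 7)]
            assert any(insert in t for t in tx.values())
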