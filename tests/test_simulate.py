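"""Synthetic-data generator: determinism, planted truth, calibration."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

from butyrnet.consensus import (
    VALIDATION_SOURCES,
    anticorrelation_filter,
    build_consensus,
)
from butyrnet.de import PRESETS, direction_map, records_to_frame, select_candidates
from butyrnet.simulate import (
    SimulationConfig,
    generate_de_table,
    generate_gene_sets,
    generate_ppi_edges,
    generate_splicing_events,
    generate_synergy_readouts,
    generate_target_predictions,
    gene_ids,
    simulate_truth,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_regulated": 1.5},
            {"frac_regulated": -0.1},
            {"event_type_mix": (0.5, 0.5, 0.5, 0.0, 0.0)},
            {"event_type_mix": (1.0, 0.0, 0.0, 0.0)},
            {"effect_log2fc": -1.0},
            {"coverage_mean": 0.0},
            {"true_cdi": -0.5},
            {"n_replicates": 1},
            {"set_size_range": (5, 3)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestDeterminism:
    def test_identical_seed_bit_identical_tables(self, small_config):
        r1, t1 = generate_de_table(small_config, "protein_coding")
        r2, t2 = generate_de_table(small_config, "protein_coding")
        assert records_to_frame(r1).equals(records_to_frame(r2))
        assert t1.true_pairs == t2.true_pairs

    def test_different_seed_differs(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        r1, _ = generate_de_table(small_config, "protein_coding")
        r2, _ = generate_de_table(other, "protein_coding")
        assert not records_to_frame(r1).equals(records_to_frame(r2))

    def test_substreams_independent(self, small_config):
        """Interleaving another generator call does not perturb a stream."""
        truth = simulate_truth(small_config)
        r1, _ = generate_de_table(small_config, "miRNA", truth)
        generate_ppi_edges(small_config, gene_ids(small_config.n_mrna))
        generate_synergy_readouts(small_config)
        r2, _ = generate_de_table(small_config, "miRNA", truth)
        assert records_to_frame(r1).equals(records_to_frame(r2))

    def test_ppi_edges_deterministic(self, small_config):
        ids = gene_ids(small_config.n_mrna)
        assert generate_ppi_edges(small_config, ids) == generate_ppi_edges(
            small_config, ids
        )


class TestTruthAndDeTables:
    def test_planted_pairs_anticorrelated(self, small_config):
        truth = simulate_truth(small_config)
        assert len(truth.true_pairs) == small_config.n_planted_pairs
        for mirna, gene in truth.true_pairs:
            assert (
                truth.regulated_mirnas[mirna] != truth.regulated_mrnas[gene]
            )

    def test_no_signal_strict_null_selects_nothing(self):
        config = SimulationConfig(
            seed=2, n_mrna=500, n_mirna=50, frac_regulated=0.0,
            n_planted_pairs=0, strict_null=True,
        )
        records, truth = generate_de_table(config, "protein_coding")
        assert truth.regulated_mrnas == {}
        assert select_candidates(records, PRESETS["mrna"]) == []

    def test_planted_count_and_threshold_scan(self):
        """Exactly n*frac records carry planted signal; the count passing the
        mRNA thresholds equals planted minus sub-floor, by brute-force scan."""
        config = SimulationConfig(seed=1, n_mrna=1000, frac_regulated=0.1,
                                  effect_log2fc=2.5)
        records, truth = generate_de_table(config, "protein_coding")
        assert len(truth.regulated_mrnas) == 100
        planted = [r for r in records if r.gene_id in truth.regulated_mrnas]
        assert len(planted) == 100
        for r in planted:
            assert abs(r.log2fc) >= config.effect_log2fc
            assert r.p_adj < PRESETS["mrna"].p_adj_cut
        n_pass = 0
        for r in records:
            sig = r.p_adj < 0.01 and abs(r.log2fc) > 1.5
            floor = max(r.mean_rpm_untreated, r.mean_rpm_treated) > 0.7
            if sig and floor:
                n_pass += 1
        selected = select_candidates(records, PRESETS["mrna"])
        assert len(selected) == n_pass
        expected_planted_pass = 100 - len(
            truth.subfloor_mrnas & set(truth.regulated_mrnas)
        )
        n_planted_selected = sum(
            1 for r in selected if r.gene_id in truth.regulated_mrnas
        )
        assert n_planted_selected == expected_planted_pass


class TestPredictions:
    def test_empty_truth_error(self, small_config):
        truth = simulate_truth(
            dataclasses.replace(small_config, n_planted_pairs=0)
        )
        with pytest.raises(ValueError):
            generate_target_predictions(truth, small_config)

    def test_zero_decoys_consensus_recovers_exactly_true_pairs(self, small_config):
        config = dataclasses.replace(small_config, n_decoy_predictions=0)
        truth = simulate_truth(config)
        preds = generate_target_predictions(truth, config)
        cons = build_consensus(
            preds, truth.regulated_mirnas, truth.regulated_mrnas
        )
        recovered = {(ia.mirna_id, ia.gene_id) for ia in anticorrelation_filter(cons)}
        assert recovered == set(truth.true_pairs)

    def test_validated_pairs_have_one_validation_source(self, small_config):
        truth = simulate_truth(small_config)
        preds = generate_target_predictions(truth, small_config)
        for pair in truth.validated_pairs:
            entries = [
                p for p in preds
                if (p.mirna_id, p.gene_id) == pair and p.source in VALIDATION_SOURCES
            ]
            assert len(entries) == 1
            assert entries[0].evidence_tier == "strong_validated"
            n_pred = sum(
                1 for p in preds
                if (p.mirna_id, p.gene_id) == pair and p.source not in VALIDATION_SOURCES
            )
            assert n_pred >= 1

    def test_decoys_fail_for_controlled_reasons(self, small_config):
        """With decoys present, consensus + anti-correlation still returns
        exactly the planted pairs (every decoy fails some stage)."""
        truth = simulate_truth(small_config)
        preds = generate_target_predictions(truth, small_config)
        cons = build_consensus(preds, truth.regulated_mirnas, truth.regulated_mrnas)
        anti = {(ia.mirna_id, ia.gene_id) for ia in anticorrelation_filter(cons)}
        assert anti == set(truth.true_pairs)
        # some decoys survive consensus but die at anti-correlation
        assert len(cons) > len(truth.true_pairs)


class TestPpi:
    def test_tree_when_attachment_one(self):
        config = SimulationConfig(seed=0, interactome_size=5, attachment_degree=1)
        edges = generate_ppi_edges(config, [f"N{i}" for i in range(5)])
        assert len(edges) == 4
        g = nx.Graph(edges)
        assert nx.is_connected(g)

    def test_degree_sum_twice_edge_count(self, small_config):
        edges = generate_ppi_edges(small_config, gene_ids(small_config.n_mrna))
        g = nx.Graph(edges)
        assert sum(dict(g.degree).values()) == 2 * len(edges)
        assert len(edges) == len(set(edges))  # no duplicates
        assert all(a != b for a, b in edges)  # no self-loops

    def test_too_few_nodes_error(self):
        config = SimulationConfig(seed=0, interactome_size=10)
        with pytest.raises(ValueError):
            generate_ppi_edges(config, ["a", "b"])


class TestGeneSets:
    def test_exact_sizes(self):
        config = SimulationConfig(seed=0, n_gene_sets=3, set_size_range=(5, 5))
        sets = generate_gene_sets(config, gene_ids(100))
        assert len(sets) == 3
        assert all(len(m) == 5 for m in sets.values())
        for members in sets.values():
            assert len(set(members)) == len(members)

    def test_set_size_exceeding_universe_error(self):
        config = SimulationConfig(seed=0, set_size_range=(50, 60))
        with pytest.raises(ValueError):
            generate_gene_sets(config, gene_ids(20))

    def test_enriched_set_overrepresents_designated_genes(self):
        config = SimulationConfig(seed=0, n_gene_sets=2, set_size_range=(50, 50))
        universe = gene_ids(1000)
        enriched = universe[:100]
        sets = generate_gene_sets(config, universe, enriched, odds_ratio=20.0)
        n_in = len(set(sets["CELL_CYCLE"]) & set(enriched))
        assert n_in > 15  # uniform expectation would be 5


class TestSplicingGenerator:
    def test_exact_counts_recover_true_psi(self):
        """In the noiseless limit empirical PSI equals true PSI exactly, so
        null events have delta-PSI identically zero."""
        config = SimulationConfig(
            seed=4, n_splicing_events=100, frac_splicing_regulated=0.0
        )
        events, planted = generate_splicing_events(config, exact_counts=True)
        assert planted == set()
        for ev in events:
            assert ev.delta_psi == pytest.approx(0.0, abs=1e-12)
            psis = ev.psi_replicates("untreated")
            assert len(set(psis)) == 1  # identical across replicates

    def test_planted_events_shift_by_delta(self):
        config = SimulationConfig(
            seed=4, n_splicing_events=200, frac_splicing_regulated=0.5,
            planted_delta_psi=0.4,
        )
        events, planted = generate_splicing_events(config, exact_counts=True)
        assert len(planted) == 100
        for ev in events:
            if ev.event_id in planted:
                assert ev.delta_psi == pytest.approx(0.4, abs=1e-12)

    def test_event_type_mix_recovered(self):
        """The observed skipped-exon fraction tracks the configured 60.3%."""
        config = SimulationConfig(seed=3, n_splicing_events=2000)
        events, _ = generate_splicing_events(config)
        se_frac = sum(1 for ev in events if ev.event_type == "SE") / len(events)
        assert se_frac == pytest.approx(0.603, abs=0.03)


class TestSynergyGenerator:
    def test_mean_recovery_under_noise(self):
        """At 10% CV and 4 replicates the mean recovered CDI over seeds is
        within 0.05 of the generating value (reduced seed count here; the
        full 200-seed check runs in the acceptance suite)."""
        cdis = []
        for seed in range(50):
            config = SimulationConfig(seed=seed, true_cdi=0.63, readout_cv=0.1)
            cdis.append(generate_synergy_readouts(config).cdi)
        assert np.mean(cdis) == pytest.approx(0.63, abs=0.05)

    def test_nonpositive_effects_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(effect_a=0.0)
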