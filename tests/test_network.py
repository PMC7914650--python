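"""Zero-order network extraction, miRNA integration, hub ranking, export."""

import numpy as np
import pytest

from butyrnet.network import (
    RegulatoryNetwork,
    export_network,
    import_graphml,
    integrate_mirna_edges,
    rank_hubs,
    read_edge_list,
    zero_order_subnetwork,
)
from butyrnet.simulate import SimulationConfig, generate_ppi_edges


class TestZeroOrder:
    def test_basic_example(self):
        net = zero_order_subnetwork({"a", "b", "c"}, [("a", "b"), ("a", "x")])
        assert net.nodes == {"a", "b"}
        assert net.edges() == [("a", "b")]

    def test_all_nodes_seeded_is_identity_minus_isolates(self):
        edges = [("a", "b"), ("b", "c"), ("d", "e")]
        net = zero_order_subnetwork({"a", "b", "c", "d", "e", "f"}, edges)
        assert net.nodes == {"a", "b", "c", "d", "e"}
        assert len(net.edges()) == 3

    def test_empty_seed_set_error(self):
        with pytest.raises(ValueError):
            zero_order_subnetwork(set(), [("a", "b")])

    def test_self_loops_ignored(self):
        net = zero_order_subnetwork({"a", "b"}, [("a", "a"), ("a", "b")])
        assert net.edges() == [("a", "b")]

    def test_min_degree_filter(self):
        # single-pass removal: only the degree-3 center survives min_degree=2
        edges = [("a", "b"), ("a", "c"), ("a", "d")]
        net = zero_order_subnetwork({"a", "b", "c", "d"}, edges, min_degree=2)
        assert net.nodes == {"a"}
        assert net.edges() == []

    def test_matches_exhaustive_edge_scan(self):
        """Node and edge counts match a brute-force scan on random
        scale-free interactomes with 30% seed samples."""
        rng = np.random.default_rng(17)
        for trial in range(25):
            config = SimulationConfig(
                seed=trial, interactome_size=150, attachment_degree=2, n_mrna=300
            )
            ids = [f"N{i}" for i in range(300)]
            edges = generate_ppi_edges(config, ids)
            nodes = sorted({n for e in edges for n in e})
            seeds = set(rng.choice(nodes, size=len(nodes) // 3, replace=False))
            net = zero_order_subnetwork(seeds, edges)
            kept = [e for e in edges if e[0] in seeds and e[1] in seeds]
            touched = {n for e in kept for n in e}
            assert len(net.edges()) == len(kept)
            assert net.nodes == touched
            # protein nodes never escape the seed set (zero-order closure)
            assert net.nodes <= seeds


class TestIntegrate:
    def test_empty_interactions_unchanged(self):
        net = zero_order_subnetwork({"a", "b"}, [("a", "b")])
        out = integrate_mirna_edges(net, [])
        assert out.nodes == net.nodes and out.edges() == net.edges()

    def test_table1_regulatory_edge_count(self, table1):
        """Integrating the curated table over its own gene set yields one
        regulatory edge per table row."""
        net = integrate_mirna_edges(
            RegulatoryNetwork(), table1, add_missing_genes=True
        )
        assert len(net.edges("mt")) == 24
        kinds = {net.kind(n) for n in net.nodes}
        assert kinds == {"protein", "mirna"}

    def test_skips_interactions_outside_network(self, table1):
        net = zero_order_subnetwork({"a", "b"}, [("a", "b")])
        out = integrate_mirna_edges(net, table1, add_missing_genes=False)
        assert out.nodes == {"a", "b"}

    def test_input_not_mutated(self, table1):
        net = zero_order_subnetwork({"a", "b"}, [("a", "b")])
        integrate_mirna_edges(net, table1, add_missing_genes=True)
        assert net.nodes == {"a", "b"}


class TestRankHubs:
    def test_star_graph_center_first(self):
        net = zero_order_subnetwork(
            set("cabdef"), [("c", x) for x in "abdef"]
        )
        assert rank_hubs(net, 1) == [("c", 5)]

    def test_tie_break_by_identifier(self):
        net = zero_order_subnetwork({"b", "a", "z", "y"}, [("z", "y"), ("b", "a")])
        assert [n for n, _ in rank_hubs(net, 4)] == ["a", "b", "y", "z"]

    def test_top_k_validation(self, table1):
        net = integrate_mirna_edges(RegulatoryNetwork(), table1, add_missing_genes=True)
        with pytest.raises(ValueError):
            rank_hubs(net, 0)
        with pytest.raises(ValueError):
            rank_hubs(RegulatoryNetwork(), 1)

    def test_top_hub_gene_has_five_mirna_partners(self, table1):
        """In the curated interaction table the most-connected target gene
        is EIF4G2 with five distinct miRNA partners."""
        net = integrate_mirna_edges(RegulatoryNetwork(), table1, add_missing_genes=True)
        top, degree = rank_hubs(net, 1)[0]
        assert top == "EIF4G2" and degree == 5

    def test_ranking_matches_full_sort(self):
        rng = np.random.default_rng(3)
        config = SimulationConfig(seed=9, interactome_size=80, n_mrna=300)
        edges = generate_ppi_edges(config, [f"N{i}" for i in range(300)])
        net = zero_order_subnetwork({n for e in edges for n in e}, edges)
        k = int(rng.integers(1, len(net.nodes)))
        expected = sorted(net.nodes, key=lambda n: (-net.degree(n), n))[:k]
        assert [n for n, _ in rank_hubs(net, k)] == expected


class TestExport:
    @pytest.fixture
    def mixed_net(self, table1):
        net = zero_order_subnetwork(
            {"EIF4G2", "BIRC5", "WEE1"},
            [("EIF4G2", "BIRC5"), ("BIRC5", "WEE1")],
        )
        return integrate_mirna_edges(net, table1)

    def test_graphml_round_trip(self, mixed_net, tmp_path):
        path = tmp_path / "net.graphml"
        export_network(mixed_net, path, "graphml")
        back = import_graphml(path)
        assert back.nodes == mixed_net.nodes
        assert sorted(map(tuple, map(sorted, back.edges()))) == sorted(
            map(tuple, map(sorted, mixed_net.edges()))
        )
        for n in mixed_net.nodes:
            assert back.kind(n) == mixed_net.kind(n)
            assert back.degree(n) == mixed_net.degree(n)

    def test_sif_line_count_and_relations(self, mixed_net, tmp_path):
        path = tmp_path / "net.sif"
        export_network(mixed_net, path, "sif")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == len(mixed_net.edges())
        relations = {line.split("\t")[1] for line in lines}
        assert relations <= {"pp", "mt"}
        assert path.with_suffix(".sif.attrs.tsv").exists()

    def test_sif_deterministic_bytes(self, mixed_net, tmp_path):
        p1, p2 = tmp_path / "a.sif", tmp_path / "b.sif"
        export_network(mixed_net, p1, "sif")
        export_network(mixed_net, p2, "sif")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_network_is_error(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(RegulatoryNetwork(), tmp_path / "x.sif", "sif")

    def test_unknown_format_is_error(self, mixed_net, tmp_path):
        with pytest.raises(ValueError):
            export_network(mixed_net, tmp_path / "x.bin", "bin")

    def test_read_edge_list_sif_and_tsv(self, tmp_path):
        sif = tmp_path / "e.sif"
        sif.write_text("a\tpp\tb\tc\n")
        assert read_edge_list(sif) == [("a", "b"), ("a", "c")]
        tsv = tmp_path / "e.tsv"
        tsv.write_text("a\tb\nb\tc\n")
        assert read_edge_list(tsv) == [("a", "b"), ("b", "c")]


def test_degree_equals_adjacency_recount(table1):
    """Per-node degree equals an independent adjacency recount, and the
    degree sum is twice the edge count."""
    for seed in range(5):
        config = SimulationConfig(seed=seed, interactome_size=60, n_mrna=300)
        edges = generate_ppi_edges(config, [f"N{i}" for i in range(300)])
        net = zero_order_subnetwork({n for e in edges for n in e}, edges)
        net = integrate_mirna_edges(net, table1, add_missing_genes=True)
        recount: dict[str, int] = {}
        for a, b in net.edges():
            recount[a] = recount.get(a, 0) + 1
            recount[b] = recount.get(b, 0) + 1
        for n in net.nodes:
            assert net.degree(n) == recount.get(n, 0)
        assert sum(net.degree(n) for n in net.nodes) == 2 * len(net.edges())
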