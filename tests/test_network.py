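"""Bipartite network construction, degree statistics and export round trips."""

import pytest

from netpharm.adme import CompoundRecord
from netpharm.enrichment import EnrichmentResult
from netpharm.fixtures import GENERIC_PATHWAYS, make_fixture_enrichment
from netpharm.network import (
    BipartiteNetwork,
    build_ct_network,
    build_tp_network,
    degree_stats,
    export_network,
    import_network,
    target_coverage_fraction,
)
from netpharm.targets import InteractionRecord


def cmpd(mol_id):
    return CompoundRecord(mol_id, mol_id.lower(), frozenset(["SMK"]), 30.0, 0.5)


def result(set_id, p, hits):
    return EnrichmentResult(
        set_id, set_id, len(hits), len(hits) + 5, 40, 500, p, min(1.0, 3 * p), tuple(hits)
    )


class TestBuildCT:
    def test_duplicate_interactions_collapse(self):
        compounds = [cmpd("M1"), cmpd("M2")]
        inter = [
            InteractionRecord("M1", "T1"), InteractionRecord("M1", "T2"),
            InteractionRecord("M2", "T3"), InteractionRecord("M1", "T1"),
        ]
        net = build_ct_network(compounds, inter)
        assert net.edge_count == 3
        assert net.left_nodes == ["M1", "M2"] and net.right_nodes == ["T1", "T2", "T3"]

    def test_dangling_compound_is_an_error(self):
        with pytest.raises(ValueError, match="M9"):
            build_ct_network([cmpd("M1")], [InteractionRecord("M9", "T1")])

    def test_empty_interactions_give_empty_network(self, caplog):
        with caplog.at_level("WARNING"):
            net = build_ct_network([cmpd("M1")], [])
        assert net.edge_count == 0 and net.left_nodes == []

    def test_merge_idempotence_carries_to_the_network(self):
        from netpharm.targets import merge_interactions

        compounds = [cmpd("M1"), cmpd("M2")]
        table = [InteractionRecord("M1", "T1"), InteractionRecord("M2", "T1")]
        once = build_ct_network(compounds, table)
        twice = build_ct_network(compounds, merge_interactions([table, table]))
        assert once.edges == twice.edges

    def test_colliding_raw_ids_stay_disjoint(self):
        net = BipartiteNetwork("compound", "target")
        net.add_edge("X", "X")  # same raw id on both sides
        assert net.left_nodes == ["X"] and net.right_nodes == ["X"]
        assert net.edge_count == 1


class TestDegreeStats:
    def test_star(self):
        net = build_ct_network([cmpd("M1")], [InteractionRecord("M1", f"T{i}") for i in range(5)])
        st = degree_stats(net)
        assert (st.mean_left, st.mean_right, st.edge_count) == (5.0, 1.0, 5)

    def test_complete_bipartite_3x4(self):
        compounds = [cmpd(f"M{i}") for i in range(3)]
        inter = [InteractionRecord(f"M{i}", f"T{j}") for i in range(3) for j in range(4)]
        st = degree_stats(build_ct_network(compounds, inter))
        assert st.edge_count == 12
        assert all(st.per_node_degree[f"M{i}"] == 4 for i in range(3))
        assert all(st.per_node_degree[f"T{j}"] == 3 for j in range(4))

    def test_fixture_mean_target_degree_rounds_to_eight(self, fixture_ct_network):
        st = degree_stats(fixture_ct_network)
        assert len(fixture_ct_network.right_nodes) == 116
        assert st.edge_count == 950
        assert st.mean_right == pytest.approx(950 / 116)
        assert st.mean_right_rounded == 8

    def test_handshake_identity(self, fixture_ct_network):
        st = degree_stats(fixture_ct_network)
        left = sum(st.per_node_degree[n] for n in fixture_ct_network.left_nodes)
        right = sum(st.per_node_degree[n] for n in fixture_ct_network.right_nodes)
        assert left == right == st.edge_count

    def test_empty_network_is_an_error(self):
        with pytest.raises(ValueError):
            degree_stats(BipartiteNetwork("compound", "target"))


class TestCoverage:
    @pytest.mark.parametrize(
        "gene, exact, reported",
        [("PPARG", 100 * 23 / 37, 62), ("PTGS2", 100 * 19 / 37, 51), ("NOS2", 100 * 18 / 37, 48)],
    )
    def test_printed_coverage_percentages(self, fixture_ct_network, gene, exact, reported):
        pct, rep = target_coverage_fraction(fixture_ct_network, gene)
        assert pct == pytest.approx(exact)
        assert rep == reported

    def test_unknown_target_is_an_error(self, fixture_ct_network):
        with pytest.raises(KeyError):
            target_coverage_fraction(fixture_ct_network, "NOPE")


class TestBuildTP:
    def test_each_filter_excludes_one_pathway(self):
        res = [
            result("pwA", 0.01, [f"T{i}" for i in range(9)]),   # kept
            result("pwB", 0.20, [f"T{i}" for i in range(12)]),  # p too large
            result("pwC", 0.01, ["T1", "T2", "T3"]),            # too few hits
        ]
        net = build_tp_network(res)
        assert net.right_nodes == ["pwA"]
        assert net.edge_count == 9

    def test_fdr_filter_mode(self):
        res = [result("pwA", 0.02, [f"T{i}" for i in range(9)])]  # fdr = 0.06
        assert build_tp_network(res, use_fdr=True).right_nodes == []
        assert build_tp_network(res).right_nodes == ["pwA"]

    def test_pathway_table_reproduces_published_network_size(self):
        res = make_fixture_enrichment()
        net = build_tp_network(res, exclude=GENERIC_PATHWAYS)
        assert len(net.right_nodes) == 24
        assert net.edge_count == 232
        # without excluding the catch-all set, all printed rows qualify
        full = build_tp_network(res)
        assert len(full.right_nodes) == 25
        assert full.edge_count == 260


class TestExport:
    @pytest.mark.parametrize("fmt", ["SIF", "GraphML"])
    def test_round_trip_is_identity_on_nodes_and_edges(self, tmp_path, fmt, fixture_ct_network):
        path = tmp_path / f"net.{fmt.lower()}"
        export_network(fixture_ct_network, path, fmt)
        back = import_network(path, fmt)
        assert back.left_nodes == fixture_ct_network.left_nodes
        assert back.right_nodes == fixture_ct_network.right_nodes
        assert back.edges == fixture_ct_network.edges

    def test_sif_line_count_and_relation(self, tmp_path, fixture_ct_network):
        path = tmp_path / "net.sif"
        export_network(fixture_ct_network, path, "SIF")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == fixture_ct_network.edge_count + 1  # header + one line/edge
        assert all(ln.split("\t")[1] == "targets" for ln in lines[1:])

    def test_empty_network_exports_header_only(self, tmp_path):
        path = tmp_path / "empty.sif"
        export_network(BipartiteNetwork("target", "pathway"), path, "SIF")
        assert path.read_text().startswith("# target\tmember\tpathway")
        assert import_network(path, "SIF").edge_count == 0

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(BipartiteNetwork("compound", "target"), tmp_path / "x", "dot")
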