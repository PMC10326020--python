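"""Gene-level network assembly, ranking and export formats."""

import numpy as np
import pandas as pd
import pytest

from crosslasso.ensemble import RobustLassoCoefficientMatrix
from crosslasso.network import (
    IntegratedAssociationNetwork,
    build_ian,
    export_network,
    export_rnk,
    filter_subnetwork,
    rank_genes,
    read_edge_tsv,
    read_rnk,
)

import networkx as nx


def rlcm(entries, y_ids, x_ids, provenance="rppa_rnaseq"):
    df = pd.DataFrame(
        [(y, x, c, 0.9) for (y, x), c in entries.items()],
        columns=["y_analyte", "x_analyte", "coefficient", "frequency"],
    )
    return RobustLassoCoefficientMatrix(
        entries=df, y_ids=y_ids, x_ids=x_ids, n_replicates=10, provenance=provenance
    )


def meta_table(rows):
    return pd.DataFrame(
        {"gene_symbol": [g for _, g, _ in rows], "assay": [a for _, _, a in rows]},
        index=pd.Index([i for i, _, _ in rows], name="analyte_id"),
    )


@pytest.fixture
def simple_meta():
    return meta_table([
        ("p1", "G1", "rppa"),
        ("t1", "G1", "rnaseq"),
        ("t2", "G2", "rnaseq"),
        ("peakA", "G2", "atacseq"),
    ])


class TestBuildIan:
    def test_nodes_coalesce_by_gene_and_edges_carry_magnitudes(self, simple_meta):
        r = rlcm({("p1", "t1"): 0.5, ("t1", "peakA"): -0.2}, ["p1", "t1"], ["t1", "peakA"])
        ian = build_ian(r, None, simple_meta, threshold=0.01)
        assert ian.n_nodes == 2
        assert ian.node_assays("G1") == {"rppa", "rnaseq"}
        assert ian.node_assays("G2") == {"atacseq"}
        weights = sorted(d["weight"] for _, _, d in ian.edges())
        assert weights == [0.2, 0.5]
        assert all(d["weight"] > 0 for _, _, d in ian.edges())

    def test_self_edges_link_assays_of_one_gene(self, simple_meta):
        r = rlcm({("p1", "t1"): 0.7}, ["p1"], ["t1"])
        ian = build_ian(r, None, simple_meta, threshold=0.01)
        assert ian.n_nodes == 1 and ian.n_edges == 1
        (a, b, d), = ian.edges()
        assert a == b == "G1"

    def test_threshold_is_strict_and_conserves_entry_count(self, simple_meta):
        entries = {("p1", "t2"): 0.5, ("p1", "t1"): 0.1, ("t1", "peakA"): 0.009}
        r = rlcm(entries, ["p1", "t1"], ["t1", "t2", "peakA"])
        ian = build_ian(r, None, simple_meta, threshold=0.01)
        assert ian.n_edges == 2  # 0.009 dropped; |0.1| > 0.01 kept
        comparison = build_ian(r, None, simple_meta, threshold=0.1)
        assert comparison.n_edges == 1  # |0.1| not strictly above 0.1

    def test_threshold_above_max_gives_empty_network(self, simple_meta):
        r = rlcm({("p1", "t1"): 0.5}, ["p1"], ["t1"])
        ian = build_ian(r, None, simple_meta, threshold=0.9)
        assert ian.n_edges == 0 and ian.n_nodes == 0

    def test_two_layer_pairs_merge(self, simple_meta):
        r1 = rlcm({("p1", "t2"): 0.5}, ["p1"], ["t2"], provenance="rppa_rnaseq")
        r2 = rlcm({("t2", "peakA"): 0.3}, ["t2"], ["peakA"], provenance="rnaseq_atacseq")
        ian = build_ian(r1, r2, simple_meta, threshold=0.01)
        pairs = {d["layer_pair"] for _, _, d in ian.edges()}
        assert pairs == {"rppa_rnaseq", "rnaseq_atacseq"}
        assert ian.n_edges == 2

    def test_missing_gene_symbol_rejected(self, simple_meta):
        r = rlcm({("p1", "t9"): 0.5}, ["p1"], ["t9"])
        with pytest.raises(ValueError, match="t9"):
            build_ian(r, None, simple_meta, threshold=0.01)


class TestFilterSubnetwork:
    def _chain(self):
        g = nx.MultiGraph()
        for n in "abcd":
            g.add_node(n, assays={"rnaseq"})
        for u, v in [("a", "b"), ("b", "c"), ("c", "d")]:
            g.add_edge(u, v, weight=1.0, coefficient=1.0, layer_pair="p",
                       y_analyte=u, x_analyte=v)
        return IntegratedAssociationNetwork(g)

    def test_chain_two_hops(self):
        sub = filter_subnetwork(self._chain(), ["a"], hops=2)
        assert set(sub.graph.nodes) == {"a", "b", "c"}

    def test_star_from_center_and_leaf(self):
        g = nx.MultiGraph()
        g.add_node("hub", assays={"rppa"})
        for leaf in ("l1", "l2", "l3"):
            g.add_node(leaf, assays={"rnaseq"})
            g.add_edge("hub", leaf, weight=1.0, coefficient=1.0, layer_pair="p",
                       y_analyte="hub", x_analyte=leaf)
        star = IntegratedAssociationNetwork(g)
        assert set(filter_subnetwork(star, ["hub"], 1).graph.nodes) == {"hub", "l1", "l2", "l3"}
        assert set(filter_subnetwork(star, ["l1"], 1).graph.nodes) == {"hub", "l1"}

    def test_absent_seed_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no seed gene"):
            sub = filter_subnetwork(self._chain(), ["zz"], 1)
        assert sub.n_nodes == 0


class TestRankGenes:
    def test_hand_computed_alpha(self):
        g = nx.MultiGraph()
        for n in ("g", "h", "i"):
            g.add_node(n, assays={"rnaseq"})
        g.add_edge("g", "h", weight=0.3, coefficient=0.3, layer_pair="rppa_rnaseq",
                   y_analyte="1", x_analyte="2")
        g.add_edge("g", "i", weight=0.2, coefficient=-0.2, layer_pair="rppa_rnaseq",
                   y_analyte="1", x_analyte="3")
        ian = IntegratedAssociationNetwork(g)
        ranking = rank_genes(ian, layer_sizes=(2, 3, 4))
        assert ranking.alpha("g") == pytest.approx(0.5 / 24)
        assert ranking.normalization == 24

    def test_isolated_gene_scores_zero(self):
        g = nx.MultiGraph()
        g.add_node("lonely", assays={"rppa"})
        ranking = rank_genes(IntegratedAssociationNetwork(g))
        assert ranking.alpha("lonely") == 0.0

    def test_order_invariant_to_normalization(self, rng):
        ian = random_ian(rng, 8, 12)
        order1 = list(rank_genes(ian, (1, 1, 1)).table["gene"])
        order2 = list(rank_genes(ian, (59, 3062, 9321)).table["gene"])
        assert order1 == order2

    def test_matches_bruteforce_on_random_networks(self, rng):
        for _ in range(20):
            ian = random_ian(rng, n_genes=6, n_edges=10)
            ranking = rank_genes(ian, (2, 2, 2))
            brute = {g: 0.0 for g in ian.graph.nodes}
            for a, b, d in ian.graph.edges(data=True):
                brute[a] += abs(d["coefficient"])
                if b != a:
                    brute[b] += abs(d["coefficient"])
            for gene, alpha in zip(ranking.table["gene"], ranking.table["alpha"]):
                assert alpha == pytest.approx(brute[gene] / 8.0)

    def test_adding_edge_increases_both_endpoint_alphas(self, rng):
        ian = random_ian(rng, 5, 6)
        before = rank_genes(ian)
        genes = list(ian.graph.nodes)[:2]
        ian.graph.add_edge(genes[0], genes[1], weight=0.4, coefficient=0.4,
                           layer_pair="rppa_rnaseq", y_analyte="n", x_analyte="m")
        after = rank_genes(ian)
        assert after.alpha(genes[0]) > before.alpha(genes[0])
        assert after.alpha(genes[1]) > before.alpha(genes[1])

    def test_abs_of_sum_mode_cancels_signs(self):
        g = nx.MultiGraph()
        for n in ("g", "h"):
            g.add_node(n, assays={"rnaseq"})
        g.add_edge("g", "h", weight=0.3, coefficient=0.3, layer_pair="rppa_rnaseq",
                   y_analyte="1", x_analyte="2")
        g.add_edge("g", "h", weight=0.3, coefficient=-0.3, layer_pair="rppa_rnaseq",
                   y_analyte="3", x_analyte="4")
        ian = IntegratedAssociationNetwork(g)
        assert rank_genes(ian, mode="abs_of_sum").alpha("g") == 0.0
        assert rank_genes(ian, mode="sum_abs").alpha("g") == pytest.approx(0.6)


def random_ian(rng, n_genes, n_edges):
    g = nx.MultiGraph()
    genes = [f"G{i}" for i in range(n_genes)]
    for gene in genes:
        g.add_node(gene, assays={"rnaseq"})
    for k in range(n_edges):
        a, b = rng.choice(genes, size=2)  # self-edges possible
        c = float(rng.uniform(-1, 1)) or 0.1
        g.add_edge(a, b, weight=abs(c), coefficient=c,
                   layer_pair=str(rng.choice(["rppa_rnaseq", "rnaseq_atacseq"])),
                   y_analyte=f"y{k}", x_analyte=f"x{k}")
    g.remove_nodes_from(list(nx.isolates(g)))  # an assembled network has no isolated genes
    return IntegratedAssociationNetwork(g)


class TestExports:
    def test_rnk_sorted_unique_roundtrip(self, tmp_path, rng):
        ian = random_ian(rng, 6, 9)
        ranking = rank_genes(ian)
        export_rnk(ranking, tmp_path / "g.rnk")
        lines = (tmp_path / "g.rnk").read_text().splitlines()
        assert len(lines) == len(ranking)
        cols = [ln.split("\t") for ln in lines]
        assert all(len(c) == 2 for c in cols)  # headerless two-column dialect
        scores = [float(c[1]) for c in cols]
        assert scores == sorted(scores, reverse=True)
        back = read_rnk(tmp_path / "g.rnk")
        assert list(back["alpha"]) == scores  # full precision survives

    def test_rnk_rejects_duplicate_gene(self, tmp_path):
        from crosslasso.network import GeneRanking
        table = pd.DataFrame({"gene": ["A", "A"], "alpha": [1.0, 0.5]})
        with pytest.raises(ValueError, match="duplicate"):
            export_rnk(GeneRanking(table=table, normalization=1.0), tmp_path / "g.rnk")

    def test_sif_one_line_per_edge(self, tmp_path, rng):
        ian = random_ian(rng, 4, 5)
        export_network(ian, tmp_path / "n.sif", format="sif")
        lines = (tmp_path / "n.sif").read_text().splitlines()
        assert len(lines) == ian.n_edges
        assert all(ln.split("\t")[1] == "assoc" for ln in lines)

    def test_empty_network_exports(self, tmp_path):
        empty = IntegratedAssociationNetwork(nx.MultiGraph())
        export_network(empty, tmp_path / "e.sif", format="sif")
        assert (tmp_path / "e.sif").read_text() == ""
        export_network(empty, tmp_path / "e.tsv", format="edge_tsv")
        assert (tmp_path / "e.tsv").read_text().count("\n") == 1  # header only

    def test_edge_tsv_roundtrip_reconstructs(self, tmp_path, rng):
        ian = random_ian(rng, 5, 8)
        export_network(ian, tmp_path / "edges.tsv", format="edge_tsv")
        back = read_edge_tsv(tmp_path / "edges.tsv")
        assert back.n_nodes == ian.n_nodes and back.n_edges == ian.n_edges
        assert {g: back.node_assays(g) for g in back.graph.nodes} == {
            g: ian.node_assays(g) for g in ian.graph.nodes
        }
        export_network(back, tmp_path / "edges2.tsv", format="edge_tsv")
        assert (tmp_path / "edges2.tsv").read_bytes() == (tmp_path / "edges.tsv").read_bytes()

    def test_graphml_carries_assay_sets(self, tmp_path, rng):
        ian = random_ian(rng, 4, 4)
        export_network(ian, tmp_path / "n.graphml", format="graphml")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert set(g.nodes) == set(ian.graph.nodes)
        assert all("assays" in d for _, d in g.nodes(data=True))

    def test_unknown_format_rejected(self, tmp_path, rng):
        with pytest.raises(ValueError, match="unsupported"):
            export_network(random_ian(rng, 3, 3), tmp_path / "x", format="gml")
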