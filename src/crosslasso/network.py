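"""Gene-level Integrated Association Networks (IANs), gene ranking and exports.

Robust coefficient matrices from the two layer pairs (protein~transcript and
transcript~chromatin) are coalesced into a single undirected gene-level
multigraph: nodes are gene symbols carrying the set of assays that measured
them, edges are retained coefficients with weight = |coefficient|. Parallel
edges (distinct analyte pairs mapping to the same gene pair) are preserved,
as are self-edges linking different assays of the same gene.

Gene ranking sums the weights of a gene's incident edges per layer pair and
normalizes by the product of the three layer sizes — a constant per run, so
the order is normalization-invariant; it is kept so scores are comparable
across networks from the same input sizes. The ranked list exports to the
GSEA preranked ``.rnk`` dialect; the graph exports to SIF, an edge TSV that
round-trips, and GraphML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .ensemble import RobustLassoCoefficientMatrix

#: named edge-magnitude cutoffs: loose one for display, stricter one for
#: cross-network comparison / enrichment export
DISPLAY_THRESHOLD = 0.01
COMPARISON_THRESHOLD = 0.1


@dataclass
class IntegratedAssociationNetwork:
    """Undirected gene-level multigraph with assay-annotated nodes."""

    graph: nx.MultiGraph
    display_threshold: float = DISPLAY_THRESHOLD

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        """Iterate (gene_a, gene_b, attrs) over all parallel edges."""
        return self.graph.edges(data=True)

    def node_assays(self, gene: str) -> set[str]:
        return set(self.graph.nodes[gene]["assays"])


@dataclass
class GeneRanking:
    """Genes ordered by their aggregate association weight alpha."""

    table: pd.DataFrame  # columns gene, alpha; sorted alpha desc, gene asc
    normalization: float

    def __len__(self) -> int:
        return len(self.table)

    def alpha(self, gene: str) -> float:
        hit = self.table.loc[self.table["gene"] == gene, "alpha"]
        return float(hit.iloc[0]) if len(hit) else 0.0


def _add_entries(
    g: nx.MultiGraph,
    rlcm: RobustLassoCoefficientMatrix,
    meta: pd.DataFrame,
    threshold: float,
) -> None:
    for rec in rlcm.entries.itertuples(index=False):
        if abs(rec.coefficient) <= threshold:
            continue
        for analyte in (rec.y_analyte, rec.x_analyte):
            if analyte not in meta.index:
                raise ValueError(f"analyte {analyte!r} has no gene symbol in the metadata")
        gy = str(meta.loc[rec.y_analyte, "gene_symbol"])
        gx = str(meta.loc[rec.x_analyte, "gene_symbol"])
        ay = str(meta.loc[rec.y_analyte, "assay"])
        ax = str(meta.loc[rec.x_analyte, "assay"])
        for gene, assay in ((gy, ay), (gx, ax)):
            if gene not in g:
                g.add_node(gene, assays=set())
            g.nodes[gene]["assays"].add(assay)
        g.add_edge(
            gy,
            gx,
            weight=abs(float(rec.coefficient)),
            coefficient=float(rec.coefficient),
            layer_pair=rlcm.provenance,
            y_analyte=rec.y_analyte,
            x_analyte=rec.x_analyte,
        )


def build_ian(
    rlcm_1: RobustLassoCoefficientMatrix,
    rlcm_2: RobustLassoCoefficientMatrix | None,
    meta: pd.DataFrame,
    threshold: float = DISPLAY_THRESHOLD,
) -> IntegratedAssociationNetwork:
    """Merge one or two robust coefficient matrices into a gene-level network.

    One edge per retained entry with |coefficient| strictly above
    ``threshold``; endpoints are the gene symbols of the two analytes,
    looked up in ``meta`` (DataFrame indexed by analyte id with columns
    gene_symbol, assay).
    """
    g = nx.MultiGraph()
    _add_entries(g, rlcm_1, meta, threshold)
    if rlcm_2 is not None:
        _add_entries(g, rlcm_2, meta, threshold)
    return IntegratedAssociationNetwork(graph=g, display_threshold=threshold)


def filter_subnetwork(
    ian: IntegratedAssociationNetwork, seed_genes: list[str], hops: int = 1
) -> IntegratedAssociationNetwork:
    """Induced subnetwork of every node within ``hops`` edges of a seed gene."""
    if hops < 1:
        raise ValueError("hops must be >= 1")
    present = [g for g in seed_genes if g in ian.graph]
    if not present:
        warnings.warn("no seed gene present in the network; returning an empty network", stacklevel=2)
        return IntegratedAssociationNetwork(nx.MultiGraph(), ian.display_threshold)
    keep: set[str] = set()
    for s in present:
        lengths = nx.single_source_shortest_path_length(ian.graph, s, cutoff=hops)
        keep.update(lengths)
    return IntegratedAssociationNetwork(
        graph=ian.graph.subgraph(keep).copy(), display_threshold=ian.display_threshold
    )


def rank_genes(
    ian: IntegratedAssociationNetwork,
    layer_sizes: tuple[int, ...] = (1, 1, 1),
    mode: str = "sum_abs",
) -> GeneRanking:
    """Aggregate incident edge weights into a per-gene score alpha.

    ``sum_abs`` (default) sums |coefficient| over a gene's incident edges;
    ``abs_of_sum`` sums signed coefficients within each layer pair first and
    takes the absolute value of each per-pair sum. Self-edges contribute
    once. The normalization constant is the product of ``layer_sizes`` and
    does not affect the order; ties are broken alphabetically.
    """
    if mode not in ("sum_abs", "abs_of_sum"):
        raise ValueError(f"unknown mode {mode!r}")
    if any(s < 1 for s in layer_sizes):
        raise ValueError("layer sizes must be >= 1")
    denom = 1.0
    for s in layer_sizes:
        denom *= s
    if mode == "sum_abs":
        acc: dict[str, float] = {g: 0.0 for g in ian.graph.nodes}
        for a, b, data in ian.graph.edges(data=True):
            w = abs(data["coefficient"])
            acc[a] += w
            if b != a:
                acc[b] += w
        rows = [(gene, total / denom) for gene, total in acc.items()]
    else:  # abs_of_sum: signed sums within each layer pair, |.| taken per pair
        per_pair: dict[str, dict[str, float]] = {g: {} for g in ian.graph.nodes}
        for a, b, data in ian.graph.edges(data=True):
            pair = data["layer_pair"]
            for g in (a,) if a == b else (a, b):
                per_pair[g][pair] = per_pair[g].get(pair, 0.0) + data["coefficient"]
        rows = [
            (gene, sum(abs(v) for v in sums.values()) / denom)
            for gene, sums in per_pair.items()
        ]
    table = pd.DataFrame(rows, columns=["gene", "alpha"])
    table = table.sort_values(["alpha", "gene"], ascending=[False, True], kind="stable")
    return GeneRanking(table=table.reset_index(drop=True), normalization=denom)


def export_rnk(ranking: GeneRanking, path: str | Path) -> None:
    """GSEA preranked file: headerless two-column TSV, unique gene keys,
    scores descending, full float precision."""
    genes = ranking.table["gene"]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"duplicate gene symbol in ranking: {dup!r}")
    if genes.eq("").any():
        raise ValueError("empty gene symbol in ranking")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in ranking.table.itertuples(index=False):
            fh.write(f"{rec.gene}\t{repr(float(rec.alpha))}\n")


def read_rnk(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "alpha"],
                       dtype={"gene": str}, float_precision="round_trip")


_EDGE_COLS = [
    "gene_y", "gene_x", "weight", "coefficient", "layer_pair",
    "y_analyte", "x_analyte", "y_assay", "x_assay",
]


def export_network(
    ian: IntegratedAssociationNetwork, path: str | Path, format: str = "edge_tsv"
) -> None:
    """Write the network as ``sif`` (Cytoscape), ``edge_tsv`` (lossless,
    re-importable) or ``graphml`` (carries node assay sets)."""
    if format == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for a, b, _ in ian.graph.edges(data=True):
                fh.write(f"{a}\tassoc\t{b}\n")
    elif format == "edge_tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(_EDGE_COLS) + "\n")
            for a, b, d in ian.graph.edges(data=True):
                ay = sorted(ian.graph.nodes[a]["assays"])
                fh.write(
                    f"{a}\t{b}\t{repr(float(d['weight']))}\t{repr(float(d['coefficient']))}\t"
                    f"{d['layer_pair']}\t{d['y_analyte']}\t{d['x_analyte']}\t"
                    f"{_assay_of(ian, a, d, 'y')}\t{_assay_of(ian, b, d, 'x')}\n"
                )
    elif format == "graphml":
        g = nx.MultiGraph()
        for n, d in ian.graph.nodes(data=True):
            g.add_node(n, assays=",".join(sorted(d["assays"])))
        for a, b, d in ian.graph.edges(data=True):
            g.add_edge(a, b, **d)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported network format {format!r}")


def _assay_of(ian: IntegratedAssociationNetwork, gene: str, data: dict, side: str) -> str:
    # a gene node can be multi-assay; record the assay set of the node
    return ",".join(sorted(ian.graph.nodes[gene]["assays"]))


def read_edge_tsv(path: str | Path, display_threshold: float = DISPLAY_THRESHOLD) -> IntegratedAssociationNetwork:
    """Reconstruct a network from an ``edge_tsv`` export (inverse of
    :func:`export_network` up to isolated nodes, which an IAN never has)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={c: str for c in _EDGE_COLS if c not in ("weight", "coefficient")})
    g = nx.MultiGraph()
    for rec in df.itertuples(index=False):
        for gene, assays in ((rec.gene_y, rec.y_assay), (rec.gene_x, rec.x_assay)):
            if gene not in g:
                g.add_node(gene, assays=set())
            g.nodes[gene]["assays"].update(str(assays).split(","))
        g.add_edge(
            rec.gene_y,
            rec.gene_x,
            weight=float(rec.weight),
            coefficient=float(rec.coefficient),
            layer_pair=rec.layer_pair,
            y_analyte=rec.y_analyte,
            x_analyte=rec.x_analyte,
        )
    return IntegratedAssociationNetwork(graph=g, display_threshold=display_threshold)
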