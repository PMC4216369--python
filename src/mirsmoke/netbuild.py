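"""miRNA–target network construction.

Builds bipartite miRNA–gene graphs from a target-prediction table
(filtered to predictions supported by at least six sources), optionally
restricted to a reference gene list (e.g. lung-cancer prognostic genes),
with group-tagged nodes and edges, degree statistics, and GraphML / TSV
export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class TargetNetwork:
    graph: nx.Graph  # bipartite: node attr kind in {"mirna", "gene"}

    @property
    def mirna_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "mirna"]

    @property
    def gene_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def summary(self) -> dict:
        """Unique- and shared-target counts across miRNA group tags.

        A gene is *unique* to a group when every miRNA targeting it
        carries that single group tag; genes reached by miRNAs of two or
        more groups are *shared*.
        """
        unique: dict[str, int] = {}
        shared = 0
        for gene in self.gene_nodes:
            tags = {self.graph.nodes[m]["group"]
                    for m in self.graph.neighbors(gene)}
            if len(tags) == 1:
                tag = next(iter(tags))
                unique[tag] = unique.get(tag, 0) + 1
            else:
                shared += 1
        return {
            "n_mirna": len(self.mirna_nodes),
            "n_genes": len(self.gene_nodes),
            "n_edges": self.n_edges,
            "unique_targets": unique,
            "shared_targets": shared,
        }


def filter_predictions(
    predictions: pd.DataFrame, min_sources: int = 6
) -> pd.DataFrame:
    """Keep predictions supported by at least ``min_sources`` sources."""
    return predictions[predictions["support_count"] >= min_sources].reset_index(
        drop=True)


def build_network(
    predictions: pd.DataFrame,
    mirna_groups: Mapping[str, str],
    restrict_genes: Sequence[str] | None = None,
    min_degree: int = 1,
    mirna_directions: Mapping[str, str] | None = None,
) -> TargetNetwork:
    """Bipartite miRNA–gene network from a prediction table.

    Every miRNA in ``predictions`` must have a group tag (CS / FS / NS /
    common).  Gene nodes are optionally restricted to ``restrict_genes``;
    miRNA nodes whose post-restriction degree falls below ``min_degree``
    ("only the most highly connected miRNAs") are dropped with their
    edges, and degrees are recomputed.
    """
    untagged = set(predictions["mirna_id"]) - set(mirna_groups)
    if untagged:
        raise ValueError(f"miRNAs without a group tag: {sorted(untagged)[:5]}")
    df = predictions
    if restrict_genes is not None:
        allowed = set(restrict_genes)
        if not allowed:
            raise ValueError("gene restriction list is empty")
        df = df[df["gene"].isin(allowed)]
        if df.empty:
            warnings.warn("gene restriction removed every prediction",
                          stacklevel=2)

    g = nx.Graph()
    for row in df.itertuples(index=False):
        tag = mirna_groups[row.mirna_id]
        if row.mirna_id not in g:
            direction = (mirna_directions or {}).get(row.mirna_id, "")
            g.add_node(row.mirna_id, kind="mirna", group=tag,
                       direction=direction)
        if row.gene not in g:
            g.add_node(row.gene, kind="gene")
        g.add_edge(row.mirna_id, row.gene, group=tag,
                   support=int(row.support_count))

    drop = [n for n, d in g.nodes(data=True)
            if d["kind"] == "mirna" and g.degree[n] < min_degree]
    g.remove_nodes_from(drop)
    g.remove_nodes_from([n for n, d in g.nodes(data=True)
                         if d["kind"] == "gene" and g.degree[n] == 0])
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree[n]
    return TargetNetwork(graph=g)


def connectivity_report(
    net: TargetNetwork,
    top_n: int | None = None,
    reference_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Nodes ranked by degree (ties by identifier), plus list coverage.

    Coverage is the fraction of ``reference_genes`` present among the
    network's gene nodes, or ``None`` when no list is given.
    """
    rows = sorted(
        ((n, d["kind"], net.graph.degree[n])
         for n, d in net.graph.nodes(data=True)),
        key=lambda r: (-r[2], r[0]))
    if top_n is not None:
        rows = rows[:top_n]
    table = pd.DataFrame(rows, columns=["node", "kind", "degree"])
    coverage = None
    if reference_genes is not None:
        ref = set(reference_genes)
        if not ref:
            raise ValueError("reference gene list is empty")
        present = ref & set(net.gene_nodes)
        coverage = len(present) / len(ref)
    return table, coverage


def write_graphml(net: TargetNetwork, path: str) -> None:
    nx.write_graphml(net.graph, path)


def write_edge_list(net: TargetNetwork, path: str) -> None:
    rows = [
        {"mirna_id": u if net.graph.nodes[u]["kind"] == "mirna" else v,
         "gene": v if net.graph.nodes[u]["kind"] == "mirna" else u,
         "group": d.get("group", ""), "support": d.get("support", "")}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene", "group", "support"]) \
        .sort_values(["mirna_id", "gene"]).to_csv(path, sep="\t", index=False)
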