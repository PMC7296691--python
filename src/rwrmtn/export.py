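"""Attribute-annotated result graphs (SIF + node table, or GraphML).

The export replaces interactive visualization: the disease of interest,
known and candidate miRNAs, their target genes and supporting PubMed
records become nodes with class/rank/score attributes, and known vs
candidate disease associations are distinguished by an ``edge_class``
attribute, so any downstream viewer can style them (e.g. solid vs dashed).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .evidence import EvidenceTable
from .network import AssociationTable, MirnaTargetNetwork, _norm
from .propagation import RankingResult

__all__ = ["build_result_graph", "export_result_graph"]

NODE_CLASSES = ("disease", "candidate_mirna", "known_mirna", "gene", "pubmed")
EDGE_CLASSES = ("known_association", "candidate_association", "targets", "evidence")


def build_result_graph(
    ranking: RankingResult,
    net: MirnaTargetNetwork,
    assoc: AssociationTable,
    disease_id: str,
    evidence: EvidenceTable | None = None,
) -> nx.Graph:
    """Assemble the annotated result graph for one ranking."""
    if not ranking.rows:
        raise ValueError("ranking is empty")
    did = str(disease_id).strip()
    if did not in assoc.diseases:
        raise KeyError(f"unknown disease id {did!r}")
    g = nx.Graph()
    disease_node = f"disease:{did}"
    g.add_node(disease_node, node_class="disease", label=assoc.diseases[did])

    known_in_net = [m for m in assoc.mirnas_for(did) if net.has_mirna(m)]
    known_keys = {_norm(m) for m in known_in_net}
    for m in known_in_net:
        display = net.mirna_ids[net.mirna_index[_norm(m)]]
        g.add_node(display, node_class="known_mirna")
        g.add_edge(disease_node, display, edge_class="known_association")

    for rank, mirna, score in ranking.rows:
        g.add_node(mirna, node_class="candidate_mirna", rank=int(rank),
                   score=float(score))
        g.add_edge(disease_node, mirna, edge_class="candidate_association")

    shown = [m for m in known_in_net] + [r.mirna_id for r in ranking.rows]
    for m in shown:
        for gene in net.targets_of(m):
            if gene not in g:
                g.add_node(gene, node_class="gene")
            g.add_edge(m, gene, edge_class="targets")

    if evidence is not None:
        ranked = {_norm(r.mirna_id): r.mirna_id for r in ranking.rows}
        for row in evidence.rows:
            key = _norm(row.mirna_id)
            if key not in ranked:
                continue
            for pmid in row.pubmed_ids:
                node = f"pubmed:{pmid}"
                if node not in g:
                    g.add_node(node, node_class="pubmed", pubmed_id=str(pmid))
                g.add_edge(ranked[key], node, edge_class="evidence")
    # sanity: exactly one disease node, candidate ranks attached
    assert sum(1 for _, d in g.nodes(data=True)
               if d["node_class"] == "disease") == 1
    return g


def export_result_graph(
    ranking: RankingResult,
    net: MirnaTargetNetwork,
    assoc: AssociationTable,
    disease_id: str,
    out: str | Path,
    evidence: EvidenceTable | None = None,
    fmt: str = "graphml",
) -> list[Path]:
    """Write the result graph; returns the written paths.

    fmt="graphml" writes a single GraphML file; fmt="sif" writes a SIF
    edge file plus a node-attribute TSV next to it.
    """
    graph = build_result_graph(ranking, net, assoc, disease_id, evidence)
    out = Path(out)
    if fmt == "graphml":
        path = out if out.suffix == ".graphml" else out.with_suffix(".graphml")
        nx.write_graphml(graph, path)
        return [path]
    if fmt == "sif":
        sif = out if out.suffix == ".sif" else out.with_suffix(".sif")
        nodes = sif.with_name(sif.stem + "_nodes.tsv")
        with open(sif, "w", encoding="utf-8") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{data['edge_class']}\t{v}\n")
        with open(nodes, "w", encoding="utf-8") as fh:
            fh.write("node\tnode_class\trank\tscore\tlabel\n")
            for n, data in sorted(graph.nodes(data=True)):
                fh.write(
                    f"{n}\t{data['node_class']}\t{data.get('rank', '')}\t"
                    f"{data.get('score', '')}\t{data.get('label', '')}\n"
                )
        return [sif, nodes]
    raise ValueError(f"unknown export format: {fmt!r} (use 'graphml' or 'sif')")
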