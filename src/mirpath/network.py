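"""Bipartite miRNA-pathway association network export.

Nodes are pathways and miRNAs; an edge connects a pathway to its best
miRNA when the association passes a q-value threshold.  Files are written
in Cytoscape-readable formats (SIF or GraphML).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .enrichment import AssociationRecord
from .errors import ValidationError

logger = logging.getLogger(__name__)


def build_network(records: list[AssociationRecord], q_threshold: float = 0.05) -> nx.Graph:
    """Keep the associations with q <= threshold; isolated nodes are omitted.

    The graph is bipartite by construction (edges only run miRNA->pathway)
    and carries node ``kind`` attributes plus per-edge q, p and x.
    """
    net = nx.Graph()
    for r in records:
        if not r.has_association or not (r.q_value == r.q_value):  # NaN-safe
            continue
        if r.q_value <= q_threshold:
            net.add_node(r.mirna_id, kind="mirna")
            net.add_node(r.pathway_id, kind="pathway")
            net.add_edge(
                r.mirna_id, r.pathway_id,
                q_value=float(r.q_value), p_value=float(r.p_value), x=int(r.x),
            )
    logger.info(
        "association network: %d nodes, %d edges at q <= %g",
        net.number_of_nodes(), net.number_of_edges(), q_threshold,
    )
    return net


def export_network(net: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Write the network as SIF ("mirna targets_pathway pathway") or GraphML."""
    path = Path(path)
    if fmt == "sif":
        lines = []
        for u, v in sorted(net.edges()):
            mirna, pathway = (u, v) if net.nodes[u]["kind"] == "mirna" else (v, u)
            lines.append(f"{mirna}\ttargets_pathway\t{pathway}\n")
        with open(path, "w", encoding="utf-8") as handle:
            handle.writelines(lines)
    elif fmt == "graphml":
        nx.write_graphml(net, path, named_key_ids=True)
    else:
        raise ValidationError(f"unknown network format {fmt!r} (expected 'sif' or 'graphml')")
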