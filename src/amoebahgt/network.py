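"""Bipartite gene-trafficking networks and Cytoscape-consumable exports.

Nodes are host genes on one side and viral genes (or whole viral families,
at family resolution) on the other; edges carry the similarity attributes of
the underlying hits.  Exports: SIF lines, GraphML (round-trippable), and a
plain edge TSV.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .align import AlignmentHit
from .errors import ConfigError
from .pipeline import ScanHit

HOST_SIDE = 0
VIRAL_SIDE = 1


def build_exchange_network(
    hits: list[tuple[str, str, AlignmentHit]],
    resolution: str = "gene",
    family_of: dict[str, str] | None = None,
) -> nx.Graph:
    """Bipartite network from (host gene, viral gene, hit) triples.

    At ``family`` resolution viral nodes are merged by family (via
    ``family_of``) and parallel edges collapse to the best (lowest) e-value,
    keeping that hit's identity and coverage.  At ``gene`` resolution every
    viral gene is its own node.
    """
    if resolution not in ("gene", "family"):
        raise ConfigError(f"unknown resolution {resolution!r}")
    if resolution == "family" and family_of is None:
        raise ConfigError("family resolution requires a family_of map")
    g = nx.Graph()
    for host_gene, viral_gene, hit in hits:
        viral_node = family_of[viral_gene] if resolution == "family" else viral_gene
        g.add_node(host_gene, bipartite=HOST_SIDE, side="host")
        g.add_node(viral_node, bipartite=VIRAL_SIDE, side="viral")
        attrs = {
            "identity_pct": hit.identity_pct,
            "evalue": hit.evalue,
            "coverage_pct": hit.coverage_pct,
        }
        if g.has_edge(host_gene, viral_node):
            if hit.evalue < g.edges[host_gene, viral_node]["evalue"]:
                g.edges[host_gene, viral_node].update(attrs)
        else:
            g.add_edge(host_gene, viral_node, **attrs)
    return g


def network_from_scan(scan_hits: list[ScanHit], resolution: str = "family", family_of: dict[str, str] | None = None) -> nx.Graph:
    """Network of genome-scan loci: host side is the scaffold locus."""
    triples = [
        (f"{h.scaffold_id}:{h.genomic_start}-{h.genomic_end}", h.viral_gene_id, h.hit)
        for h in scan_hits
    ]
    return build_exchange_network(triples, resolution, family_of)


def export_network(network: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Write a network as ``sif``, ``graphml`` or ``tsv``."""
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(network.edges()):
                a, b = (u, v) if network.nodes[u].get("side") == "host" else (v, u)
                fh.write(f"{a} interactsWith {b}\n")
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("host_node\tviral_node\tidentity_pct\tcoverage_pct\tevalue\n")
            for u, v, attrs in sorted(network.edges(data=True)):
                a, b = (u, v) if network.nodes[u].get("side") == "host" else (v, u)
                fh.write(
                    f"{a}\t{b}\t{attrs['identity_pct']:.2f}\t"
                    f"{attrs['coverage_pct']:.2f}\t{attrs['evalue']:.3g}\n"
                )
    else:
        raise ConfigError(f"unknown export format {fmt!r}")


def import_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
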