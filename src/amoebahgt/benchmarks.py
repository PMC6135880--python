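"""Seeded end-to-end evaluation runs at the package's study conditions.

These functions regenerate synthetic inputs, execute the pipeline, and score
the outcome against the generators' truth tables.  They exist so the same
measurements can be driven from the test suite and from the reproduction
script.  Problem sizes are the package defaults: 20-scaffold genomes with 200
host genes and 12 implants for recovery runs, 3 viral families of 8 proteins
plus 4 cellular decoy panels of 8 as the search database, 100 random 5–8
taxon trees for topology recovery.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .io import OrfRecord
from .phylo import LabeledTree, infer_transfer_direction, neighbor_joining
from .pipeline import assign_taxonomy
from .rhizome import rhizome_scan
from .search import reciprocal_best_hits, search_best_hits
from .simulate import (
    generate_host_genome,
    generate_reference_panels,
    implant_transfers,
    make_mosaic_gene,
    panel_proteome,
    random_protein,
)
from .synteny import conservation_matrix, map_block, select_viral_scaffolds


@dataclass(frozen=True)
class RecoveryResult:
    """Implant-recovery outcome over seeded replicates."""

    recall: float
    false_positive_rate: float
    n_implants: int
    n_host_genes: int
    n_replicates: int


def implant_recovery(
    base_seed: int,
    n_replicates: int = 20,
    divergence: float = 0.1,
    n_scaffolds: int = 20,
    orfs_per_scaffold: int = 10,
    n_transfers: int = 12,
    n_families: int = 3,
    genes_per_family: int = 8,
) -> RecoveryResult:
    """Generate genomes with implanted viral genes, run the best-hit labeling
    stage at default thresholds, and measure implant recall and the fraction
    of host-background genes mislabeled as viral."""
    found = total = fp = host_total = 0
    for rep in range(n_replicates):
        seed = base_seed + 1000 * rep
        panels, cellular, tax = generate_reference_panels(
            n_families, genes_per_family, (250.0, 50.0), seed=seed
        )
        genome = generate_host_genome(n_scaffolds, orfs_per_scaffold, seed=seed + 1)
        genome = implant_transfers(genome, panels, n_transfers, divergence, seed=seed + 2)
        db = panel_proteome(panels, cellular)
        labels = assign_taxonomy(search_best_hits(genome.proteome(), db), tax)
        truth = {r.gene_id: r.source_category for r in genome.truth}
        for l in labels:
            if truth[l.gene_id].startswith("viral"):
                total += 1
                found += l.category == "virus"
            else:
                host_total += 1
                fp += l.category == "virus"
    return RecoveryResult(
        recall=found / total,
        false_positive_rate=fp / host_total,
        n_implants=total,
        n_host_genes=host_total,
        n_replicates=n_replicates,
    )


def _random_additive_tree(rng: random.Random, labels: list[str]):
    """Random unrooted binary topology with branch lengths in [0.1, 2];
    returns (newick, exact leaf-to-leaf path distances)."""
    import collections

    nodes = list(labels)
    nwk = {l: l for l in labels}
    graph = collections.defaultdict(dict)
    counter = 0
    while len(nodes) > 3:
        a, b = rng.sample(nodes, 2)
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        new = f"_n{counter}"
        counter += 1
        graph[new][a] = graph[a][new] = la
        graph[new][b] = graph[b][new] = lb
        nwk[new] = f"({nwk[a]}:{la:.6f},{nwk[b]}:{lb:.6f})"
        nodes = [x for x in nodes if x not in (a, b)] + [new]
    parts = []
    for x in nodes:
        lx = rng.uniform(0.1, 2.0)
        graph["_c"][x] = graph[x]["_c"] = lx
        parts.append(f"{nwk[x]}:{lx:.6f}")
    newick = "(" + ",".join(parts) + ");"
    dists = {}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in graph[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in labels:
            dists[(src, dst)] = seen[dst]
    return newick, dists


def nj_topology_recovery(base_seed: int, n_trees: int = 100) -> float:
    """Fraction of random additive 5–8 taxon matrices whose generating
    topology neighbor joining recovers exactly."""
    rng = random.Random(base_seed)
    recovered = 0
    for _ in range(n_trees):
        n = rng.randint(5, 8)
        labels = [f"t{i}" for i in range(n)]
        true_nwk, dists = _random_additive_tree(rng, labels)
        d = np.array([[dists[(a, b)] for b in labels] for a in labels])
        est_nwk = neighbor_joining(labels, d)
        tns = dendropy.TaxonNamespace()
        ta = dendropy.Tree.get(data=true_nwk, schema="newick", taxon_namespace=tns)
        tb = dendropy.Tree.get(data=est_nwk, schema="newick", taxon_namespace=tns)
        ta.encode_bipartitions()
        tb.encode_bipartitions()
        recovered += treecompare.symmetric_difference(ta, tb) == 0
    return recovered / n_trees


#: six benchmark gene-tree topologies: three with the amoebal clade nested in
#: viral paraphyly, three with the viral clade nested in amoebal paraphyly
DIRECTION_CASES = [
    ("(Out,((V1,V2),(V3,(Q,A1))));", "virus_to_amoeba"),
    ("(Out,(V1,(V2,(Q,A1))));", "virus_to_amoeba"),
    ("(Out,((V1,V2),(V3,((Q,A1),A2))));", "virus_to_amoeba"),
    ("(Out,((A1,A2),(A3,(V1,V2))));", "amoeba_to_virus"),
    ("(Out,(A1,(A2,(V1,V2))));", "amoeba_to_virus"),
    ("(Out,((A1,Q),(A2,(V1,V2))));", "amoeba_to_virus"),
]

MIXED_CASES = [
    "(Out,((V1,A1),(V2,(Q,V3))));",
    "(Out,((V1,V2),(Q,A1)));",
    "(Out,((A1,V1),(A2,(Q,V2))));",
]


def _direction_groups(newick: str) -> dict[str, str]:
    groups = {}
    for label in newick.replace("(", " ").replace(")", " ").replace(";", " ").replace(",", " ").split():
        if label == "Out":
            groups[label] = "other_cellular"
        elif label == "Q":
            groups[label] = "query"
        elif label.startswith("A"):
            groups[label] = "amoeba"
        else:
            groups[label] = "virus"
    # trees without an explicit query leaf use A1 as the host gene
    if "Q" not in groups:
        groups["A1"] = "query"
    return groups


def direction_rule_accuracy() -> float:
    """Fraction of the designed topologies called as designed, requiring every
    intermixed control to come out inconclusive."""
    correct = 0
    for newick, expected in DIRECTION_CASES:
        call = infer_transfer_direction(LabeledTree(newick, _direction_groups(newick)))
        correct += call.direction == expected
    for newick in MIXED_CASES:
        call = infer_transfer_direction(LabeledTree(newick, _direction_groups(newick)))
        if call.direction != "inconclusive":
            return 0.0
    return correct / len(DIRECTION_CASES)


def mosaic_anchor_accuracy(seed: int) -> float:
    """Build a three-source mosaic gene at zero divergence and check that the
    non-overlapping anchor windows classify to their true domains."""
    rng = random.Random(seed)
    sources = {
        "v1": ("virus:mimi_like", "M" + random_protein(rng, 299)),
        "b1": ("bacteria", "M" + random_protein(rng, 299)),
        "e1": ("other_eukaryote", "M" + random_protein(rng, 299)),
    }
    spec = [
        ("virus:mimi_like", "v1", 40),
        ("bacteria", "b1", 40),
        ("other_eukaryote", "e1", 40),
    ]
    protein, intervals = make_mosaic_gene(spec, sources, seed=seed)
    db = [(pid, s) for pid, (_c, s) in sources.items()]
    taxmap = {pid: c for pid, (c, _s) in sources.items()}
    profile = rhizome_scan("mosaic", protein, db, taxmap)
    by_start = {f.start: f for f in profile.fragments}
    expected = {"virus:mimi_like": "virus", "bacteria": "bacteria", "other_eukaryote": "eukaryote"}
    hits = sum(
        by_start[start].origin == expected[cat] for start, _e, cat, _p in intervals
    )
    return hits / len(intervals)


def _orf_row(gene_id, scaffold, index, protein):
    start = 1 + 400 * index
    return OrfRecord(gene_id, scaffold, start, start + 3 * (len(protein) + 1) - 1, "+", 0, protein)


def synteny_truth_design(seed: int):
    """Engineered 3-genome conservation design.

    The source genome carries one scaffold with four viral-best-hit genes.
    Target "full" holds identical copies in order (expect 4 conserved, order
    1.0); "partial" holds two of them, reversed, on one scaffold (expect 2,
    order 0.5); "none" holds unrelated genes (expect 0, order 0).  Returns
    (conservation DataFrame, order scores dict, expected totals dict).
    """
    panels, cellular, tax = generate_reference_panels(2, 6, (150.0, 30.0), seed=seed)
    viral = [p for panel in panels for p in panel.proteins][:4]
    rng = random.Random(seed + 7)
    host = lambda: "M" + random_protein(rng, 149)

    src_orfs = [_orf_row(f"src_v{i}", "src_s1", i, seq) for i, (_pid, seq) in enumerate(viral)]
    src_orfs += [_orf_row(f"src_h{i}", "src_s2", i, host()) for i in range(3)]
    src_prot = [(o.gene_id, o.protein) for o in src_orfs]

    full_orfs = [_orf_row(f"full_v{i}", "full_s1", i, seq) for i, (_p, seq) in enumerate(viral)]
    full_orfs += [_orf_row(f"full_h{i}", "full_s2", i, host()) for i in range(3)]
    partial_orfs = [
        _orf_row("part_v2", "part_s1", 0, viral[2][1]),
        _orf_row("part_v0", "part_s1", 1, viral[0][1]),
        _orf_row("part_h0", "part_s2", 0, host()),
    ]
    none_orfs = [_orf_row(f"none_h{i}", "none_s1", i, host()) for i in range(3)]

    db = panel_proteome(panels, cellular)
    labels = assign_taxonomy(search_best_hits(src_prot, db), tax)
    blocks = select_viral_scaffolds(src_orfs, labels, min_viral_genes=3)

    targets = {"full": full_orfs, "partial": partial_orfs, "none": none_orfs}
    results = {}
    order_scores = {}
    for name, orfs in targets.items():
        prot = [(o.gene_id, o.protein) for o in orfs]
        rbh = reciprocal_best_hits(src_prot, prot)
        results[name] = {b.scaffold_id: map_block(b, orfs, rbh) for b in blocks}
        order_scores[name] = {b.scaffold_id: results[name][b.scaffold_id].order_score for b in blocks}
    matrix = conservation_matrix(blocks, results, list(targets))
    expected_totals = {"full": 4, "partial": 2, "none": 0}
    return matrix, order_scores, expected_totals
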