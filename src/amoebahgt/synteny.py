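"""Cross-genome conservation and collinearity of viral-best-hit scaffolds.

Scaffolds carrying at least ``min_viral_genes`` virus-labeled genes are
selected as synteny blocks; each block is mapped onto target genomes through
reciprocal best hits.  Gene presence uses RBH rather than one-way hits to
avoid paralog inflation.  Collinearity is the longest common subsequence of
the block's gene order against the partner order along a single target
scaffold, taken as the better of source order and its full reversal —
draft-genome scaffolds have arbitrary orientation, so a fully reversed run
still counts as collinear.  Partners split across target scaffolds count
toward presence but cap the order score, keeping the "present" and "in
synteny" questions separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .io import OrfRecord
from .phylo import neighbor_joining
from .pipeline import GeneTaxLabel
from .search import OrthologGroup


@dataclass(frozen=True)
class ConservationResult:
    """How one block fares in one target genome."""

    conserved_count: int
    order_score: float
    matched_scaffolds: tuple[str, ...]


@dataclass(frozen=True)
class SyntenyBlock:
    """An ordered run of viral-best-hit genes on one source scaffold."""

    scaffold_id: str
    gene_ids: tuple[str, ...]  # ordered by start coordinate
    results: dict[str, ConservationResult] = field(default_factory=dict)


def select_viral_scaffolds(
    orfs: list[OrfRecord],
    labels: list[GeneTaxLabel],
    min_viral_genes: int = 3,
) -> list[SyntenyBlock]:
    """One block per scaffold carrying >= ``min_viral_genes`` virus-labeled
    genes, genes ordered by start coordinate."""
    viral_genes = {l.gene_id for l in labels if l.category == "virus"}
    by_scaffold: dict[str, list[OrfRecord]] = {}
    for o in orfs:
        if o.gene_id in viral_genes:
            by_scaffold.setdefault(o.scaffold_id, []).append(o)
    blocks = []
    for sid in sorted(by_scaffold):
        genes = sorted(by_scaffold[sid], key=lambda o: o.start)
        if len(genes) >= min_viral_genes:
            blocks.append(SyntenyBlock(sid, tuple(o.gene_id for o in genes)))
    return blocks


def _lcs_length(a: list, b: list) -> int:
    if not a or not b:
        return 0
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    for i, x in enumerate(a, 1):
        for j, y in enumerate(b, 1):
            dp[i, j] = dp[i - 1, j - 1] + 1 if x == y else max(dp[i - 1, j], dp[i, j - 1])
    return int(dp[-1, -1])


def map_block(
    block: SyntenyBlock,
    target_orfs: list[OrfRecord],
    rbh_pairs: list[tuple[str, str]],
) -> ConservationResult:
    """Conservation of one block in one target genome.

    ``rbh_pairs`` are (source gene, target gene) reciprocal best hits between
    the two proteomes.  The conserved count is the number of block genes with
    a partner anywhere in the target; the order score is the best
    single-scaffold LCS (source order vs partner coordinate order, reversal
    allowed) divided by the block size.
    """
    partner = dict(rbh_pairs)
    target_pos = {o.gene_id: (o.scaffold_id, o.start) for o in target_orfs}
    placed: dict[str, list[tuple[int, str]]] = {}  # target scaffold -> (start, source gene)
    conserved = 0
    for g in block.gene_ids:
        t = partner.get(g)
        if t is None:
            continue
        conserved += 1
        if t in target_pos:
            sid, start = target_pos[t]
            placed.setdefault(sid, []).append((start, g))
    best_lcs = 0
    for sid, entries in placed.items():
        order = [g for _, g in sorted(entries)]
        source_order = [g for g in block.gene_ids if g in set(order)]
        best_lcs = max(
            best_lcs,
            _lcs_length(source_order, order),
            _lcs_length(source_order[::-1], order),
        )
    return ConservationResult(
        conserved_count=conserved,
        order_score=best_lcs / len(block.gene_ids),
        matched_scaffolds=tuple(sorted(placed)),
    )


def conservation_matrix(
    blocks: list[SyntenyBlock],
    results: dict[str, dict[str, ConservationResult]],
    genomes: list[str],
) -> pd.DataFrame:
    """Block × genome matrix of conserved-gene counts with a totals row.

    ``results[genome][scaffold_id]`` holds the mapped result of each block.
    """
    data = {}
    for genome in genomes:
        col = []
        for block in blocks:
            res = results.get(genome, {}).get(block.scaffold_id)
            col.append(res.conserved_count if res else 0)
        data[genome] = col
    df = pd.DataFrame(data, index=[b.scaffold_id for b in blocks])
    df.loc["total"] = df.sum()
    return df


def genome_tree_from_ortholog_jaccard(
    groups: list[OrthologGroup],
    genomes: list[str],
) -> str:
    """Genome tree from ortholog-group sharing: pairwise distance
    1 − Jaccard(groups containing G, groups containing H), then neighbor
    joining.  Stands in for a whole-genome-alignment tree at desk scale."""
    if len(genomes) < 3:
        raise ArgumentError("need at least 3 genomes for a genome tree")
    genomes = sorted(genomes)
    membership = {g: {grp.group_id for grp in groups if g in grp.genomes} for g in genomes}
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = membership[genomes[i]], membership[genomes[j]]
            union = len(a | b)
            jac = len(a & b) / union if union else 0.0
            d[i, j] = d[j, i] = 1.0 - jac
    return neighbor_joining(genomes, d)
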