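"""Best-hit search, reciprocal best hits, and ortholog-group clustering.

Searches are exhaustive full-dynamic-programming scans (no heuristic seeding):
every query is scored against every database subject, and the full alignment
is retrieved only for candidates that can still pass the e-value threshold.
Best-hit ties are broken totally and deterministically: lowest e-value, then
higher raw score, then lexicographically smallest subject id.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .align import DEFAULT_SCHEME, AlignmentHit, ScoringScheme, align_pair, make_aligner
from .errors import ArgumentError

Proteome = list[tuple[str, str]]  # (gene_id, protein sequence)


@dataclass(frozen=True)
class Thresholds:
    """Hit-acceptance thresholds of the homolog screens: amino-acid identity
    >= ``identity_min`` %, e-value <= ``evalue_max``, query coverage
    >= ``coverage_min`` %."""

    identity_min: float = 30.0
    evalue_max: float = 1e-2
    coverage_min: float = 30.0


DEFAULT_THRESHOLDS = Thresholds()


def _passes(hit: AlignmentHit, thresholds: Thresholds) -> bool:
    return (
        hit.identity_pct >= thresholds.identity_min
        and hit.evalue <= thresholds.evalue_max
        and hit.coverage_pct >= thresholds.coverage_min
    )


def search_best_hits(
    queries: Proteome,
    database: Proteome,
    db_length: int | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict[str, AlignmentHit | None]:
    """Best passing hit per query against a database, or ``None`` (no-hit).

    ``db_length`` is the effective database length used in every e-value; it
    defaults to the total residue count of the database.
    """
    if not database:
        raise ArgumentError("database must be non-empty")
    if db_length is None:
        db_length = sum(len(s) for _, s in database)
    aligner = make_aligner(scheme)
    results: dict[str, AlignmentHit | None] = {}
    for qid, qseq in queries:
        scored = sorted(
            ((int(round(aligner.score(qseq, sseq))), sid, sseq) for sid, sseq in database),
            key=lambda t: (-t[0], t[1]),
        )
        cutoff = scheme.min_score_for_evalue(thresholds.evalue_max, len(qseq), db_length)
        best: AlignmentHit | None = None
        for score, sid, sseq in scored:
            if score < cutoff or score < scheme.min_raw_score:
                break  # sorted descending: nothing further can pass
            hit = align_pair(qseq, sseq, scheme, qid, sid, db_length)
            if hit is not None and _passes(hit, thresholds):
                best = hit
                break
        results[qid] = best
    return results


def reciprocal_best_hits(
    proteome_a: Proteome,
    proteome_b: Proteome,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[tuple[str, str]]:
    """Gene pairs that are each other's best hit in the two proteomes.

    Symmetric by construction: ``RBH(A, B)`` equals ``RBH(B, A)`` with the
    tuples swapped.  Output is sorted.
    """
    if not proteome_a or not proteome_b:
        raise ArgumentError("both proteomes must be non-empty")
    ab = search_best_hits(proteome_a, proteome_b, thresholds=thresholds, scheme=scheme)
    ba = search_best_hits(proteome_b, proteome_a, thresholds=thresholds, scheme=scheme)
    pairs = []
    for ga, hit in ab.items():
        if hit is None:
            continue
        back = ba.get(hit.subject_id)
        if back is not None and back.subject_id == ga:
            pairs.append((ga, hit.subject_id))
    return sorted(pairs)


@dataclass(frozen=True)
class OrthologGroup:
    """A connected component of the union of pairwise RBH graphs."""

    group_id: str
    members: frozenset[tuple[str, str]]  # (genome_id, gene_id)

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.members)


def cluster_orthologs(
    proteomes: dict[str, Proteome],
    min_len_aa: int = 100,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[list[OrthologGroup], dict[tuple[str, str], float]]:
    """Ortholog groups across >= 2 genomes plus per-genome-pair sharing
    fractions.

    Genes shorter than ``min_len_aa`` are excluded before clustering.  Groups
    are connected components of the union of all pairwise RBH graphs with
    members from at least two genomes.  The sharing fraction of genome G with
    genome H is |groups containing G that also contain H| / |groups containing
    G| (asymmetric in general).
    """
    if len(proteomes) < 2:
        raise ArgumentError("cluster_orthologs needs at least two genomes")
    filtered = {
        g: [(gid, seq) for gid, seq in prot if len(seq) >= min_len_aa]
        for g, prot in proteomes.items()
    }
    graph = nx.Graph()
    for ga, gb in combinations(sorted(filtered), 2):
        if not filtered[ga] or not filtered[gb]:
            continue
        for a, b in reciprocal_best_hits(filtered[ga], filtered[gb], thresholds, scheme):
            graph.add_edge((ga, a), (gb, b))
    groups = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c))
    for k, comp in enumerate(components, start=1):
        members = frozenset(comp)
        if len({g for g, _ in members}) >= 2:
            groups.append(OrthologGroup(f"OG{k:05d}", members))
    sharing: dict[tuple[str, str], float] = {}
    for ga, gb in combinations(sorted(filtered), 2):
        with_a = [grp for grp in groups if ga in grp.genomes]
        with_b = [grp for grp in groups if gb in grp.genomes]
        sharing[(ga, gb)] = (
            sum(1 for grp in with_a if gb in grp.genomes) / len(with_a) if with_a else 0.0
        )
        sharing[(gb, ga)] = (
            sum(1 for grp in with_b if ga in grp.genomes) / len(with_b) if with_b else 0.0
        )
    return groups, sharing
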