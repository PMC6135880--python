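"""Within-gene mosaicism scanning ("rhizome" analysis).

A protein is fenestrated into 40-aa windows advanced by 20 aa; each fragment
is searched against a labeled reference collection and takes the domain-level
category of its best passing hit (virus / eukaryote / bacteria / archaea),
or ``unclassified``.  Fragment searches waive the coverage gate — fragments
are already short — which is recorded in the profile metadata.  The resulting
profile is exportable as a Circos-table-viewer style cross-tabulation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .align import DEFAULT_SCHEME, ScoringScheme
from .errors import ArgumentError
from .search import DEFAULT_THRESHOLDS, Proteome, Thresholds, search_best_hits

#: headline origin categories, matching a virus/eukaryote/bacteria/archaea legend
ORIGINS = ("virus", "eukaryote", "bacteria", "archaea")
_DOMAIN_OF = {
    "amoebozoa": "eukaryote",
    "other_eukaryote": "eukaryote",
    "bacteria": "bacteria",
    "archaea": "archaea",
}


@dataclass(frozen=True)
class Fragment:
    """One fenestration window, 1-based inclusive residue coordinates."""

    start: int
    end: int
    sequence: str
    origin: str = "unclassified"
    subject_id: str | None = None
    identity_pct: float | None = None
    evalue: float | None = None
    viral_family: str | None = None


@dataclass(frozen=True)
class RhizomeProfile:
    """Per-fragment taxonomic origins of one gene under fenestration.

    ``mosaicism_index`` = distinct classified origins / classified fragments;
    ``None`` when nothing classifies.
    """

    gene_id: str
    window_aa: int
    step_aa: int
    fragments: tuple[Fragment, ...]
    coverage_waived: bool = True

    @property
    def mosaicism_index(self) -> float | None:
        classified = [f.origin for f in self.fragments if f.origin != "unclassified"]
        if not classified:
            return None
        return len(set(classified)) / len(classified)


def fenestrate(protein: str, window_aa: int = 40, step_aa: int = 20) -> list[Fragment]:
    """Slice a protein into full-width windows at fixed steps.

    Windows start at offsets 0, step, 2·step, ... while a full window fits;
    a protein shorter than the window yields a single whole-length fragment.
    Trailing residues past the last full window get no extra anchored window,
    keeping fragment statistics comparable across genes.
    """
    if not protein:
        raise ArgumentError("empty protein")
    if not (window_aa >= step_aa >= 1):
        raise ArgumentError("need window_aa >= step_aa >= 1")
    n = len(protein)
    if n < window_aa:
        return [Fragment(1, n, protein)]
    return [
        Fragment(off + 1, off + window_aa, protein[off : off + window_aa])
        for off in range(0, n - window_aa + 1, step_aa)
    ]


def classify_fragments(
    fragments: list[Fragment],
    reference_db: Proteome,
    taxonomy_map: dict[str, str],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[Fragment]:
    """Label each fragment by its best passing hit's domain-level category.

    The coverage threshold is waived (fragments are single-window slices);
    identity and e-value gates are kept.  Classification is per-fragment and
    therefore invariant to processing order.
    """
    from dataclasses import replace

    from .pipeline import parse_taxonomy_value

    frag_thresholds = Thresholds(
        identity_min=thresholds.identity_min,
        evalue_max=thresholds.evalue_max,
        coverage_min=0.0,
    )
    queries = [(f"frag{i}", f.sequence) for i, f in enumerate(fragments)]
    best = search_best_hits(queries, reference_db, thresholds=frag_thresholds, scheme=scheme)
    out = []
    for i, frag in enumerate(fragments):
        hit = best[f"frag{i}"]
        if hit is None:
            out.append(frag)
            continue
        category, family = parse_taxonomy_value(taxonomy_map[hit.subject_id])
        origin = "virus" if category == "virus" else _DOMAIN_OF[category]
        out.append(
            replace(
                frag,
                origin=origin,
                subject_id=hit.subject_id,
                identity_pct=hit.identity_pct,
                evalue=hit.evalue,
                viral_family=family,
            )
        )
    return out


def rhizome_scan(
    gene_id: str,
    protein: str,
    reference_db: Proteome,
    taxonomy_map: dict[str, str],
    window_aa: int = 40,
    step_aa: int = 20,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> RhizomeProfile:
    """Fenestrate and classify one gene in a single call."""
    frags = classify_fragments(
        fenestrate(protein, window_aa, step_aa), reference_db, taxonomy_map, thresholds, scheme
    )
    return RhizomeProfile(gene_id, window_aa, step_aa, tuple(frags))


def rhizome_report(profile: RhizomeProfile) -> str:
    """Circos-table-viewer cross-tabulation: one row per fragment, one column
    per origin category, cell 1 for the assigned origin else 0 (row sums are
    0 for unclassified fragments)."""
    lines = ["fragment\t" + "\t".join(ORIGINS)]
    for f in profile.fragments:
        cells = ["1" if f.origin == o else "0" for o in ORIGINS]
        lines.append(f"{profile.gene_id}_{f.start}_{f.end}\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def origin_counts(profile: RhizomeProfile) -> dict[str, int]:
    """Per-category fragment counts (``unclassified`` included)."""
    return dict(Counter(f.origin for f in profile.fragments))
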