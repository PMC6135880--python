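"""Seeded synthetic inputs: host genomes, reference panels, implanted viral
transfers, and mosaic genes, each with machine-readable truth tables.

The generator emulates the statistical structure the downstream screens
assume: multi-scaffold draft genomes with a GC-homogeneous host background
(default 58.3% GC), several giant-virus "family" ORFomes, decoy cellular
reference panels (amoebozoa / other eukaryote / bacteria / archaea), viral
genes implanted at controlled amino-acid divergence, and deliberately mosaic
genes.  Implanted genes are reverse-translated with uniform synonymous-codon
choice and are *not* re-tuned to the host GC, so they carry a detectable
compositional signal.

Construction guarantees exact ORF-caller recovery: every gene is written with
an in-frame stop codon immediately upstream of its ATG, so the longest-per-
stop caller starts exactly at the annotated start.  Intergenic spacers are
>= 30 nt.  All coordinates are 1-based inclusive and include the stop codon,
matching the GFF3 emitted alongside.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .errors import ArgumentError, GenerationError
from .io import OrfRecord, Scaffold, write_fasta, write_gff3
from .seqcore import gc_content, reverse_complement

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOPS = ("TAA", "TAG", "TGA")

# standard genetic code, grouped by amino acid (no stop codons)
CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

DEFAULT_FAMILY_NAMES = (
    "pandora_like",
    "mimi_like",
    "marseille_like",
    "pitho_like",
    "mollivirus_like",
)
CELLULAR_CATEGORIES = ("amoebozoa", "other_eukaryote", "bacteria", "archaea")

#: default host background GC fraction
HOST_GC = 0.583


@dataclass(frozen=True)
class ViralPanel:
    """One simulated giant-virus family ORFome."""

    family_id: str
    proteins: tuple[tuple[str, str], ...]  # (protein_id, amino-acid sequence)


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one implanted or background gene."""

    gene_id: str
    source_category: str  # host | viral:<family> | bacteria | archaea | other_eukaryote | mosaic
    source_protein_id: str
    divergence: float
    scaffold_id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class SyntheticGenome:
    """A generated genome: scaffolds, annotated ORFs, and the truth table."""

    genome_id: str
    scaffolds: tuple[Scaffold, ...]
    orfs: tuple[OrfRecord, ...]
    truth: tuple[TruthRow, ...]

    def proteome(self) -> list[tuple[str, str]]:
        return [(o.gene_id, o.protein) for o in self.orfs]

    def scaffold_map(self) -> dict[str, Scaffold]:
        return {s.scaffold_id: s for s in self.scaffolds}

    def write(self, out_dir: str | Path, prefix: str | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.genome_id
        write_fasta(self.scaffolds, out / f"{prefix}.fasta")
        write_gff3(self.orfs, out / f"{prefix}.gff3")
        write_truth_table(self.truth, out / f"{prefix}.truth.tsv")


# ---------------------------------------------------------------------------
# low-level sequence construction


def random_protein(rng: random.Random, length: int) -> str:
    """Random protein of the given total length, starting with M."""
    if length < 2:
        raise ArgumentError("protein length must be >= 2")
    return "M" + "".join(rng.choice(AMINO_ACIDS) for _ in range(length - 1))


def mutate_protein(protein: str, divergence: float, rng: random.Random) -> str:
    """Substitute each site (after the fixed initiator M) with probability
    ``divergence``, replacing with a uniformly chosen different residue."""
    out = [protein[0]]
    for aa in protein[1:]:
        if rng.random() < divergence:
            out.append(rng.choice([x for x in AMINO_ACIDS if x != aa]))
        else:
            out.append(aa)
    return "".join(out)


def _codon_weights(gc_target: float) -> dict[str, list[float]]:
    theta = gc_target / (1.0 - gc_target)
    return {
        aa: [theta ** (c.count("G") + c.count("C")) for c in codons]
        for aa, codons in CODONS.items()
    }


def reverse_translate(protein: str, rng: random.Random, gc_target: float | None = None) -> str:
    """Coding DNA for a protein (no stop codon appended).

    Codon choice is uniform among synonymous codons, or weighted toward a GC
    target when one is given (weight ``(t/(1-t))**GC(codon)``).
    """
    weights = _codon_weights(gc_target) if gc_target is not None else None
    parts = []
    for aa in protein:
        if aa not in CODONS:
            raise ArgumentError(f"cannot reverse-translate residue {aa!r}")
        codons = CODONS[aa]
        if weights is None:
            parts.append(rng.choice(codons))
        else:
            parts.append(rng.choices(codons, weights=weights[aa])[0])
    return "".join(parts)


def gene_dna(protein: str, rng: random.Random, gc_target: float | None = None) -> str:
    """ATG-initiated, stop-terminated coding sequence for a protein."""
    if not protein.startswith("M"):
        raise ArgumentError("gene proteins must start with M")
    return reverse_translate(protein, rng, gc_target) + rng.choice(STOPS)


def _random_dna(rng: random.Random, length: int, gc: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AT"))
    return "".join(out)


# ---------------------------------------------------------------------------
# reference panels


def generate_reference_panels(
    n_families: int,
    genes_per_family: int,
    length_distribution: tuple[float, float] = (250.0, 50.0),
    seed: int = 0,
    n_cellular_per_panel: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[ViralPanel], dict[str, list[tuple[str, str]]], dict[str, str]]:
    """Generate viral family ORFomes plus four labeled cellular decoy panels.

    Returns ``(viral_panels, cellular_panels, taxonomy_map)`` where the
    taxonomy map sends every protein id to ``virus:<family>`` or its cellular
    category.  With ``out_dir`` set, emits ``panels.fasta`` and
    ``taxonomy.tsv`` (byte-identical for identical seeds and arguments).
    """
    if n_families < 1 or genes_per_family < 1:
        raise ArgumentError("counts must be positive")
    mean, sd = length_distribution
    if mean < 60:
        raise ArgumentError("mean protein length must be >= 60 aa")
    if n_cellular_per_panel is None:
        n_cellular_per_panel = genes_per_family
    rng = random.Random(seed)

    def draw_length() -> int:
        return max(60, int(round(rng.gauss(mean, sd))))

    panels = []
    taxonomy: dict[str, str] = {}
    for i in range(n_families):
        fam = (
            DEFAULT_FAMILY_NAMES[i]
            if i < len(DEFAULT_FAMILY_NAMES)
            else f"viral_family_{i + 1}"
        )
        prots = []
        for j in range(genes_per_family):
            pid = f"{fam}_p{j + 1:03d}"
            prots.append((pid, random_protein(rng, draw_length())))
            taxonomy[pid] = f"virus:{fam}"
        panels.append(ViralPanel(fam, tuple(prots)))
    cellular: dict[str, list[tuple[str, str]]] = {}
    for cat in CELLULAR_CATEGORIES:
        prots = []
        for j in range(n_cellular_per_panel):
            pid = f"{cat}_p{j + 1:03d}"
            prots.append((pid, random_protein(rng, draw_length())))
            taxonomy[pid] = cat
        cellular[cat] = prots
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        everything = [p for panel in panels for p in panel.proteins]
        everything += [p for prots in cellular.values() for p in prots]
        write_fasta(everything, out / "panels.fasta")
        with open(out / "taxonomy.tsv", "w") as fh:
            fh.write("protein_id\tcategory\n")
            for pid, cat in sorted(taxonomy.items()):
                fh.write(f"{pid}\t{cat}\n")
    return panels, cellular, taxonomy


def panel_proteome(panels: Sequence[ViralPanel], cellular: dict[str, list[tuple[str, str]]] | None = None) -> list[tuple[str, str]]:
    """Flatten panels (and optionally cellular references) to one proteome."""
    out = [p for panel in panels for p in panel.proteins]
    if cellular:
        for cat in sorted(cellular):
            out.extend(cellular[cat])
    return out


# ---------------------------------------------------------------------------
# host genome


def _cassette(protein: str, strand: str, rng: random.Random, gc_target: float | None) -> tuple[str, int, int]:
    """Blocker + coding sequence; returns (dna, gene offset, gene length).

    The blocker is an in-frame stop immediately upstream of the start codon
    (in gene orientation), which pins the ORF caller to the annotated start.
    """
    dna = gene_dna(protein, rng, gc_target)
    if strand == "+":
        return "TAA" + dna, 3, len(dna)
    return reverse_complement(dna) + "TTA", 0, len(dna)


def generate_host_genome(
    n_scaffolds: int,
    orfs_per_scaffold: int,
    gc_target: float = HOST_GC,
    seed: int = 0,
    genome_id: str = "host",
    orf_length_aa: tuple[float, float] = (200.0, 40.0),
) -> SyntheticGenome:
    """Generate a multi-scaffold host genome of random ATG...stop genes.

    Host gene codon usage is biased toward ``gc_target`` and the intergenic
    spacers (uniform 30–300 nt) are composed to bring the concatenated-genome
    GC within ±0.02 of the target.  Every emitted gene appears in exactly one
    truth row (category ``host``).
    """
    if not (0.0 < gc_target < 1.0):
        raise ArgumentError("gc_target must lie in (0, 1)")
    if orfs_per_scaffold < 1 or n_scaffolds < 1:
        raise ArgumentError("counts must be positive")
    rng = random.Random(seed)
    mean, sd = orf_length_aa

    plan = []  # per scaffold: list of (protein, strand, spacer_before), final spacer
    cassette_gc = cassette_len = 0
    spacer_total = 0
    for i in range(n_scaffolds):
        genes = []
        for j in range(orfs_per_scaffold):
            length = max(60, int(round(rng.gauss(mean, sd))))
            protein = random_protein(rng, length)
            strand = rng.choice("+-")
            spacer = rng.randint(30, 300)
            cas, off, glen = _cassette(protein, strand, rng, gc_target)
            genes.append((cas, off, glen, protein, strand, spacer))
            cassette_gc += cas.count("G") + cas.count("C")
            cassette_len += len(cas)
            spacer_total += spacer
        final = rng.randint(30, 300)
        spacer_total += final
        plan.append((genes, final))

    total_len = cassette_len + spacer_total
    spacer_gc = (gc_target * total_len - cassette_gc) / spacer_total
    spacer_gc = min(0.98, max(0.02, spacer_gc))

    scaffolds = []
    orfs = []
    truth = []
    for i, (genes, final) in enumerate(plan):
        sid = f"{genome_id}_scaf{i + 1:04d}"
        parts = []
        pos = 0  # 0-based length so far
        for j, (cas, off, glen, protein, strand, spacer) in enumerate(genes):
            sp = _random_dna(rng, spacer, spacer_gc)
            parts.append(sp)
            pos += spacer
            parts.append(cas)
            start = pos + off + 1  # 1-based inclusive
            end = start + glen - 1
            pos += len(cas)
            gid = f"{sid}_g{j + 1:03d}"
            orfs.append(OrfRecord(gid, sid, start, end, strand, (start - 1) % 3, protein))
            truth.append(TruthRow(gid, "host", gid, 0.0, sid, start, end, strand))
        parts.append(_random_dna(rng, final, spacer_gc))
        scaffolds.append(Scaffold(sid, "".join(parts), genome_id))

    genome_seq = "".join(s.sequence for s in scaffolds)
    if abs(gc_content(genome_seq) - gc_target) > 0.02:
        raise GenerationError(
            f"could not reach GC target {gc_target:.3f} "
            f"(achieved {gc_content(genome_seq):.3f})"
        )
    return SyntheticGenome(genome_id, tuple(scaffolds), tuple(orfs), tuple(truth))


# ---------------------------------------------------------------------------
# transfer implantation


def implant_transfers(
    genome: SyntheticGenome,
    panels: Sequence[ViralPanel],
    n_transfers: int,
    divergence: float,
    seed: int = 0,
) -> SyntheticGenome:
    """Insert diverged copies of viral panel proteins into intergenic space.

    Each transfer samples a distinct panel protein, substitutes amino acids at
    the stated per-site rate, reverse-translates it with uniform codon choice
    (leaving the compositional signal un-tuned), and splices the new gene —
    with >= 30 nt host-composition pads and an upstream stop blocker — into a
    random intergenic position.  Downstream coordinates shift; no existing
    gene is disrupted.
    """
    if not (0.0 <= divergence <= 0.6):
        raise ArgumentError("divergence must lie in [0, 0.6]")
    pool = [(panel.family_id, pid, seq) for panel in panels for pid, seq in panel.proteins]
    if n_transfers > len(pool):
        raise ArgumentError(
            f"n_transfers {n_transfers} exceeds panel size {len(pool)}"
        )
    rng = random.Random(seed)
    chosen = rng.sample(pool, n_transfers)

    seqs = {s.scaffold_id: s.sequence for s in genome.scaffolds}
    per_scaffold: dict[str, list] = {s.scaffold_id: [] for s in genome.scaffolds}
    gene_rows = {}
    for orf, row in zip(genome.orfs, genome.truth):
        per_scaffold[orf.scaffold_id].append(orf)
        gene_rows[orf.gene_id] = row
    new_truth: list[TruthRow] = []

    for k, (fam, pid, src) in enumerate(chosen, start=1):
        mutated = mutate_protein(src, divergence, rng)
        strand = rng.choice("+-")
        cas, off, glen = _cassette(mutated, strand, rng, None)
        pad_l = _random_dna(rng, rng.randint(30, 60), HOST_GC)
        pad_r = _random_dna(rng, rng.randint(30, 60), HOST_GC)
        block = pad_l + cas
        insert_off = len(pad_l) + off
        insert = block + pad_r

        sid = rng.choice(sorted(seqs))
        seq = seqs[sid]
        occupied = sorted((o.start, o.end) for o in per_scaffold[sid])
        # Candidate insertion points: intergenic, trimmed by 3 nt on the side
        # of every flanking gene so the stop blockers stay contiguous.
        gaps = []
        prev_end = 0
        for a, b in occupied:
            lo = prev_end + 4 if prev_end > 0 else 1
            hi = a - 3
            if hi >= lo:
                gaps.append((lo, hi))
            prev_end = b
        lo = prev_end + 4 if prev_end > 0 else 1
        if len(seq) >= lo:
            gaps.append((lo, len(seq)))
        if not gaps:
            raise GenerationError(f"no intergenic space left on scaffold {sid}")
        lo, hi = rng.choice(gaps)
        point = rng.randint(lo, hi)  # insert before this 1-based position
        seqs[sid] = seq[: point - 1] + insert + seq[point - 1 :]
        shift = len(insert)
        shifted = []
        for o in per_scaffold[sid]:
            if o.start >= point:
                o = replace(o, start=o.start + shift, end=o.end + shift)
                row = gene_rows[o.gene_id]
                gene_rows[o.gene_id] = replace(row, start=row.start + shift, end=row.end + shift)
            shifted.append(o)
        start = point - 1 + insert_off + 1
        end = start + glen - 1
        gid = f"implant{k:03d}"
        new_orf = OrfRecord(gid, sid, start, end, strand, (start - 1) % 3, mutated)
        shifted.append(new_orf)
        shifted.sort(key=lambda o: o.start)
        per_scaffold[sid] = shifted
        gene_rows[gid] = TruthRow(gid, f"viral:{fam}", pid, divergence, sid, start, end, strand)

    scaffolds = tuple(
        Scaffold(s.scaffold_id, seqs[s.scaffold_id], genome.genome_id)
        for s in genome.scaffolds
    )
    orfs = tuple(o for sid in sorted(per_scaffold) for o in per_scaffold[sid])
    truth = tuple(gene_rows[o.gene_id] for o in orfs)
    return SyntheticGenome(genome.genome_id, scaffolds, orfs, truth)


# ---------------------------------------------------------------------------
# mosaic genes


def make_mosaic_gene(
    segment_spec: Sequence[tuple[str, str, int]],
    sources: dict[str, tuple[str, str]],
    seed: int = 0,
    divergence: float = 0.0,
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Concatenate segments copied from labeled source proteins.

    ``segment_spec`` rows are ``(source_category, source_protein_id,
    length_aa)``; ``sources`` maps protein id to ``(category, sequence)``.
    Returns the chimeric protein and truth intervals ``(start, end, category,
    protein_id)`` in 1-based inclusive residue coordinates tiling the protein
    without gaps or overlap.
    """
    if len(segment_spec) < 2:
        raise ArgumentError("a mosaic gene needs at least 2 segments")
    rng = random.Random(seed)
    parts = []
    intervals = []
    pos = 0
    for cat, pid, length in segment_spec:
        if length < 20:
            raise ArgumentError("segment length must be >= 20 aa")
        if pid not in sources:
            raise ArgumentError(f"unknown source_protein_id {pid!r}")
        src_cat, src_seq = sources[pid]
        if cat != src_cat:
            raise ArgumentError(f"segment category {cat!r} != source category {src_cat!r}")
        if len(src_seq) < length:
            raise ArgumentError(f"source {pid!r} shorter than segment length {length}")
        start = rng.randint(0, len(src_seq) - length)
        frag = src_seq[start : start + length]
        if divergence > 0:
            frag = "M" + frag  # guard residue; mutate_protein keeps position 0
            frag = mutate_protein(frag, divergence, rng)[1:]
        parts.append(frag)
        intervals.append((pos + 1, pos + length, cat, pid))
        pos += length
    return "".join(parts), intervals


# ---------------------------------------------------------------------------
# truth-table IO

TRUTH_COLUMNS = (
    "gene_id",
    "source_category",
    "source_protein_id",
    "divergence",
    "scaffold_id",
    "start",
    "end",
    "strand",
)


def write_truth_table(rows: Sequence[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.source_category}\t{r.source_protein_id}\t"
                f"{r.divergence:g}\t{r.scaffold_id}\t{r.start}\t{r.end}\t{r.strand}\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ArgumentError(f"unexpected truth-table header {header}")
        for line in fh:
            g, cat, src, div, sid, start, end, strand = line.rstrip("\n").split("\t")
            rows.append(TruthRow(g, cat, src, float(div), sid, int(start), int(end), strand))
    return rows
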