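"""Sequence utilities: translation, ORF calling, assembly statistics, GC profiling.

The ORF model is deliberately simple and deterministic: ATG-initiated,
stop-terminated, no internal stop, scanned over all six reading frames, and
within one frame overlapping starts yield only the longest ORF per stop codon.
This matches how the synthetic genomes are constructed (intron-free, ATG
starts), so the caller recovers implanted gene models at exact coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .errors import ArgumentError
from .io import OrfRecord, Scaffold

STOP_CODONS = {"TAA", "TAG", "TGA"}
_DNA_RE = re.compile(r"^[ACGTN]*$")


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def translate(dna: str, frame: int = 0, strand: str = "+") -> str:
    """Translate a DNA string under the standard genetic code.

    Stop codons are rendered as ``*``; trailing stops are kept by the caller's
    choice (this function translates everything it is given).  Codons with an
    ambiguous base (N) translate to ``X``.  Non-ACGTN symbols raise
    :class:`ArgumentError`.
    """
    dna = dna.upper()
    if not _DNA_RE.match(dna):
        bad = sorted(set(dna) - set("ACGTN"))
        raise ArgumentError(f"non-ACGTN symbols in DNA: {bad}")
    if strand == "-":
        dna = reverse_complement(dna)
    elif strand != "+":
        raise ArgumentError(f"bad strand {strand!r}")
    sub = dna[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def extract_protein(scaffold_seq: str, start: int, end: int, strand: str) -> str:
    """Protein of a gene spanning [start, end] (1-based, stop codon included)."""
    dna = scaffold_seq[start - 1 : end]
    prot = translate(dna, 0, strand)
    return prot[:-1] if prot.endswith("*") else prot


def six_frame_translations(scaffold: Scaffold) -> list[tuple[str, int, str]]:
    """All six (strand, frame, protein-with-stops) translations of a scaffold."""
    out = []
    for strand in "+-":
        for frame in range(3):
            out.append((strand, frame, translate(scaffold.sequence, frame, strand)))
    return out


def frame_to_genomic(aa_start: int, aa_end: int, strand: str, frame: int, scaffold_len: int) -> tuple[int, int]:
    """Map a 1-based inclusive residue interval of a frame translation to
    1-based inclusive genomic coordinates on the forward strand."""
    nt_off0 = frame + (aa_start - 1) * 3      # 0-based offset in the framed strand
    nt_off1 = frame + aa_end * 3 - 1
    if strand == "+":
        return nt_off0 + 1, nt_off1 + 1
    return scaffold_len - nt_off1, scaffold_len - nt_off0


def find_orfs(scaffold: Scaffold, min_len_aa: int = 10) -> list[OrfRecord]:
    """Call ORFs on both strands, three frames each.

    An ORF is the region from an ATG to the next in-frame stop, with the start
    chosen as the first ATG after the previous in-frame stop (longest ORF per
    stop).  Returned records are sorted by (start, end, strand) and named
    ``<scaffold>_orf<N>`` in that order; only ORFs with protein length
    ``>= min_len_aa`` are reported.
    """
    if min_len_aa < 1:
        raise ArgumentError("min_len_aa must be >= 1")
    seq = scaffold.sequence.upper()
    n = len(seq)
    found: list[tuple[int, int, str, int, str]] = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            i = frame
            pending_start: int | None = None
            while i + 3 <= n:
                codon = s[i : i + 3]
                if pending_start is None and codon == "ATG":
                    pending_start = i
                if codon in STOP_CODONS:
                    if pending_start is not None:
                        aa_len = (i - pending_start) // 3
                        if aa_len >= min_len_aa:
                            lo, hi = pending_start, i + 2  # 0-based incl., stop incl.
                            if strand == "+":
                                found.append((lo + 1, hi + 1, strand, frame, s[lo : hi + 1]))
                            else:
                                found.append((n - hi, n - lo, strand, frame, s[lo : hi + 1]))
                        pending_start = None
                i += 3
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    orfs = []
    for k, (start, end, strand, frame, dna) in enumerate(found, start=1):
        prot = translate(dna, 0, "+")[:-1]
        orfs.append(
            OrfRecord(
                f"{scaffold.scaffold_id}_orf{k}", scaffold.scaffold_id,
                start, end, strand, frame, prot,
            )
        )
    return orfs


@dataclass(frozen=True)
class AssemblyStats:
    """Draft-assembly summary: size, contig count, mean length, N50 and the
    proportions of contigs shorter than 1 kb / longer than 10 kb (by count,
    strict inequalities)."""

    genome_size_bp: int
    n_contigs: int
    mean_length_bp: float
    n50_bp: int
    prop_lt_1kb: float
    prop_gt_10kb: float


def assembly_stats(scaffolds: list[Scaffold]) -> AssemblyStats:
    if not scaffolds:
        raise ArgumentError("assembly_stats requires at least one scaffold")
    lengths = np.array(sorted((len(s) for s in scaffolds), reverse=True))
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2)])
    return AssemblyStats(
        genome_size_bp=total,
        n_contigs=len(lengths),
        mean_length_bp=float(total / len(lengths)),
        n50_bp=n50,
        prop_lt_1kb=float((lengths < 1000).mean()),
        prop_gt_10kb=float((lengths > 10000).mean()),
    )


def gc_content(dna: str) -> float:
    if not dna:
        raise ArgumentError("empty sequence")
    g = dna.count("G") + dna.count("C")
    return g / len(dna)


def gc_profile(
    scaffold: Scaffold,
    window_bp: int,
    step_bp: int,
    homogeneity_band: float = 0.10,
) -> tuple[list[tuple[int, float]], bool]:
    """Sliding-window GC along a scaffold.

    Windows start at offsets 0, step, 2·step, ... while a full window fits.
    Returns the (0-based window start, GC fraction) list and a homogeneity
    verdict: ``True`` iff max window GC − min window GC ≤ ``homogeneity_band``.
    """
    if not (window_bp >= step_bp >= 1):
        raise ArgumentError("need window_bp >= step_bp >= 1")
    seq = scaffold.sequence
    if len(seq) < window_bp:
        raise ArgumentError(
            f"scaffold {scaffold.scaffold_id} shorter ({len(seq)}) than window ({window_bp})"
        )
    windows = []
    for off in range(0, len(seq) - window_bp + 1, step_bp):
        windows.append((off, gc_content(seq[off : off + window_bp])))
    gcs = [g for _, g in windows]
    return windows, (max(gcs) - min(gcs)) <= homogeneity_band
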