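# Methods

## Scope and model of the analysis

The package treats "candidate horizontal sequence transfer between an amoebal
host genome and giant-virus ORFomes" as a chain of operational definitions,
each deterministic given its inputs:

* a gene's **taxonomic origin** is the category of its single best database
  hit under fixed thresholds (identity ≥ 30 %, E ≤ 10⁻², query coverage
  ≥ 30 %), with *ORFan* for no passing hit;
* a **transfer candidate** is a virus-labeled gene that is longer than
  100 aa and sits on a scaffold whose annotated genes are in strict
  non-viral majority (ORFans count as non-viral, ties fail) — the context
  gate separates genuinely integrated genes from stray viral scaffolds in a
  draft assembly;
* a candidate's **re-screen pattern** summarises the composition of its
  merged pool of significant hits (E < 10⁻⁴ and alignment strictly longer
  than 100 aa, pooled from a cellular-reference search and an amoebal
  proteome search): viral-majority / amoebal-majority at > 50 % of passing
  hits, else mixed;
* a **transfer direction** is read off a gene tree by nesting rules
  (below), not by eye.

These definitions are deliberately explicit where the underlying practice is
usually a pipeline of external tools; the single-best-hit origin call in
particular replaces LCA-style classifiers, a simplification that every report
header states.

## Alignment engine and statistics

All protein comparisons are exhaustive local Smith–Waterman with affine gaps
(a gap of length k costs open + k·extend; defaults BLOSUM62, open 11,
extend 1), executed through Biopython's C `PairwiseAligner`. There is no
heuristic seeding: at the package's desk scale, full dynamic programming is
affordable and keeps results exactly reproducible. Best-hit searches compute
score-only DP against every subject and retrieve a full alignment only while
a candidate can still pass the E-value gate (scores are scanned in
descending order, so the first passing alignment is the best hit); ties
break by e-value, then raw score, then lexicographic subject id.

E-values follow Karlin–Altschul, E = K·m·n·exp(−λS), with the published
gapped-BLOSUM62 constants λ = 0.267 and K = 0.041 held fixed, m the query
length and n the total residue count of the searched database. This is
deterministic and adequate for threshold logic; it does not reproduce any
BLAST release bit-for-bit (no composition-based statistics, no length
corrections). Identity is identities / alignment columns (gap columns in
the denominator); `X` and the stop symbol `*` never count as identities.
Coverage is query-side (aligned query residues / query length), the common
convention when the screened unit is the query gene; subject coverage is
carried in every hit record for transparency.

## Trees and direction calls

Distances on pre-aligned, equal-length proteins are Poisson-corrected,
d = −ln(1 − p), with p the mismatch fraction over columns where neither
sequence is gapped; p ≥ 0.95 clamps to d = 3.0 to keep matrices finite.
Neighbor joining is the classical Q-criterion agglomeration with fully
deterministic tie-breaking (lexicographically smallest cluster-label pair)
and negative branch lengths clamped to zero with the deficit moved to the
sister edge. Multiple-alignment construction is delegated: synthetic gene
families are generated ungapped, and real data should be aligned externally
before entering this module.

Direction inference roots the gene tree at an `other_cellular` outgroup
leaf when one exists, else at the midpoint (the rooting used is recorded in
every call). With A = amoebal leaves ∪ {query} and V = viral leaves:

* **virus → amoeba**: A is monophyletic, its sister group is exclusively
  viral, and V is *not* monophyletic (the amoebal gene nests inside viral
  diversity);
* **amoeba → virus**: the mirror condition;
* anything else — including two clean sister clades, which support neither
  direction — is **inconclusive**.

No topology can satisfy both rules, because each requires the other group
to be paraphyletic. Ancestral sequences use Fitch parsimony
(intersection/union bottom-up, alphabetically smallest root state, gaps
treated as missing).

## Rhizome scan

Fenestration slices a protein into 40-aa windows advanced by 20 aa; a
protein shorter than one window yields a single whole-length fragment, and
trailing residues past the last full window get no extra anchored window so
fragment statistics stay comparable across genes (fragment count is exactly
⌊(L−40)/20⌋+1). Fragment classification reuses the scan thresholds with the
coverage gate waived — fragments are already single windows — and reports
domain-level origins (virus / eukaryote / bacteria / archaea) matching the
conventional rhizome legend; viral family detail stays in the fragment
record. The mosaicism index is distinct classified origins / classified
fragments.

## Synteny

Blocks are scaffolds carrying at least 3 virus-labeled genes (coordinate
order). Presence in a target genome uses reciprocal best hits, not one-way
hits, to avoid paralog inflation. Collinearity is LCS of the block's gene
order against the partner order along a single target scaffold, taking the
better of source order and its full reversal — draft scaffolds have
arbitrary orientation. Partners scattered across target scaffolds count
toward presence but cap the order score, keeping "present" and "in synteny"
separate questions. The genome tree shown beside the conservation matrix
uses 1 − Jaccard distances on ortholog-group membership followed by
neighbor joining — a desk-scale stand-in for a whole-genome-alignment tree.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the screens rely on:

* **Host genomes** — multi-scaffold, intron-free ATG…stop genes on both
  strands, intergenic spacers uniform in [30, 300] nt, background GC tuned
  to a target (default 0.583, the amoebal value quoted alongside the ~0.60
  GC of pandoraviruses) within ±0.02 via GC-weighted synonymous-codon
  choice plus compensating spacer composition. Host protein lengths are
  N(200, 40) aa truncated at 60; reference-panel proteins default to
  N(250, 50) aa. Every gene is written with an in-frame stop codon
  immediately upstream of its start codon, which pins the longest-per-stop
  ORF caller to the annotated start and makes truth-table recovery exact —
  a construction guarantee, not an empirical observation.
* **Transfers** — sampled panel proteins, substituted per site at the
  requested divergence (uniform replacement by a different residue; no
  rate matrix, since every downstream filter depends only on identity
  fraction), reverse-translated with *uniform* codon choice so implants
  keep a detectable compositional signal against the tuned host background,
  then spliced into intergenic space with ≥ 30 nt pads. Divergence is a
  free parameter (0–0.6): how diverged real transferred genes are is
  unknown, so no default is pretended.
* **Mosaic genes** — ≥ 2 segments of ≥ 20 aa copied from labeled sources,
  tiling the protein without gaps or overlap.

Deliberately absent: realistic codon-usage models, introns and alternative
starts, sequencing/assembly error, paralogous gene families within the host
background, and database-scale reference diversity. Passing the synthetic
suites therefore demonstrates that the *decision logic* is correct and
well-calibrated under its own assumptions — not that the thresholds would
reproduce any specific counts against live public databases, which depend
on database versions and are out of scope.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| identity_min | 30 | % | homolog-screen gate |
| evalue_max | 1e-2 | — | homolog-screen gate |
| coverage_min | 30 | % of query | homolog-screen gate |
| rescreen evalue | < 1e-4 (strict) | — | significance for the merged pool |
| rescreen alignment length | > 100 (strict) | aa | significance for the merged pool |
| candidate length gate | > 100 | aa | excludes short, noise-prone ORFs |
| COG e-value | 0.1 | — | permissive functional annotation |
| fenestration | 40 / 20 | aa window / step | rhizome granularity |
| min_viral_genes | 3 | genes/scaffold | synteny block selection |
| host GC target | 0.583 | fraction | amoebal background |
| distance ceiling | 3.0 | subst./site | saturation clamp at p ≥ 0.95 |

## Numerical and edge-case conventions

1-based inclusive coordinates everywhere, matching GFF3; gene spans include
the stop codon. `N` codons translate to `X`. Assembly-statistic proportions
use strict inequalities ("< 1 kb", "> 10 kb") over contig counts; N50 is
the length at which descending cumulative lengths first reach half the
total. Strict majorities throughout (context gate ties fail; re-screen
needs > 50 %); an empty re-screen pool yields *mixed* with a warning rather
than an error. Report percentages are rounded per statistic the way such
breakdowns are conventionally printed: family and COG shares as integer
percent (one decimal below 1 %), gene-set shares at one decimal.

## Evaluation problem sizes

The reproduction script and acceptance suite run: implant recovery on
20-scaffold genomes (200 host genes, 12 implants, 3 viral families × 8
proteins plus 4 cellular panels × 8 as the database) over 20 seeded
replicates at divergence 0 and 0.1; aligner-vs-oracle agreement on 500
random pairs of 5–30 aa; neighbor-joining recovery on 100 random additive
5–8 taxon matrices; the six designed direction topologies plus intermixed
controls; a three-source mosaic gene at zero divergence; and a three-genome
synteny design (full / partial-reversed / absent conservation). These sizes
are the package's chosen study conditions for a single-CPU desk run.

## Known limitations

Single-best-hit labeling is cruder than LCA classification and can
over-assign categories when references are sparse. Karlin–Altschul
constants are fixed, so absolute E-values at extreme compositions are
approximate. The ORF caller is ATG-only and intron-blind by design, matched
to the synthetic genomes; real eukaryotic annotation requires a dedicated
gene predictor upstream. Frameshift-aware alignment is not implemented, so
the six-frame scan reports per-frame loci only. Published absolute counts
from live-database analyses (total viral-best-hit genes, scan-hit totals)
are environment-dependent and are not targets of this package.
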