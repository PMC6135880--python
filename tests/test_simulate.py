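import random

import pytest

from amoebahgt.align import align_pair
from amoebahgt.errors import ArgumentError
from amoebahgt.seqcore import gc_content, translate
from amoebahgt.simulate import (
    generate_host_genome,
    generate_reference_panels,
    implant_transfers,
    make_mosaic_gene,
    mutate_protein,
    read_truth_table,
)


class TestReferencePanels:
    def test_counts(self):
        panels, cellular, tax = generate_reference_panels(3, 10, (300, 50), seed=1)
        assert sum(len(p.proteins) for p in panels) == 30
        assert len(panels) == 3
        assert set(cellular) == {"amoebozoa", "other_eukaryote", "bacteria", "archaea"}

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_reference_panels(2, 4, (120, 20), seed=9, out_dir=a)
        generate_reference_panels(2, 4, (120, 20), seed=9, out_dir=b)
        assert (a / "panels.fasta").read_bytes() == (b / "panels.fasta").read_bytes()
        assert (a / "taxonomy.tsv").read_bytes() == (b / "taxonomy.tsv").read_bytes()

    def test_zero_sd_length(self):
        panels, _, _ = generate_reference_panels(1, 1, (100, 0), seed=7)
        (pid, seq), = panels[0].proteins
        assert len(seq) == 100

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ArgumentError):
            generate_reference_panels(0, 5, (100, 10), seed=1)


class TestHostGenome:
    def test_truth_table_count(self):
        genome = generate_host_genome(5, 10, 0.583, seed=2)
        assert len(genome.truth) == 50
        assert all(r.source_category == "host" for r in genome.truth)

    def test_orfs_have_no_internal_stop(self):
        genome = generate_host_genome(3, 5, 0.5, seed=4)
        seqs = genome.scaffold_map()
        for o in genome.orfs:
            dna = seqs[o.scaffold_id].sequence[o.start - 1 : o.end]
            prot = translate(dna, 0, o.strand)
            assert prot.endswith("*") and "*" not in prot[:-1]
            assert prot[:-1] == o.protein

    def test_gc_within_band(self):
        genome = generate_host_genome(20, 20, 0.50, seed=3)
        gc = gc_content("".join(s.sequence for s in genome.scaffolds))
        assert 0.48 <= gc <= 0.52

    def test_gc_target_validated(self):
        with pytest.raises(ArgumentError):
            generate_host_genome(2, 2, 1.5, seed=1)

    def test_truth_rows_match_gff_genes(self, tmp_path):
        genome = generate_host_genome(4, 6, 0.583, seed=5)
        genome.write(tmp_path)
        truth = read_truth_table(tmp_path / "host.truth.tsv")
        assert {r.gene_id for r in truth} == {o.gene_id for o in genome.orfs}

    def test_intergenic_spacing_at_least_30(self):
        genome = generate_host_genome(4, 8, 0.583, seed=6)
        for sid in {o.scaffold_id for o in genome.orfs}:
            spans = sorted(
                (o.start, o.end) for o in genome.orfs if o.scaffold_id == sid
            )
            for (_, e1), (s2, _) in zip(spans, spans[1:]):
                assert s2 - e1 - 1 >= 30


class TestImplants:
    def test_zero_divergence_is_exact_copy(self, small_panels):
        panels, _, _ = small_panels
        sources = {pid: seq for p in panels for pid, seq in p.proteins}
        genome = generate_host_genome(4, 4, 0.583, seed=7)
        modified = implant_transfers(genome, panels, 5, 0.0, seed=8)
        implants = [r for r in modified.truth if r.source_category.startswith("viral")]
        assert len(implants) == 5
        prot = {o.gene_id: o.protein for o in modified.orfs}
        for r in implants:
            assert prot[r.gene_id] == sources[r.source_protein_id]

    def test_implant_count_in_truth(self, small_panels):
        panels, _, _ = small_panels
        genome = generate_host_genome(6, 5, 0.583, seed=9)
        modified = implant_transfers(genome, panels, 12, 0.1, seed=5)
        viral_rows = [r for r in modified.truth if r.source_category.startswith("viral")]
        assert len(viral_rows) == 12

    def test_host_genes_not_disrupted(self, small_panels):
        panels, _, _ = small_panels
        genome = generate_host_genome(4, 5, 0.583, seed=10)
        modified = implant_transfers(genome, panels, 6, 0.2, seed=11)
        seqs = modified.scaffold_map()
        originals = {o.gene_id: o.protein for o in genome.orfs}
        for o in modified.orfs:
            if o.gene_id in originals:
                dna = seqs[o.scaffold_id].sequence[o.start - 1 : o.end]
                assert translate(dna, 0, o.strand)[:-1] == originals[o.gene_id]

    def test_identity_tracks_divergence(self, small_panels):
        """Implants at 10% divergence align to their sources at ~90% identity."""
        panels, _, _ = small_panels
        sources = {pid: seq for p in panels for pid, seq in p.proteins}
        genome = generate_host_genome(6, 5, 0.583, seed=12)
        modified = implant_transfers(genome, panels, 10, 0.1, seed=13)
        prot = {o.gene_id: o.protein for o in modified.orfs}
        idents = [
            align_pair(prot[r.gene_id], sources[r.source_protein_id]).identity_pct
            for r in modified.truth
            if r.source_category.startswith("viral")
        ]
        mean = sum(idents) / len(idents)
        assert 87.0 <= mean <= 93.0

    def test_too_many_transfers_rejected(self, small_panels):
        panels, _, _ = small_panels
        genome = generate_host_genome(2, 2, 0.583, seed=14)
        with pytest.raises(ArgumentError):
            implant_transfers(genome, panels, 10_000, 0.1, seed=1)

    def test_divergence_range_validated(self, small_panels):
        panels, _, _ = small_panels
        genome = generate_host_genome(2, 2, 0.583, seed=15)
        with pytest.raises(ArgumentError):
            implant_transfers(genome, panels, 1, 0.9, seed=1)


def test_divergence_calibration():
    """Observed substitution fraction matches the requested rate within
    binomial sampling error."""
    rng = random.Random(42)
    protein = "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(4999))
    for rate in (0.05, 0.2, 0.5):
        mutated = mutate_protein(protein, rate, rng)
        observed = sum(a != b for a, b in zip(protein[1:], mutated[1:])) / 4999
        assert abs(observed - rate) < 3 * (rate * (1 - rate) / 4999) ** 0.5 + 1e-9


class TestMosaic:
    def _sources(self):
        rng = random.Random(20)
        make = lambda n: "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))
        return {
            "v1": ("virus:pandora_like", make(300)),
            "b1": ("bacteria", make(300)),
            "e1": ("other_eukaryote", make(300)),
        }

    def test_three_segments_tile_protein(self):
        sources = self._sources()
        spec = [
            ("virus:pandora_like", "v1", 40),
            ("bacteria", "b1", 40),
            ("other_eukaryote", "e1", 40),
        ]
        protein, intervals = make_mosaic_gene(spec, sources, seed=1)
        assert len(protein) == 120
        assert [(a, b) for a, b, *_ in intervals] == [(1, 40), (41, 80), (81, 120)]

    def test_single_segment_rejected(self):
        sources = self._sources()
        with pytest.raises(ArgumentError):
            make_mosaic_gene([("bacteria", "b1", 40)], sources, seed=1)

    def test_segment_is_substring_of_source(self):
        sources = self._sources()
        protein, intervals = make_mosaic_gene(
            [("virus:pandora_like", "v1", 40), ("bacteria", "b1", 40)], sources, seed=2
        )
        for start, end, _cat, pid in intervals:
            assert protein[start - 1 : end] in sources[pid][1]

    def test_unknown_source_rejected(self):
        with pytest.raises(ArgumentError):
            make_mosaic_gene(
                [("bacteria", "nope", 40), ("bacteria", "nope", 40)], self._sources(), seed=1
            )
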