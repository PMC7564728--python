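"""Generator self-verification: every artifact recovers its truth."""

import numpy as np
import pytest

from tlpkit.gene_structure import spliced_cds, translate_cds
from tlpkit.io_formats import read_fasta, read_hit_table
from tlpkit.phylogeny import distance_matrix
from tlpkit.signature_scan import (
    CBM_CANONICAL, CBM_VARIANT, candidate_funnel, detect_cbm, scan,
)
from tlpkit.protein_features import count_cysteines
from tlpkit.synthetic_data import (
    build_gene_model, design_protein, evolve_alignment, make_expression,
    make_genome,
)


class TestDesignProtein:
    def test_signature_and_cysteines_self_verify(self, signature):
        d = design_protein(250, 16, with_signature=True,
                           cbm_class="canonical", seed=1)
        matches = scan(d.record, signature)
        assert any((m.start, m.end) == d.signature_span for m in matches)
        assert count_cysteines(d.record.sequence) == 16
        assert detect_cbm(d.record).canonical is True

    def test_variant_cbm_planted(self, signature):
        d = design_protein(250, 16, True, "variant", seed=2)
        rep = detect_cbm(d.record)
        assert (rep.canonical, rep.variant) == (False, True)

    def test_negative_control_has_no_signature(self, signature):
        d = design_protein(250, 10, with_signature=False, seed=3)
        assert scan(d.record, signature) == []
        assert d.signature_span is None

    def test_broken_signature_decoy_rejected_by_engine(self, signature):
        d = design_protein(250, 10, with_signature=False, seed=4,
                           break_signature=True)
        assert scan(d.record, signature) == []

    def test_same_seed_reproducible(self):
        a = design_protein(250, 16, True, "canonical", seed=9)
        b = design_protein(250, 16, True, "canonical", seed=9)
        assert a.record.sequence == b.record.sequence
        assert a.signature_span == b.signature_span

    @pytest.mark.parametrize("length,n_cys", [(20, 5), (250, 1), (250, 240)])
    def test_infeasible_constraints_rejected(self, length, n_cys):
        with pytest.raises(ValueError):
            design_protein(length, n_cys, with_signature=True, seed=0)


class TestBuildGeneModel:
    @pytest.fixture()
    def protein(self):
        return design_protein(120, 6, True, seed=5,
                              protein_id="SYNX001G.1").record

    def test_single_exon_length_arithmetic(self, protein):
        model, _ = build_gene_model(protein, 1, "1H", 1, "+", seed=0)
        assert model.cds_length == 3 * (len(protein) + 1)
        assert model.exon_count == 1

    @pytest.mark.parametrize("exon_count", [1, 2, 3, 4])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_extract_splice_translate_round_trip(self, protein, exon_count,
                                                 strand):
        model, gseq = build_gene_model(protein, exon_count, "1H", 1,
                                       strand, seed=7)
        assert translate_cds(spliced_cds(model, gseq)) == protein.sequence

    def test_introns_have_gt_ag_ends(self, protein):
        model, gseq = build_gene_model(protein, 3, "1H", 1, "+", seed=8)
        for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
            intron = gseq[e1:s2 - 1]
            assert intron.startswith("GT") and intron.endswith("AG")

    def test_same_seed_identical_output(self, protein):
        m1, g1 = build_gene_model(protein, 2, "1H", 1, "+", seed=11)
        m2, g2 = build_gene_model(protein, 2, "1H", 1, "+", seed=11)
        assert g1 == g2 and m1 == m2


class TestMakeGenome:
    def test_funnel_recovers_planted_loci_exactly(self, small_genome,
                                                  signature):
        """Planted-truth recovery: precision and recall both 1.0, and
        the default bundle reproduces the 32-transcript/19-locus
        collapse."""
        g = small_genome
        retained, report = candidate_funnel(g.proteome, g.hits, signature,
                                            g.locus_map)
        retained_ids = set(report.retained_ids)
        expected = g.truth.expected_retained
        assert retained_ids == expected  # recall 1.0 and precision 1.0
        assert report.n_with_signature == 32
        assert report.n_unique_loci == 19

    def test_truth_metadata_self_verifies(self, small_genome, signature):
        g = small_genome
        by_id = {p.protein_id: p for p in g.proteome}
        for entry in g.truth.planted.values():
            longest = by_id[entry.longest_transcript]
            assert count_cysteines(longest.sequence) == entry.n_cysteine
            assert any((m.start, m.end) == entry.signature_span
                       for m in scan(longest, signature))
            rep = detect_cbm(longest)
            assert rep.canonical == (entry.cbm_class == "canonical")
            assert rep.variant == (entry.cbm_class == "variant")
            model = g.gene_models[entry.longest_transcript]
            assert model.exon_count == entry.exon_count
            assert model.chromosome == entry.chromosome

    def test_decoys_lack_signature_but_some_pass_evalue(self, small_genome,
                                                        signature):
        g = small_genome
        by_id = {p.protein_id: p for p in g.proteome}
        decoy_hits = [h for h in g.hits if h.query_id in g.truth.decoy_ids]
        assert any(h.e_value <= 1e-10 for h in decoy_hits)
        assert any(h.e_value > 1e-10 for h in decoy_hits)
        for did in g.truth.decoy_ids:
            assert scan(by_id[did], signature) == []

    def test_whole_genome_splice_translate_round_trip(self, small_genome):
        g = small_genome
        by_id = {p.protein_id: p for p in g.proteome}
        for tid, model in g.gene_models.items():
            cds = spliced_cds(model, g.chromosomes[model.chromosome])
            assert translate_cds(cds) == by_id[tid].sequence

    def test_tandem_cluster_on_one_chromosome(self, small_genome):
        g = small_genome
        clustered = [e for e in g.truth.planted.values()
                     if e.tandem_cluster_id is not None]
        assert len(clustered) == 4
        assert {e.chromosome for e in clustered} == {"5H"}

    def test_empty_genome(self, signature):
        g = make_genome(n_true=0, n_decoy=2, n_isoform_extra=0, seed=1,
                        tandem_spec={}, dense_chromosomes=True)
        retained, report = candidate_funnel(g.proteome, g.hits, signature,
                                            g.locus_map)
        assert retained == []
        assert report.n_unique_loci == 0

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            make_genome(n_true=3, n_decoy=2, n_isoform_extra=2, seed=5,
                        tandem_spec={}, dense_chromosomes=True).write(
                tmp_path / sub)
        for name in ("proteome.fasta", "genome.fasta", "models.gff3",
                     "hits.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_written_bundle_reloads(self, tmp_path):
        g = make_genome(n_true=3, n_decoy=2, n_isoform_extra=2, seed=5,
                        tandem_spec={}, dense_chromosomes=True)
        g.write(tmp_path)
        proteome = read_fasta(tmp_path / "proteome.fasta")
        hits = read_hit_table(tmp_path / "hits.tsv")
        assert {p.protein_id for p in proteome} == \
            {p.protein_id for p in g.proteome}
        assert len(hits) == len(g.hits)


class TestEvolveAlignment:
    def test_zero_length_branches_identical(self):
        aln = evolve_alignment("((A:0,B:0):0,(C:0,D:0):0);", 100, seed=2)
        assert len(set(aln.rows)) == 1

    def test_same_seed_identical(self):
        newick = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);"
        a = evolve_alignment(newick, 200, seed=6)
        b = evolve_alignment(newick, 200, seed=6)
        assert a == b

    def test_poisson_distance_estimates_path_length(self):
        """Law of large numbers: at 10k sites the Poisson-corrected
        distance approaches the true path length within 3 standard
        errors."""
        t = 0.15  # per-branch -> path length 0.3
        aln = evolve_alignment(f"(A:{t},B:{t},C:{t});", 10_000, seed=14)
        dm = distance_matrix(aln, "poisson")
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            d = dm[a, b]
            p = 1 - np.exp(-d)
            se = np.sqrt(p * (1 - p) / 10_000) / (1 - p)
            assert abs(d - 2 * t) < 3 * se + 0.01  # small multi-hit bias


class TestMakeExpression:
    def test_zero_noise_exact_means(self):
        profiles = {"g1": [1.0, 2.0], "g2": [3.0, 4.0]}
        m = make_expression(profiles, tissues=("EMB", "LEA"), noise_sd=0,
                            seed=0)
        assert np.allclose(m.values, [[1, 2], [3, 4]])

    def test_values_clipped_non_negative(self):
        m = make_expression({"g1": [0.1] * 8}, noise_sd=5.0, seed=1)
        assert (m.values >= 0).all()

    def test_same_seed_identical(self):
        profiles = {"g1": [5.0] * 8, "g2": [1.0] * 8}
        a = make_expression(profiles, noise_sd=1.0, seed=4)
        b = make_expression(profiles, noise_sd=1.0, seed=4)
        assert np.allclose(a.values, b.values)
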