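"""Generators: determinism, planted truth, and closed-form expectations."""

import numpy as np
import pytest

from oyescan import io as oio
from oyescan import synthgen as sg
from oyescan.seqs import revcomp


def _file_bytes(d):
    return {p.name: p.read_bytes() for p in sorted(d.iterdir())}


class TestPangenome:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        design = sg.PangenomeDesign(
            phenotype={"a": sg.POSITIVE, "b": sg.NEGATIVE},
            decoy_family_ids=("d0",), protein_len=60,
        )
        sg.gen_pangenome(design, 11, tmp_path / "x")
        sg.gen_pangenome(design, 11, tmp_path / "y")
        assert _file_bytes(tmp_path / "x") == _file_bytes(tmp_path / "y")
        sg.gen_pangenome(design, 12, tmp_path / "z")
        assert _file_bytes(tmp_path / "x") != _file_bytes(tmp_path / "z")

    def test_planted_presence_equals_phenotype(self, small_pangenome):
        design, _, truth = small_pangenome
        assert truth.presence_vector(design.planted_family_id) == truth.phenotype_vector()

    def test_decoys_violate_phenotype_and_are_nonempty(self, small_pangenome):
        design, _, truth = small_pangenome
        pheno = truth.phenotype_vector()
        for fam in design.decoy_family_ids:
            vec = truth.presence_vector(fam)
            assert vec != pheno
            assert any(vec)

    def test_zero_decoys_single_family_truth_table(self, tmp_path):
        design = sg.PangenomeDesign(
            phenotype={"a": sg.POSITIVE, "b": sg.NEGATIVE}, protein_len=60)
        truth = sg.gen_pangenome(design, 1, tmp_path)
        table = oio.read_table(tmp_path / "truth_presence.tsv")
        assert len(table) == 1
        assert set(truth.presence) == {design.planted_family_id}

    def test_one_class_only_is_refused(self):
        with pytest.raises(ValueError, match="positive"):
            sg.PangenomeDesign(phenotype={"a": sg.POSITIVE, "b": sg.POSITIVE})

    def test_fusion_carriers_must_carry_planted_family(self):
        with pytest.raises(ValueError, match="fusion_carriers"):
            sg.PangenomeDesign(
                phenotype={"a": sg.POSITIVE, "b": sg.NEGATIVE},
                fusion_carriers=frozenset({"b"}),
            )

    def test_genes_do_not_overlap_and_fit_contigs(self, small_pangenome):
        _, genomes, _ = small_pangenome
        for genome in genomes:
            for contig in genome.contigs:
                ordered = genome.genes_on(contig)
                for g1, g2 in zip(ordered, ordered[1:]):
                    assert g1.end < g2.start
                for g in ordered:
                    assert g.end <= len(genome.contigs[contig])

    def test_cds_translates_to_protein(self, small_pangenome):
        from Bio.Seq import Seq

        _, genomes, _ = small_pangenome
        g = genomes[0]
        rec = g.genes[0]
        cds = g.contigs[rec.contig][rec.start - 1 : rec.end]
        assert str(Seq(cds).translate()) == "M" + rec.protein + "*"

    def test_fused_gene_has_concatenated_length(self, small_pangenome):
        design, genomes, truth = small_pangenome
        gene_id, junction = truth.fused["p2"]
        prot = next(
            g for gen in genomes for g in gen.genes if g.gene_id == gene_id
        ).protein
        assert junction == design.protein_len
        assert len(prot) == design.protein_len + design.partner_len


class TestFamilySet:
    def test_zero_substitution_prob_gives_identical_leaves(self):
        model = sg.FamilyModel("ACDEFGHIKL" * 5, {"x": 4}, per_branch_sub_prob=0.0)
        leaves = sg.build_family_set(model, 3)
        assert all(seq == model.ancestor for _, _, seq in leaves)

    def test_diagnostic_residues_exact_by_construction(self):
        model = sg.FamilyModel(
            "A" * 60, {"steroid": 5, "bile": 5}, per_branch_sub_prob=0.3,
            diagnostic_columns={17: {"steroid": "N", "bile": "Y"}},
        )
        for _, label, seq in sg.build_family_set(model, 4):
            assert seq[16] == {"steroid": "N", "bile": "Y"}[label]

    def test_diagnostic_column_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="diagnostic column"):
            sg.FamilyModel("A" * 10, {"x": 2}, diagnostic_columns={11: {"x": "N"}})

    def test_within_clade_identity_matches_closed_form(self):
        p = 0.12
        length = 400
        model = sg.FamilyModel(
            sg.random_protein(np.random.default_rng(0), length),
            {"c": 24}, per_branch_sub_prob=p,
        )
        leaves = [s for _, _, s in sg.build_family_set(model, 9)]
        idents = [
            np.mean([a == b for a, b in zip(leaves[i], leaves[j])])
            for i in range(len(leaves)) for j in range(i + 1, len(leaves))
        ]
        expected = sg.expected_within_clade_identity(p, 0, length)
        assert abs(np.mean(idents) - expected) < 0.03


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(5)
    panel = {"g1": sg.random_dna(rng, 500), "g2": sg.random_dna(rng, 600)}
    bg = sg.random_background(rng, 2, 2000)
    return panel, bg


class TestMetagenome:
    def test_zero_error_reads_are_source_substrings(self, setup, tmp_path):
        panel, bg = setup
        design = sg.MetagenomeDesign(
            groups={"f": 2}, carriage={"f": {"g1": 1.0, "g2": 1.0}},
            depth=50, read_length=40, error_prob=0.0,
        )
        sg.gen_metagenome(design, panel, bg, 1, tmp_path)
        sources = list(panel.values()) + list(bg.values())
        for fq in tmp_path.glob("*.fastq"):
            for _, seq in oio.read_fastq(fq):
                assert any(seq in s or revcomp(seq) in s for s in sources)

    def test_depth_equals_fastq_record_count(self, setup, tmp_path):
        panel, bg = setup
        design = sg.MetagenomeDesign(
            groups={"f": 1}, carriage={"f": {"g1": 1.0}}, depth=1000,
            read_length=50,
        )
        sg.gen_metagenome(design, panel, bg, 2, tmp_path)
        (fq,) = list(tmp_path.glob("*.fastq"))
        assert len(oio.read_fastq(fq)) == 1000

    def test_read_count_conservation_across_runs(self, setup, tmp_path):
        panel, bg = setup
        design = sg.MetagenomeDesign(
            groups={"f": 2}, carriage={"f": {"g1": 0.5}}, depth=200,
            read_length=50, runs_per_sample=3,
        )
        truths = sg.gen_metagenome(design, panel, bg, 3, tmp_path)
        meta = oio.read_table(tmp_path / "metadata.tsv")
        for t in truths:
            runs = meta[meta.biosample == t.biosample]["run"]
            assert len(runs) == 3
            total = sum(len(oio.read_fastq(tmp_path / f"{r}.fastq")) for r in runs)
            assert total == design.depth * design.runs_per_sample

    def test_certain_carriage_marked_in_truth(self, setup, tmp_path):
        panel, bg = setup
        design = sg.MetagenomeDesign(
            groups={"f": 4}, carriage={"f": {"g1": 1.0, "g2": 0.0}},
            depth=20, read_length=50,
        )
        truths = sg.gen_metagenome(design, panel, bg, 4, tmp_path)
        assert all(t.carried["g1"] and not t.carried["g2"] for t in truths)

    def test_empty_panel_rejected(self, setup):
        _, bg = setup
        design = sg.MetagenomeDesign(groups={"f": 1}, carriage={"f": {}}, depth=10)
        with pytest.raises(ValueError, match="panel is empty"):
            sg.MetagenomeSimulator(design, {}, bg, 0)

    def test_read_longer_than_shortest_source_rejected(self, setup):
        panel, bg = setup
        design = sg.MetagenomeDesign(
            groups={"f": 1}, carriage={"f": {"g1": 1.0}}, depth=10,
            read_length=501,
        )
        with pytest.raises(ValueError, match="read_length"):
            sg.MetagenomeSimulator(design, panel, bg, 0)


def test_truth_has_no_fusion_carrier_without_planted_family(small_pangenome):
    design, _, truth = small_pangenome
    carriers = {g for g, _ in truth.members[design.planted_family_id]}
    assert set(truth.fused) <= carriers
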