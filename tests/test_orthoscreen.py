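"""Orthogroup clustering and the phenotype-concordance screen."""

import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oyescan import orthoscreen as ortho
from oyescan import synthgen as sg


def _brute_force_affine(a: str, b: str, open_=11, ext=1) -> float:
    """Independent recursion over all global alignments with affine gaps
    (a length-n gap costs open + n*ext)."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")

    def sub(x, y):
        if "X" in (x, y):
            return 0.0
        return m[x][y]

    @functools.lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -1e30
        if i < len(a) and j < len(b):
            best = max(best, sub(a[i], b[j]) + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = ext if state == "a" else open_ + ext
            best = max(best, -cost + rec(i + 1, j, "a"))
        if j < len(b):
            cost = ext if state == "b" else open_ + ext
            best = max(best, -cost + rec(i, j + 1, "b"))
        return best

    return rec(0, 0, "m")


class TestAlignScore:
    def test_self_alignment_sums_diagonal_scores(self):
        _, raw = ortho.align_score("ACDEF", "ACDEF")
        assert raw == 30  # 4+9+6+5+6

    def test_single_residue_vs_empty_costs_open_plus_extend(self):
        _, raw = ortho.align_score("A", "")
        assert raw == -12

    def test_symmetry(self, rng):
        from oyescan.seqs import random_protein

        for _ in range(5):
            a = random_protein(rng, int(rng.integers(3, 15)))
            b = random_protein(rng, int(rng.integers(3, 15)))
            assert ortho.align_score(a, b) == ortho.align_score(b, a)

    def test_matches_brute_force_on_short_pairs(self, rng):
        from oyescan.seqs import random_protein

        for _ in range(15):
            a = random_protein(rng, int(rng.integers(1, 9)))
            b = random_protein(rng, int(rng.integers(1, 9)))
            _, raw = ortho.align_score(a, b)
            assert raw == pytest.approx(_brute_force_affine(a, b))

    def test_x_scores_zero(self):
        _, raw = ortho.align_score("AXA", "AXA")
        assert raw == 8  # 4 + 0 + 4

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            ortho.align_score("AB!", "AAA")


class TestRBH:
    def test_mutual_best_pair_forms_one_orthogroup(self):
        proteomes = {
            "g1": {"a": "MKVLATTLLG" * 4, "x": "WWWWCCCCHH" * 4},
            "g2": {"b": "MKVLATTLLG" * 4, "y": "PPPPGGGGSS" * 4},
        }
        m = ortho.rbh_orthogroups(proteomes, prefilter_kmer_frac=None)
        sizes = sorted(len(v) for v in m.groups.values())
        assert sizes == [1, 1, 2]
        big = next(v for v in m.groups.values() if len(v) == 2)
        assert set(big) == {("g1", "a"), ("g2", "b")}

    def test_all_below_threshold_gives_singletons(self):
        proteomes = {
            "g1": {"a": "MKVLA"},
            "g2": {"b": "WGHCP"},
        }
        m = ortho.rbh_orthogroups(proteomes, min_bits=500, prefilter_kmer_frac=None)
        assert all(len(v) == 1 for v in m.groups.values())

    def test_components_match_planted_families(self, small_pangenome):
        design, genomes, truth = small_pangenome
        proteomes = {g.genome_id: g.proteins() for g in genomes}
        m = ortho.rbh_orthogroups(proteomes, phenotype=design.phenotype)
        planted = set(truth.members[design.planted_family_id])
        assert planted in [set(v) for v in m.groups.values()]
        for fam in design.decoy_family_ids:
            fam_members = set(truth.members[fam])
            if len(fam_members) >= 1:
                assert any(fam_members <= set(v) for v in m.groups.values())

    def test_edge_set_invariant_to_genome_order(self, small_pangenome):
        design, genomes, _ = small_pangenome
        proteomes = {g.genome_id: g.proteins() for g in genomes}
        m1 = ortho.rbh_orthogroups(proteomes, phenotype=design.phenotype)
        rev = dict(reversed(list(proteomes.items())))
        m2 = ortho.rbh_orthogroups(rev, phenotype=design.phenotype)
        assert [set(v) for v in m1.groups.values()] == [set(v) for v in m2.groups.values()]

    def test_prefilter_agrees_with_full_alignment(self, small_pangenome):
        design, genomes, _ = small_pangenome
        proteomes = {g.genome_id: g.proteins() for g in genomes}
        m1 = ortho.rbh_orthogroups(proteomes, prefilter_kmer_frac=0.05)
        m2 = ortho.rbh_orthogroups(proteomes, prefilter_kmer_frac=None)
        assert [set(v) for v in m1.groups.values()] == [set(v) for v in m2.groups.values()]

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty proteome"):
            ortho.rbh_orthogroups({"g1": {"a": "MKV"}, "g2": {}})


def _matrix_from_presence(presence: np.ndarray, pheno: list[bool]) -> ortho.OrthoMatrix:
    genomes = [f"g{i}" for i in range(presence.shape[1])]
    groups = {
        f"OG{r:03d}": [(genomes[c], f"gene{r}_{c}")
                       for c in range(presence.shape[1]) if presence[r, c]]
        for r in range(presence.shape[0])
    }
    return ortho.OrthoMatrix(genomes, groups, presence, pheno)


class TestScreen:
    def test_exact_phenotype_match_selected(self):
        m = _matrix_from_presence(
            np.array([[1, 1, 1, 0, 0, 0]]), [True] * 3 + [False] * 3)
        assert ortho.phenotype_screen(m) == ["OG000"]

    def test_ubiquitous_orthogroup_rejected(self):
        m = _matrix_from_presence(np.ones((1, 4), dtype=int),
                                  [True, True, False, False])
        assert ortho.phenotype_screen(m) == []

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_row_filter(self, data):
        n_og = data.draw(st.integers(1, 12))
        n_g = data.draw(st.integers(2, 8))
        presence = np.array(
            data.draw(st.lists(
                st.lists(st.integers(0, 1), min_size=n_g, max_size=n_g),
                min_size=n_og, max_size=n_og))
        )
        pheno = data.draw(st.lists(st.booleans(), min_size=n_g, max_size=n_g))
        if not (any(pheno) and not all(pheno)):
            pheno[0], pheno[-1] = True, False
        m = _matrix_from_presence(presence, pheno)
        expected = [
            f"OG{r:03d}" for r in range(n_og)
            if all(bool(presence[r, c]) == pheno[c] for c in range(n_g))
        ]
        assert ortho.phenotype_screen(m) == expected

    def test_requires_both_classes(self):
        m = _matrix_from_presence(np.array([[1, 0]]), [True, True])
        with pytest.raises(ValueError, match="phenotype"):
            ortho.phenotype_screen(m)


class TestLabelFilter:
    def test_keeps_only_labeled_candidates(self):
        m = _matrix_from_presence(np.array([[1, 1], [1, 1], [1, 1]]),
                                  [True, False])
        labels = {"gene0_0": "OYE", "gene1_1": "OYE"}
        kept = ortho.label_filter(["OG000", "OG001", "OG002"], m, labels, "OYE")
        assert kept == ["OG000", "OG001"]

    def test_empty_label_table_keeps_nothing(self):
        m = _matrix_from_presence(np.array([[1, 1]]), [True, False])
        assert ortho.label_filter(["OG000"], m, {}, "OYE") == []


def test_end_to_end_recovery_on_seeded_pangenomes():
    """Screen + label filter return exactly the planted family."""
    from oyescan.experiments import screen_recovery

    result = screen_recovery(n_seeds=10, seed=42)
    assert result["recovered"] == result["n"]
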