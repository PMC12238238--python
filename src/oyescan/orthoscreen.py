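"""Reciprocal-best-hit orthogroup clustering and the phenotype-concordance screen.

Orthogroups are connected components of the reciprocal-best-hit (RBH) graph
over all genome pairs, built from global affine-gap protein alignment scores
(BLOSUM62). The screen keeps exactly the orthogroups present in every
phenotype-positive genome and absent from every negative one; a label filter
then restricts candidates to a functional family of interest (e.g. genes
annotated as Old Yellow Enzymes).

The original analysis expressed its orthology cutoff as an E-value; here the
threshold is a bit-score floor (default 50 bits), since presence/absence —
not the precise cutoff — drives the screen.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqs import check_protein

# Gapped BLOSUM62(11,1) Karlin–Altschul constants used for the bit-score scale.
_LAMBDA = 0.267
_LN_K = math.log(0.041)

GAP_OPEN = 11
GAP_EXTEND = 1
DEFAULT_MIN_BITS = 50.0


def _make_aligner(gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62")
    arr = np.array(matrix)
    letters = matrix.alphabet
    # X participates but is scored 0 against everything.
    xi = letters.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    mat = substitution_matrices.Array(alphabet=letters, dims=2, data=arr)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    # Biopython charges open_gap_score for the first gapped position, so a
    # length-1 gap costs open+extend, matching the usual BLAST convention.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_ALIGNER_CACHE: dict[tuple[int, int], Align.PairwiseAligner] = {}


def align_score(
    a: str, b: str, gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND
) -> tuple[float, float]:
    """Global affine-gap alignment score of two proteins.

    Returns ``(bits, raw)``. Raw is the optimal BLOSUM62 score; bits apply
    the gapped Karlin–Altschul scale ``(λS − ln K)/ln 2``. Symmetric in its
    arguments. 'X' is accepted and scored 0 against every residue; an empty
    sequence aligns as one all-gap run.
    """
    check_protein(a)
    check_protein(b)
    if not a or not b:
        # one all-gap run spanning the non-empty sequence
        n = len(a) + len(b)
        raw = 0.0 if n == 0 else -(gap_open + gap_extend * n)
        return (_LAMBDA * raw - _LN_K) / math.log(2), raw
    key = (gap_open, gap_extend)
    if key not in _ALIGNER_CACHE:
        _ALIGNER_CACHE[key] = _make_aligner(gap_open, gap_extend)
    raw = _ALIGNER_CACHE[key].score(a.upper(), b.upper())
    bits = (_LAMBDA * raw - _LN_K) / math.log(2)
    return bits, raw


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclasses.dataclass
class OrthoMatrix:
    """Orthogroup membership with aligned presence and phenotype vectors."""

    genomes: list[str]
    groups: dict[str, list[tuple[str, str]]]  # og_id -> [(genome, gene_id)]
    presence: np.ndarray  # (n_orthogroups, n_genomes) of 0/1
    phenotype: list[bool]  # positive indicator, same genome order

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.groups)

    def members(self, og_id: str) -> list[tuple[str, str]]:
        return self.groups[og_id]


class _UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def rbh_orthogroups(
    proteomes: dict[str, dict[str, str]],
    min_bits: float = DEFAULT_MIN_BITS,
    phenotype: dict[str, str] | None = None,
    prefilter_kmer_frac: float | None = 0.05,
) -> OrthoMatrix:
    """Cluster proteomes into orthogroups by reciprocal best hits.

    ``proteomes`` maps genome → {gene_id: protein}. For every ordered genome
    pair, each gene's best hit is the highest-bit-score partner (ties broken
    by higher raw score, then lexicographic gene id); mutual best hits with
    score ≥ ``min_bits`` become edges, and orthogroups are the connected
    components. Genes with no edge stay singletons.

    ``prefilter_kmer_frac`` skips alignment of pairs sharing fewer than that
    fraction of 4-mers (a DIAMOND-style seed filter); pass ``None`` to align
    every cross-genome pair.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two genomes")
    for gid, prots in proteomes.items():
        if not prots:
            raise ValueError(f"empty proteome for genome {gid}")

    genome_ids = sorted(proteomes)
    all_genes = [(g, p) for g in genome_ids for p in sorted(proteomes[g])]
    uf = _UnionFind(all_genes)

    kmers = {
        (g, p): _kmer_set(proteomes[g][p]) for g, p in all_genes
    } if prefilter_kmer_frac is not None else {}

    for i, ga in enumerate(genome_ids):
        for gb in genome_ids[i + 1 :]:
            scores: dict[tuple[str, str], tuple[float, float]] = {}
            for pa in sorted(proteomes[ga]):
                for pb in sorted(proteomes[gb]):
                    if prefilter_kmer_frac is not None:
                        ka, kb = kmers[(ga, pa)], kmers[(gb, pb)]
                        denom = min(len(ka), len(kb)) or 1
                        if len(ka & kb) / denom < prefilter_kmer_frac:
                            continue
                    scores[(pa, pb)] = align_score(proteomes[ga][pa], proteomes[gb][pb])

            def best_hits(axis: int) -> dict[str, str]:
                best: dict[str, tuple[float, float, str]] = {}
                for (pa, pb), (bits, raw) in scores.items():
                    src, dst = (pa, pb) if axis == 0 else (pb, pa)
                    cand = (bits, raw, dst)
                    cur = best.get(src)
                    if cur is None or (cand[0], cand[1], _neg(cand[2])) > (
                        cur[0], cur[1], _neg(cur[2])
                    ):
                        best[src] = cand
                return {s: v[2] for s, v in best.items() if v[0] >= min_bits}

            fwd, rev = best_hits(0), best_hits(1)
            for pa, pb in fwd.items():
                if rev.get(pb) == pa:
                    uf.union((ga, pa), (gb, pb))

    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for gene in all_genes:
        components.setdefault(uf.find(gene), []).append(gene)

    ordered = sorted(components.values(), key=lambda ms: min(ms))
    groups = {f"OG{i:05d}": sorted(ms) for i, ms in enumerate(ordered)}
    presence = np.zeros((len(groups), len(genome_ids)), dtype=int)
    gindex = {g: j for j, g in enumerate(genome_ids)}
    for row, ms in enumerate(groups.values()):
        for g, _ in ms:
            presence[row, gindex[g]] = 1

    pheno = [bool(phenotype and phenotype.get(g) == "positive") for g in genome_ids]
    return OrthoMatrix(genome_ids, groups, presence, pheno)


class _neg(str):
    """Wrapper giving reversed lexicographic order, so a single tuple-max
    prefers the lexicographically *smallest* gene id on score ties."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def phenotype_screen(matrix: OrthoMatrix) -> list[str]:
    """Orthogroups whose presence vector equals the phenotype indicator.

    Present in every positive genome, absent from every negative one;
    returned in deterministic (orthogroup-id) order.
    """
    pheno = np.array(matrix.phenotype, dtype=bool)
    if not pheno.any() or pheno.all():
        raise ValueError("phenotype must contain both positive and negative genomes")
    hits = np.all(matrix.presence.astype(bool) == pheno[None, :], axis=1)
    return [og for og, h in zip(matrix.groups, hits) if h]


def label_filter(
    candidates: list[str],
    matrix: OrthoMatrix,
    labels: dict[str, str],
    target_label: str,
) -> list[str]:
    """Keep candidate orthogroups with ≥1 member carrying ``target_label``.

    ``labels`` maps gene_id → family label; genes missing from the table are
    treated as unlabeled.
    """
    kept = []
    for og in candidates:
        if any(labels.get(gene) == target_label for _, gene in matrix.groups[og]):
            kept.append(og)
    return kept
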