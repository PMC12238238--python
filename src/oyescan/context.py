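"""Genomic colocalization of target genes with marker genes.

Mirrors the presence rings of comparative-genomics figures: for each target
gene a genome is classified as *proximal* (a marker gene lies within a
configurable neighborhood on the same contig), *same_genome* (markers exist
but only elsewhere), or *absent* (no marker at all). "Close proximity"
defaults to within 8 intervening genes or 10 kb, whichever is satisfied;
strand is ignored.
"""

from __future__ import annotations

import dataclasses

from .io import AnnotatedGenome

PROXIMAL = "proximal"
SAME_GENOME = "same_genome"
ABSENT = "absent"

DEFAULT_WINDOW_GENES = 8
DEFAULT_WINDOW_BP = 10_000


@dataclasses.dataclass(frozen=True)
class ColocalizationCall:
    genome_id: str
    target_gene: str
    klass: str
    marker_gene: str | None
    bp_distance: int | None  # nearest feature edges; None off-contig/absent
    gene_rank_distance: int | None  # 1 = directly adjacent

    def __post_init__(self):
        if self.klass not in (PROXIMAL, SAME_GENOME, ABSENT):
            raise ValueError(f"unknown class {self.klass}")
        if self.klass == ABSENT and self.marker_gene is not None:
            raise ValueError("absent calls cannot carry a marker")


def _edge_distance(a, b) -> int:
    """bp between nearest feature edges; 0 when features touch or overlap."""
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0


def classify_colocalization(
    genome: AnnotatedGenome,
    targets: set[str],
    markers: set[str],
    window_genes: int = DEFAULT_WINDOW_GENES,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[ColocalizationCall]:
    """Classify each target gene's proximity to the nearest marker gene.

    Proximal means some marker on the same contig has at most
    ``window_genes`` intervening genes (rank distance ≤ window_genes + 1)
    OR an edge-to-edge distance ≤ ``window_bp``; either criterion suffices.
    """
    by_id = {g.gene_id: g for g in genome.genes}
    for t in targets:
        if t not in by_id:
            raise ValueError(f"target gene {t} not in genome {genome.genome_id}")
    marker_recs = [by_id[m] for m in sorted(markers) if m in by_id]

    rank: dict[str, int] = {}
    for contig in genome.contigs:
        for i, g in enumerate(genome.genes_on(contig)):
            rank[g.gene_id] = i

    calls = []
    for t in sorted(targets):
        trec = by_id[t]
        if not marker_recs:
            calls.append(ColocalizationCall(genome.genome_id, t, ABSENT, None, None, None))
            continue
        best = None  # (bp, rank, marker_id)
        for m in marker_recs:
            if m.contig != trec.contig:
                continue
            bp = _edge_distance(trec, m)
            rd = abs(rank[t] - rank[m.gene_id])
            if best is None or (bp, rd, m.gene_id) < best:
                best = (bp, rd, m.gene_id)
        if best is None:
            calls.append(
                ColocalizationCall(genome.genome_id, t, SAME_GENOME,
                                   marker_recs[0].gene_id, None, None)
            )
            continue
        bp, rd, mid = best
        proximal = (rd - 1) <= window_genes or bp <= window_bp
        calls.append(
            ColocalizationCall(
                genome.genome_id, t, PROXIMAL if proximal else SAME_GENOME,
                mid, bp, rd,
            )
        )
    return calls


def copresence_summary(calls: list[ColocalizationCall]) -> dict[str, int]:
    """Counts over a genome collection: total targets, co-present (marker
    anywhere in the genome), and proximal."""
    n_targets = len(calls)
    n_copresent = sum(c.klass in (PROXIMAL, SAME_GENOME) for c in calls)
    n_proximal = sum(c.klass == PROXIMAL for c in calls)
    assert n_proximal <= n_copresent <= n_targets
    return {"n_targets": n_targets, "n_copresent": n_copresent,
            "n_proximal": n_proximal}
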