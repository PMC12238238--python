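"""Genomic-context classification of target genes against marker genes.

Reproduces the filled/unfilled-circle logic of comparative-genomics
figures: proximal (marker within 8 intervening genes or 10 kb on the same
contig), same_genome, or absent.
"""

from oyescan import context as ctx
from oyescan import synthgen as sg

design = sg.PangenomeDesign(
    phenotype={"p1": "positive", "p2": "positive", "p3": "positive",
               "n1": "negative"},
    fusion_carriers=frozenset(),
    marker_proximal=frozenset({"p1"}),   # marker right next to the target
    marker_distal=frozenset({"p2"}),     # marker on another contig
    protein_len=120,
)
genomes, truth = sg.build_pangenome(design, seed=3)

calls = []
for genome in genomes:
    targets = {gene for g, gene in truth.members[design.planted_family_id]
               if g == genome.genome_id}
    markers = set(truth.markers.get(genome.genome_id, []))
    if targets:
        calls.extend(ctx.classify_colocalization(genome, targets, markers))

for c in calls:
    print(f"{c.genome_id}: target {c.target_gene} -> {c.klass}"
          + (f" (marker {c.marker_gene}, {c.bp_distance} bp, "
             f"rank {c.gene_rank_distance})" if c.bp_distance is not None else ""))
print("summary:", ctx.copresence_summary(calls))
# p1 is proximal (planted next door), p2 only co-present (other contig),
# p3 absent — so n_proximal < n_copresent < n_targets here.
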