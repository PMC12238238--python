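"""Generate a truth-tagged synthetic pangenome.

Six genomes (three progesterone-reducer analogs, three non-reducers) get
one planted gene family whose presence matches the phenotype, plus decoy
families that violate it, a fused two-domain variant, and marker genes
placed next to the target.
"""

from pathlib import Path

from oyescan import synthgen as sg

design = sg.PangenomeDesign(
    phenotype={"reducer1": "positive", "reducer2": "positive",
               "reducer3": "positive", "non1": "negative",
               "non2": "negative", "non3": "negative"},
    decoy_family_ids=("decoy_a", "decoy_b", "decoy_c"),
    fusion_carriers=frozenset({"reducer2"}),
    marker_proximal=frozenset({"reducer1"}),
    protein_len=150,
)
outdir = Path("scratch/example_pangenome")
truth = sg.gen_pangenome(design, seed=7, outdir=outdir)

print(f"wrote FASTA/GFF3/protein files for {len(design.genome_ids)} genomes to {outdir}")
print("planted family presence:", truth.presence_vector(design.planted_family_id))
print("phenotype indicator:    ", truth.phenotype_vector())
print("fused gene (genome, id, junction):",
      [(g, *v) for g, v in truth.fused.items()])
# The two vectors match by construction: only the planted family is
# perfectly phenotype-concordant, which is what the screen must find.
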