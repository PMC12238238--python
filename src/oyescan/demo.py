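"""Bundled demo: generate a small synthetic study and a matching RunConfig.

The demo plants one phenotype-concordant reductase family (with a fused
two-domain variant and marker-gene neighborhoods) in a six-genome
pangenome, simulates a small paired-group metagenome cohort from the
planted gene, and wires everything into a configuration the full pipeline
can run in seconds.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import synthgen as sg
from .config import RunConfig


def write_demo_inputs(workdir: str | Path, seed: int = 0) -> RunConfig:
    """Create demo inputs under ``workdir`` and return a ready RunConfig."""
    workdir = Path(workdir)
    gdir = workdir / "genomes"
    rdir = workdir / "reads"

    design = sg.PangenomeDesign(
        phenotype={
            "gpos1": sg.POSITIVE, "gpos2": sg.POSITIVE, "gpos3": sg.POSITIVE,
            "gneg1": sg.NEGATIVE, "gneg2": sg.NEGATIVE, "gneg3": sg.NEGATIVE,
        },
        decoy_family_ids=("decoy_00", "decoy_01", "decoy_02"),
        fusion_carriers=frozenset({"gpos2"}),
        marker_proximal=frozenset({"gpos1", "gpos3"}),
        marker_distal=frozenset({"gpos2"}),
        protein_len=120,
        partner_len=100,
        marker_len=100,
        divergence=0.10,
    )
    truth = sg.gen_pangenome(design, seed, gdir)

    label_rows = []
    for _, gene in truth.members[design.planted_family_id]:
        label_rows.append({"gene_id": gene, "label": "OYE"})
    for genome, genes in truth.markers.items():
        for gene in genes:
            label_rows.append({"gene_id": gene, "label": "marker"})
    for genome, gene in truth.partners.items():
        label_rows.append({"gene_id": gene, "label": "partner"})
    for fam in design.decoy_family_ids:
        for _, gene in truth.members[fam]:
            label_rows.append({"gene_id": gene, "label": "other"})
    labels_tsv = workdir / "labels.tsv"
    pd.DataFrame(label_rows).to_csv(labels_tsv, sep="\t", index=False)

    # metagenome reads drawn from the planted gene's CDS in the first genome
    genomes, _ = sg.build_pangenome(design, seed)
    by_id = {g.genome_id: g for g in genomes}
    genome, gene_id = truth.members[design.planted_family_id][0]
    gene = next(g for g in by_id[genome].genes if g.gene_id == gene_id)
    cds = by_id[genome].contigs[gene.contig][gene.start - 1 : gene.end]
    mdesign = sg.MetagenomeDesign(
        groups={"female": 5, "male": 5},
        carriage={"female": {"target": 1.0}, "male": {"target": 0.4}},
        depth=3000,
        read_length=100,
        error_prob=0.002,
    )
    backgrounds = sg.random_background(seed + 1, 3, 8000)
    sg.gen_metagenome(mdesign, {"target": cds}, backgrounds, seed + 2, rdir)

    # tree-stage anchors: one planted gene (steroid side) vs one marker gene
    anchor_steroid = truth.members[design.planted_family_id][0][1]
    anchor_marker = truth.markers["gpos1"][0]
    outgroup_gene = truth.members["decoy_00"][0][1]

    config = RunConfig(
        genomes_dir=str(gdir),
        phenotype_tsv=str(gdir / "phenotype.tsv"),
        labels_tsv=str(labels_tsv),
        reads_dir=str(rdir),
        metadata_tsv=str(rdir / "metadata.tsv"),
        outdir=str(workdir / "results"),
        seed=seed,
        null_n=200,
        qc_min_reads=1000,
        anchor_map={"steroid": [anchor_steroid], "bai": [anchor_marker]},
        outgroup_genes=[outgroup_gene],
        positions=[5, 10, 20],
    )
    config.to_yaml(workdir / "config.yaml")
    return config
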