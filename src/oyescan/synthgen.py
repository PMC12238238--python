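"""Truth-tagged synthetic data generators.

Three generators mirror the statistical structure the downstream analysis
assumes:

* a **pangenome** with exactly one gene family whose presence/absence
  matches a binary phenotype (plus decoy families that violate it), optional
  fused two-domain variants of the planted gene, and marker genes placed
  next to — or away from — the target gene;
* **homolog families** evolved down a small labelled clade tree with
  clade-diagnostic residues that are never mutated;
* paired-group **metagenomes** where each sample's source community carries
  each panel gene with a group-specific probability, and reads are drawn
  uniformly (per base) from the realized community.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical design + seed gives byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .seqs import (
    DNA,
    encode_dna,
    mutate_protein,
    random_dna,
    random_protein,
    reverse_translate,
    revcomp,
)

POSITIVE = "positive"
NEGATIVE = "negative"


# ---------------------------------------------------------------------------
# Pangenome


@dataclasses.dataclass
class PangenomeDesign:
    """Design of a planted-truth pangenome.

    ``phenotype`` maps genome id → "positive"/"negative". The planted family
    is present in exactly the positive genomes; each decoy family gets a
    presence vector that differs from the phenotype vector in at least one
    genome. ``fusion_carriers`` (⊆ positives) carry the planted gene fused
    at its C-terminus to a partner domain. ``marker_proximal`` genomes get a
    marker gene directly next to the planted gene; ``marker_distal`` genomes
    get the marker on a second contig.
    """

    phenotype: dict[str, str]
    planted_family_id: str = "fam_target"
    decoy_family_ids: tuple[str, ...] = ()
    fusion_carriers: frozenset = frozenset()
    marker_proximal: frozenset = frozenset()
    marker_distal: frozenset = frozenset()
    protein_len: int = 200
    partner_len: int = 150
    marker_len: int = 150
    divergence: float = 0.15
    spacer_bp: int = 200
    randomize_strand: bool = False
    # genome-private genes with no homologs elsewhere; they keep every
    # proteome non-empty and exercise singleton handling downstream
    singletons_per_genome: int = 2

    def __post_init__(self):
        classes = set(self.phenotype.values())
        if not classes <= {POSITIVE, NEGATIVE}:
            raise ValueError(f"phenotype labels must be '{POSITIVE}'/'{NEGATIVE}'")
        if POSITIVE not in classes or NEGATIVE not in classes:
            raise ValueError(
                "need at least one positive and one negative genome; got "
                f"{sorted(classes) or 'none'}"
            )
        positives = {g for g, p in self.phenotype.items() if p == POSITIVE}
        if not set(self.fusion_carriers) <= positives:
            raise ValueError("fusion_carriers must carry the planted family "
                             "(subset of positive genomes)")
        for field in ("marker_proximal", "marker_distal"):
            extra = set(getattr(self, field)) - set(self.phenotype)
            if extra:
                raise ValueError(f"{field} names unknown genomes: {sorted(extra)}")
        if set(self.marker_proximal) & set(self.marker_distal):
            raise ValueError("a genome cannot be both marker_proximal and marker_distal")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.phenotype)

    @property
    def positives(self) -> list[str]:
        return [g for g in self.genome_ids if self.phenotype[g] == POSITIVE]


@dataclasses.dataclass
class PangenomeTruth:
    """Ground truth emitted alongside a synthetic pangenome."""

    design: PangenomeDesign
    presence: dict[str, dict[str, bool]]  # family -> genome -> present
    members: dict[str, list[tuple[str, str]]]  # family -> [(genome, gene_id)]
    fused: dict[str, tuple[str, int]]  # genome -> (gene_id, junction aa index)
    markers: dict[str, list[str]]  # genome -> marker gene ids
    partners: dict[str, str] = dataclasses.field(default_factory=dict)
    # genome -> stand-alone partner-domain gene (positives without a fusion)

    def presence_vector(self, family_id: str) -> list[bool]:
        return [self.presence[family_id][g] for g in self.design.genome_ids]

    def phenotype_vector(self) -> list[bool]:
        return [self.design.phenotype[g] == POSITIVE for g in self.design.genome_ids]


def _decoy_presence(rng, n_genomes: int, pheno: np.ndarray) -> np.ndarray:
    """Random presence vector that is non-empty and violates the phenotype."""
    for _ in range(200):
        v = rng.integers(0, 2, size=n_genomes).astype(bool)
        if v.any() and (v != pheno).any():
            return v
    raise RuntimeError("could not sample a decoy presence vector")  # pragma: no cover


def build_pangenome(
    design: PangenomeDesign, seed: int
) -> tuple[list[oio.AnnotatedGenome], PangenomeTruth]:
    """Construct the pangenome in memory; see :func:`gen_pangenome` for files."""
    rng = np.random.default_rng(seed)
    genomes = design.genome_ids
    pheno = np.array([design.phenotype[g] == POSITIVE for g in genomes])

    ancestors = {design.planted_family_id: random_protein(rng, design.protein_len)}
    presence = {design.planted_family_id: dict(zip(genomes, pheno.tolist()))}
    for fam in design.decoy_family_ids:
        ancestors[fam] = random_protein(rng, design.protein_len)
        presence[fam] = dict(zip(genomes, _decoy_presence(rng, len(genomes), pheno).tolist()))
    partner_ancestor = random_protein(rng, design.partner_len)
    marker_ancestor = random_protein(rng, design.marker_len)

    members: dict[str, list[tuple[str, str]]] = {f: [] for f in ancestors}
    fused: dict[str, tuple[str, int]] = {}
    markers: dict[str, list[str]] = {}
    partners: dict[str, str] = {}
    annotated: list[oio.AnnotatedGenome] = []

    for gid in genomes:
        # (family_or_tag, protein) in layout order
        layout: list[tuple[str, str]] = []
        for fam in design.decoy_family_ids:
            if presence[fam][gid]:
                layout.append((fam, mutate_protein(rng, ancestors[fam], design.divergence)))
        if presence[design.planted_family_id][gid]:
            target = mutate_protein(
                rng, ancestors[design.planted_family_id], design.divergence
            )
            if gid in design.fusion_carriers:
                partner = mutate_protein(rng, partner_ancestor, design.divergence)
                layout.append(("__fused__", target + partner))
            else:
                layout.append((design.planted_family_id, target))
                if design.fusion_carriers:
                    # the partner domain also occurs as a stand-alone gene in
                    # carriers of the separate two-enzyme pathway
                    layout.append(
                        ("__partner__",
                         mutate_protein(rng, partner_ancestor, design.divergence))
                    )
        if gid in design.marker_proximal:
            layout.append(("__marker__", mutate_protein(rng, marker_ancestor,
                                                        design.divergence)))
        for _ in range(design.singletons_per_genome):
            layout.append(("__singleton__", random_protein(rng, design.protein_len)))

        contig_genes: dict[str, list[tuple[str, str]]] = {"ctg1": layout}
        if gid in design.marker_distal:
            contig_genes["ctg2"] = [
                ("__marker__", mutate_protein(rng, marker_ancestor, design.divergence))
            ]

        contigs: dict[str, str] = {}
        genes: list[oio.GeneRecord] = []
        idx = 0
        for contig_id, entries in contig_genes.items():
            parts = [random_dna(rng, design.spacer_bp)]
            pos = design.spacer_bp
            for tag, protein in entries:
                idx += 1
                gene_id = f"{gid}_{idx:04d}"
                cds = reverse_translate(rng, protein)
                strand = "+"
                if design.randomize_strand and rng.random() < 0.5:
                    strand = "-"
                    parts.append(revcomp(cds))
                else:
                    parts.append(cds)
                genes.append(
                    oio.GeneRecord(gene_id, contig_id, pos + 1, pos + len(cds),
                                   strand, protein)
                )
                pos += len(cds)
                parts.append(random_dna(rng, design.spacer_bp))
                pos += design.spacer_bp
                if tag == "__fused__":
                    fused[gid] = (gene_id, design.protein_len)
                    members[design.planted_family_id].append((gid, gene_id))
                elif tag == "__marker__":
                    markers.setdefault(gid, []).append(gene_id)
                elif tag == "__partner__":
                    partners[gid] = gene_id
                elif tag != "__singleton__":
                    members[tag].append((gid, gene_id))
            contigs[contig_id] = "".join(parts)
        annotated.append(oio.AnnotatedGenome(gid, contigs, genes))

    return annotated, PangenomeTruth(design, presence, members, fused, markers,
                                     partners)


def gen_pangenome(design: PangenomeDesign, seed: int, outdir: str | Path) -> PangenomeTruth:
    """Write genomes (FASTA+GFF3), protein FASTA and truth tables to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, truth = build_pangenome(design, seed)
    for genome in genomes:
        oio.write_fasta(outdir / f"{genome.genome_id}.fna", genome.contigs)
        oio.write_gff3(outdir / f"{genome.genome_id}.gff", genome)
        oio.write_fasta(outdir / f"{genome.genome_id}.faa", genome.proteins())

    rows = [
        {"family_id": fam, **{g: int(p) for g, p in pres.items()}}
        for fam, pres in truth.presence.items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth_presence.tsv", sep="\t", index=False)

    gene_rows = []
    for fam, pairs in truth.members.items():
        for gid, gene in pairs:
            junction = truth.fused.get(gid, ("", -1))
            is_fused = junction[0] == gene
            gene_rows.append(
                {"genome": gid, "gene_id": gene, "family_id": fam,
                 "fused": int(is_fused),
                 "junction_aa": junction[1] if is_fused else ""}
            )
    for gid, gene_ids in truth.markers.items():
        for gene in gene_ids:
            gene_rows.append({"genome": gid, "gene_id": gene, "family_id": "marker",
                              "fused": 0, "junction_aa": ""})
    for gid, gene in truth.partners.items():
        gene_rows.append({"genome": gid, "gene_id": gene, "family_id": "partner",
                          "fused": 0, "junction_aa": ""})
    pd.DataFrame(gene_rows).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)

    pd.DataFrame(
        {"genome": design.genome_ids,
         "phenotype": [design.phenotype[g] for g in design.genome_ids]}
    ).to_csv(outdir / "phenotype.tsv", sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# Homolog families


@dataclasses.dataclass
class FamilyModel:
    """Two-level clade model: ancestor → clade ancestors → leaves.

    Substitutions are independent per site with probability
    ``per_branch_sub_prob`` on each branch, uniform over the 19 alternative
    residues; ``diagnostic_columns`` (1-based ancestor positions → clade →
    residue) are set on the clade ancestor and never mutated afterwards.
    """

    ancestor: str
    clades: dict[str, int]  # label -> number of leaves
    per_branch_sub_prob: float = 0.05
    diagnostic_columns: dict[int, dict[str, str]] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.per_branch_sub_prob < 1:
            raise ValueError("per_branch_sub_prob must be in [0, 1)")
        for col in self.diagnostic_columns:
            if not 1 <= col <= len(self.ancestor):
                raise ValueError(
                    f"diagnostic column {col} outside ancestor length {len(self.ancestor)}"
                )


def build_family_set(model: FamilyModel, seed: int) -> list[tuple[str, str, str]]:
    """Return [(sequence_id, clade_label, sequence)], one per leaf."""
    rng = np.random.default_rng(seed)
    frozen = {c - 1 for c in model.diagnostic_columns}
    out = []
    for label, n_leaves in model.clades.items():
        clade_anc = list(
            mutate_protein(rng, model.ancestor, model.per_branch_sub_prob, frozen)
        )
        for col, per_clade in model.diagnostic_columns.items():
            if label in per_clade:
                clade_anc[col - 1] = per_clade[label]
        clade_anc = "".join(clade_anc)
        for i in range(n_leaves):
            leaf = mutate_protein(rng, clade_anc, model.per_branch_sub_prob, frozen)
            out.append((f"{label}_{i:03d}", label, leaf))
    return out


def gen_family_set(model: FamilyModel, seed: int, path: str | Path) -> list[tuple[str, str, str]]:
    """Write the homolog set as FASTA with ``clade=`` tags in the description."""
    leaves = build_family_set(model, seed)
    with open(path, "w") as fh:
        for seq_id, label, seq in leaves:
            fh.write(f">{seq_id} clade={label}\n{seq}\n")
    return leaves


def expected_within_clade_identity(p: float, n_diagnostic: int, length: int) -> float:
    """Closed-form mean pairwise identity between two leaves of one clade.

    Each non-diagnostic site mutates independently on each leaf branch with
    probability ``p``, always to a different residue (uniform over 19), so
    two leaves agree at a site with probability (1-p)^2 + p^2/19.
    Diagnostic sites always agree within a clade.
    """
    site = (1 - p) ** 2 + p**2 / 19
    return (n_diagnostic + (length - n_diagnostic) * site) / length


# ---------------------------------------------------------------------------
# Metagenomes


@dataclasses.dataclass
class MetagenomeDesign:
    """Paired-group metagenome design with per-group gene carriage."""

    groups: dict[str, int]  # label -> sample count
    carriage: dict[str, dict[str, float]]  # label -> gene -> probability
    depth: int = 100_000
    read_length: int = 150
    error_prob: float = 0.0
    runs_per_sample: int = 1
    panel_abundance: float = 0.01
    both_strands: bool = True

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for label, per_gene in self.carriage.items():
            if label not in self.groups:
                raise ValueError(f"carriage given for unknown group {label}")
            for gene, prob in per_gene.items():
                if not 0 <= prob <= 1:
                    raise ValueError(f"carriage[{label}][{gene}] outside [0, 1]")


@dataclasses.dataclass
class SampleTruth:
    biosample: str
    group: str
    carried: dict[str, bool]


def random_background(rng_or_seed, n: int = 5, length: int = 20_000) -> dict[str, str]:
    """Equal-abundance random background genomes (community filler)."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    return {f"bg_{i:02d}": random_dna(rng, length) for i in range(n)}


def _draw_reads_encoded(
    rng: np.random.Generator,
    big: np.ndarray,
    offsets: np.ndarray,
    lengths: np.ndarray,
    weights: np.ndarray,
    n_reads: int,
    read_len: int,
    error_prob: float,
    both_strands: bool,
) -> np.ndarray:
    """Draw reads uniformly per base from weighted sources → (n, L) uint8."""
    src = rng.choice(len(lengths), size=n_reads, p=weights)
    span = lengths[src] - read_len + 1
    starts = rng.integers(0, span)
    idx = (offsets[src] + starts)[:, None] + np.arange(read_len)[None, :]
    reads = big[idx]
    if both_strands:
        flip = rng.random(n_reads) < 0.5
        reads[flip] = (3 - reads[flip])[:, ::-1]
    if error_prob > 0:
        mask = rng.random(reads.shape) < error_prob
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        reads[mask] = (reads[mask] + shift) % 4
    return reads


def decode_reads(reads: np.ndarray) -> list[str]:
    lut = np.frombuffer(DNA.encode(), dtype=np.uint8)
    return [bytes(lut[row]).decode() for row in reads]


class MetagenomeSimulator:
    """Stream per-run read batches for a metagenome design.

    Holding every read of every sample in memory is infeasible at realistic
    depths, so iteration yields one run at a time as an encoded uint8 array.
    """

    def __init__(
        self,
        design: MetagenomeDesign,
        gene_panel: dict[str, str],
        background_genomes: dict[str, str],
        seed: int,
    ):
        if not gene_panel:
            raise ValueError("gene panel is empty")
        if not background_genomes:
            raise ValueError("no background genomes supplied")
        shortest = min(len(s) for s in list(gene_panel.values())
                       + list(background_genomes.values()))
        if design.read_length > shortest:
            raise ValueError(
                f"read_length {design.read_length} exceeds shortest source ({shortest} bp)"
            )
        self.design = design
        self.panel_ids = list(gene_panel)
        self.bg_ids = list(background_genomes)
        sources = list(background_genomes.values()) + list(gene_panel.values())
        self.lengths = np.array([len(s) for s in sources])
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)[:-1]])
        self.big = np.concatenate(
            [encode_dna([s], len(s))[0] for s in sources]
        )
        self.rng = np.random.default_rng(seed)

    def _weights(self, carried: dict[str, bool]) -> np.ndarray:
        a = self.design.panel_abundance
        n_bg = len(self.bg_ids)
        carried_flags = np.array([carried[g] for g in self.panel_ids], dtype=float)
        gene_w = a * carried_flags
        bg_total = max(1.0 - gene_w.sum(), 0.0)
        w = np.concatenate([np.full(n_bg, bg_total / n_bg), gene_w])
        return w / w.sum()

    def samples(self):
        """Yield (SampleTruth, run iterator); runs yield (run_id, reads array)."""
        d = self.design
        counter = 0
        for group, n_samples in d.groups.items():
            per_gene = d.carriage.get(group, {})
            for _ in range(n_samples):
                counter += 1
                biosample = f"S{counter:04d}"
                carried = {
                    g: bool(self.rng.random() < per_gene.get(g, 0.0))
                    for g in self.panel_ids
                }
                truth = SampleTruth(biosample, group, carried)
                weights = self._weights(carried)

                def runs(truth=truth, weights=weights):
                    for r in range(d.runs_per_sample):
                        run_id = f"{truth.biosample}_run{r + 1}"
                        reads = _draw_reads_encoded(
                            self.rng, self.big, self.offsets, self.lengths,
                            weights, d.depth, d.read_length, d.error_prob,
                            d.both_strands,
                        )
                        yield run_id, reads

                yield truth, runs()


def gen_metagenome(
    design: MetagenomeDesign,
    gene_panel: dict[str, str],
    background_genomes: dict[str, str],
    seed: int,
    outdir: str | Path,
) -> list[SampleTruth]:
    """Write per-run FASTQ files plus metadata and carriage-truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = MetagenomeSimulator(design, gene_panel, background_genomes, seed)
    meta_rows, truth_rows, truths = [], [], []
    for truth, runs in sim.samples():
        truths.append(truth)
        for run_id, reads in runs:
            names = (f"{run_id}.{i}" for i in range(len(reads)))
            oio.write_fastq(outdir / f"{run_id}.fastq",
                            zip(names, decode_reads(reads)))
            meta_rows.append({"run": run_id, "biosample": truth.biosample,
                              "group": truth.group})
        for gene, carried in truth.carried.items():
            truth_rows.append({"biosample": truth.biosample, "gene": gene,
                               "carried": int(carried)})
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "carriage_truth.tsv", sep="\t", index=False)
    return truths
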