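"""End-to-end orchestrator: screen → profile → context → tree → metaprofile.

Each stage writes one TSV (or Newick) result carrying a provenance header
with the config hash and seed; any stage failure aborts the run with the
stage name and the underlying cause.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import context as ctx
from . import hmm as hm
from . import io as oio
from . import metaprof as mp
from . import msa as ms
from . import orthoscreen as ortho
from . import phylo as ph
from .config import RunConfig


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _header(config: RunConfig) -> str:
    return f"oyescan config={config.digest()} seed={config.seed}"


def _load_genomes(config: RunConfig) -> dict[str, oio.AnnotatedGenome]:
    gdir = Path(config.genomes_dir)
    prefixes = sorted(p.stem for p in gdir.glob("*.faa"))
    if not prefixes:
        raise FileNotFoundError(f"no .faa proteomes under {gdir}")
    return {gid: oio.load_genome(gdir / gid) for gid in prefixes}


def _load_labels(config: RunConfig) -> dict[str, str]:
    if config.labels_tsv is None:
        return {}
    df = oio.read_table(config.labels_tsv)
    return dict(zip(df["gene_id"], df["label"]))


def stage_screen(config: RunConfig, outdir: Path):
    genomes = _load_genomes(config)
    pheno_df = oio.read_table(config.phenotype_tsv)
    phenotype = dict(zip(pheno_df["genome"], pheno_df["phenotype"]))
    proteomes = {gid: g.proteins() for gid, g in genomes.items()}
    matrix = ortho.rbh_orthogroups(proteomes, min_bits=config.min_bits,
                                   phenotype=phenotype)
    candidates = ortho.phenotype_screen(matrix)
    labels = _load_labels(config)
    if labels:
        candidates = ortho.label_filter(candidates, matrix, labels,
                                        config.target_label)
    rows = [
        {
            "orthogroup": og,
            "members": ";".join(f"{g}:{p}" for g, p in matrix.groups[og]),
            "presence": "".join(map(str, matrix.presence[list(matrix.groups).index(og)])),
        }
        for og in candidates
    ]
    oio.write_table(outdir / "screen_candidates.tsv", pd.DataFrame(rows),
                    _header(config))
    return genomes, matrix, candidates, labels


def stage_profile(config: RunConfig, outdir: Path, genomes, matrix, candidates,
                  labels):
    if not candidates:
        raise ValueError("screen produced no candidate orthogroups")
    all_proteins = {
        f"{gid}:{pid}": seq
        for gid, g in genomes.items()
        for pid, seq in g.proteins().items()
    }

    def family_hmm(gene_ids: list[str], model_id: str) -> hm.ProfileHMM:
        seqs = [(g, all_proteins[g]) for g in gene_ids]
        aln = ms.progressive_msa(seqs)
        trimmed, _ = ms.trim_msa(aln, max_gap_frac=config.max_gap_frac,
                                 min_len=config.min_len)
        return hm.build_profile(trimmed, pseudocount=config.pseudocount,
                                match_occupancy=config.match_occupancy,
                                model_id=model_id)

    target_genes = [f"{g}:{p}" for g, p in matrix.groups[candidates[0]]]
    models = [family_hmm(target_genes, "target")]
    for label, model_id in ((config.marker_label, "marker"),
                            (config.partner_label, "partner")):
        genes = [
            f"{gid}:{pid}" for gid, g in genomes.items() for pid in g.proteins()
            if labels.get(pid) == label
        ]
        if len(genes) >= 2:
            models.append(family_hmm(genes, model_id))

    hits, fusions = hm.calibrate_and_search(
        models, all_proteins, evalue_ceiling=config.evalue_ceiling,
        null_n=config.null_n, seed=config.seed,
    )
    hits_df = pd.DataFrame(
        [
            {"protein": h.protein_id, "model": h.model_id,
             "env_start": h.env_start, "env_end": h.env_end,
             "bits": h.bits, "evalue": h.evalue}
            for h in hits
        ]
    )
    oio.write_table(outdir / "profile_hits.tsv", hits_df, _header(config))
    fusion_rows, domain_fastas = [], []
    for call in fusions:
        fusion_rows.append({
            "protein": call.protein_id,
            "models": ";".join(h.model_id for h in call.hits),
            "splits": ";".join(map(str, call.splits)),
        })
        domain_fastas.extend(hm.split_domains(call, all_proteins[call.protein_id]))
    oio.write_table(outdir / "profile_fusions.tsv", pd.DataFrame(fusion_rows),
                    _header(config))
    if domain_fastas:
        oio.write_fasta(outdir / "fusion_domains.faa", domain_fastas)
    for model in models:
        hm.write_profile(outdir / f"profile_{model.model_id}.hmm.tsv", model)
    return models, hits


def stage_context(config: RunConfig, outdir: Path, genomes, hits):
    target_by_genome: dict[str, set[str]] = {}
    marker_by_genome: dict[str, set[str]] = {}
    for h in hits:
        gid, pid = h.protein_id.split(":", 1)
        if h.model_id == "target":
            target_by_genome.setdefault(gid, set()).add(pid)
        elif h.model_id == "marker":
            marker_by_genome.setdefault(gid, set()).add(pid)
    calls = []
    for gid, targets in sorted(target_by_genome.items()):
        calls.extend(
            ctx.classify_colocalization(
                genomes[gid], targets, marker_by_genome.get(gid, set()),
                window_genes=config.window_genes, window_bp=config.window_bp,
            )
        )
    calls_df = pd.DataFrame(
        [
            {"genome": c.genome_id, "target": c.target_gene, "class": c.klass,
             "marker": c.marker_gene or "", "bp_distance": c.bp_distance,
             "gene_rank_distance": c.gene_rank_distance}
            for c in calls
        ]
    )
    oio.write_table(outdir / "context_calls.tsv", calls_df, _header(config))
    summary = ctx.copresence_summary(calls)
    oio.write_table(outdir / "context_summary.tsv", pd.DataFrame([summary]),
                    _header(config))
    return calls


def stage_tree(config: RunConfig, outdir: Path, genomes, matrix, candidates,
               labels, hits):
    all_proteins = {
        pid: seq for g in genomes.values() for pid, seq in g.proteins().items()
    }
    member_ids = [p for _, p in matrix.groups[candidates[0]]]
    marker_ids = [pid for pid in all_proteins if labels.get(pid) == config.marker_label]
    og_ids = config.outgroup_genes or []
    tree_genes = sorted(set(member_ids + marker_ids + og_ids))
    if len(tree_genes) < 3:
        raise ValueError("need at least three sequences for a tree")
    aln = ms.progressive_msa([(g, all_proteins[g]) for g in tree_genes])
    dist, ids = ph.msa_distances(aln)
    tree = ph.nj_tree(dist, ids)
    (outdir / "tree.nwk").write_text(f"# {_header(config)}\n{tree.newick()}\n")

    if not (config.anchor_map and og_ids):
        return tree
    anchors = {lab: set(v) for lab, v in config.anchor_map.items()}
    clade_tree = ph.assign_clades(tree, anchors, set(og_ids))
    oio.write_table(
        outdir / "tree_clades.tsv",
        pd.DataFrame(sorted(clade_tree.labels.items()), columns=["leaf", "clade"]),
        _header(config),
    )
    if config.positions:
        ref = member_ids[0]
        rmap = ph.ResidueMap.from_msa(aln, ref, list(config.positions))
        freqs = ph.column_frequencies(aln, rmap, clade_tree.labels)
        rows = []
        for clade, per_pos in freqs.items():
            for pos, vec in per_pos.items():
                rows.append({"clade": clade, "position": pos,
                             **{c: v for c, v in zip(ph.ALPHABET21, vec)}})
        oio.write_table(outdir / "tree_residue_freqs.tsv", pd.DataFrame(rows),
                        _header(config))
        chars = {
            sid: "".join(aln.row(sid)[c] for c in rmap.columns)
            for sid in aln.ids
        }
        fitch = ph.fitch_ancestral(clade_tree.tree, chars)
        rows = []
        for i, per_col in enumerate(fitch.node_sets):
            for pos, states in zip(rmap.positions, per_col):
                rows.append({"node_postorder": i, "position": pos,
                             "states": "".join(sorted(states))})
        oio.write_table(outdir / "tree_ancestral_states.tsv", pd.DataFrame(rows),
                        _header(config))
    return tree


def stage_metaprofile(config: RunConfig, outdir: Path, genomes, hits):
    if not (config.reads_dir and config.metadata_tsv):
        return None
    # panel: nucleotide CDS of every target-model hit
    panel: dict[str, str] = {}
    for h in hits:
        if h.model_id != "target":
            continue
        gid, pid = h.protein_id.split(":", 1)
        gene = next(g for g in genomes[gid].genes if g.gene_id == pid)
        panel[pid] = genomes[gid].contigs[gene.contig][gene.start - 1 : gene.end]
    if not panel:
        raise ValueError("no target hits available to build the read panel")
    gp = mp.GenePanel(panel, k=config.kmer_size)
    run_counts = {}
    for fq in sorted(Path(config.reads_dir).glob("*.fastq")):
        reads = [seq for _, seq in oio.read_fastq(fq)]
        run_counts[fq.stem] = mp.map_reads(reads, gp, theta=config.theta)
    meta = oio.read_table(config.metadata_tsv)
    profiles = mp.profile_samples(run_counts, meta,
                                  qc_min_reads=config.qc_min_reads,
                                  cpm_threshold=config.cpm_threshold)
    oio.write_table(outdir / "metaprofile_samples.tsv",
                    mp.profiles_to_frame(profiles), _header(config))
    tests = mp.group_tests(profiles, config.group_a, config.group_b,
                           continuity=config.continuity)
    oio.write_table(outdir / "metaprofile_tests.tsv", tests, _header(config))
    oio.write_table(outdir / "metaprofile_lncpm.tsv", mp.log_cpm_table(profiles),
                    _header(config))
    return tests


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def run(stage_name, fn, *args):
        try:
            return fn(config, outdir, *args)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(stage_name, exc) from exc

    genomes, matrix, candidates, labels = run("screen", stage_screen)
    models, hits = run("profile", stage_profile, genomes, matrix, candidates, labels)
    run("context", stage_context, genomes, hits)
    run("tree", stage_tree, genomes, matrix, candidates, labels, hits)
    run("metaprofile", stage_metaprofile, genomes, hits)
    return outdir
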