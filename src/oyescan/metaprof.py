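"""Metagenomic quantification of gene families and group comparisons.

Reads are assigned to panel genes by k-mer containment: a read belongs to
the gene sharing the largest fraction of its k-mers (both orientations, via
strand-union gene k-mer sets) provided that fraction reaches a threshold;
ties leave the read unassigned. Per-run counts are summed per biosample,
converted to counts per million (CPM = mapped/total × 10⁶), and a gene is
called present in a sample when its CPM is strictly greater than 1.
Samples below the read-count QC floor are excluded from the tests but still
reported.

Group comparisons use a one-sided pooled two-proportion z-test on presence
(prevalence) and a one-sided Wilcoxon rank-sum test on CPM values.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .seqs import encode_dna, kmer_codes, revcomp

DEFAULT_K = 21
DEFAULT_THETA = 0.3
CPM_PRESENCE = 1.0  # strictly greater than
QC_MIN_READS = 1_000_000


# ---------------------------------------------------------------------------
# Read mapping


class GenePanel:
    """Pre-indexed k-mer sets (forward ∪ reverse-complement) per panel gene."""

    def __init__(self, genes: dict[str, str], k: int = DEFAULT_K):
        if not genes:
            raise ValueError("gene panel is empty")
        self.k = k
        self.gene_ids = list(genes)
        self.kmer_sets: list[np.ndarray] = []
        for gid in self.gene_ids:
            seq = genes[gid]
            if len(seq) < k:
                raise ValueError(f"panel gene {gid} shorter than k={k}")
            enc = encode_dna([seq, revcomp(seq)], len(seq))
            codes = kmer_codes(enc, k).ravel()
            self.kmer_sets.append(np.unique(codes[codes >= 0]))


def assign_reads_encoded(panel: GenePanel, reads: np.ndarray,
                         theta: float = DEFAULT_THETA) -> np.ndarray:
    """Per-read gene assignment for encoded reads (n, L uint8).

    Returns an int array: the panel-gene index per read, or −1 for
    unassigned (fraction below theta, or a tie for the maximum).
    """
    total = reads.shape[0]
    if total == 0:
        return np.empty(0, dtype=int)
    codes = kmer_codes(reads, panel.k)
    valid = codes >= 0
    denom = np.maximum(valid.sum(axis=1), 1)
    fracs = np.empty((len(panel.gene_ids), total))
    for gi, kset in enumerate(panel.kmer_sets):
        pos = np.searchsorted(kset, codes)
        pos = np.clip(pos, 0, len(kset) - 1)
        hit = (kset[pos] == codes) & valid
        fracs[gi] = hit.sum(axis=1) / denom
    best = fracs.max(axis=0)
    is_tie = (fracs == best[None, :]).sum(axis=0) > 1
    assigned = fracs.argmax(axis=0)
    assigned[(best < theta) | is_tie] = -1
    return assigned


def map_reads_encoded(
    panel: GenePanel, reads: np.ndarray, theta: float = DEFAULT_THETA
) -> tuple[dict[str, int], int]:
    """Assign encoded reads (n, L uint8) to panel genes.

    Returns (per-gene counts, total reads). A read is assigned to the gene
    with the highest shared-k-mer fraction when that fraction ≥ theta and
    the maximum is unique; otherwise it stays unassigned.
    """
    total = reads.shape[0]
    if total == 0:
        return {g: 0 for g in panel.gene_ids}, 0
    assigned = assign_reads_encoded(panel, reads, theta)
    ok = assigned >= 0
    counts = {g: 0 for g in panel.gene_ids}
    if ok.any():
        binc = np.bincount(assigned[ok], minlength=len(panel.gene_ids))
        for gi, g in enumerate(panel.gene_ids):
            counts[g] = int(binc[gi])
    return counts, total


def map_reads(
    reads: list[str] | np.ndarray,
    panel_genes: dict[str, str] | GenePanel,
    k: int = DEFAULT_K,
    theta: float = DEFAULT_THETA,
) -> tuple[dict[str, int], int]:
    """String-level convenience wrapper around :func:`map_reads_encoded`."""
    panel = panel_genes if isinstance(panel_genes, GenePanel) else GenePanel(panel_genes, k)
    if isinstance(reads, np.ndarray):
        enc = reads
    else:
        reads = list(reads)
        if not reads:
            return {g: 0 for g in panel.gene_ids}, 0
        lengths = {len(r) for r in reads}
        if len(lengths) > 1:
            # process per length class; counts accumulate
            counts = {g: 0 for g in panel.gene_ids}
            total = 0
            for L in sorted(lengths):
                sub = [r for r in reads if len(r) == L]
                c, t = map_reads(sub, panel, k=panel.k, theta=theta)
                for g in counts:
                    counts[g] += c[g]
                total += t
            return counts, total
        if min(lengths) < panel.k:
            raise ValueError(f"read length {min(lengths)} below k={panel.k}")
        enc = encode_dna(reads)
    return map_reads_encoded(panel, enc, theta)


# ---------------------------------------------------------------------------
# Sample profiles


@dataclasses.dataclass
class SampleProfile:
    biosample: str
    group: str
    counts: dict[str, int]
    total_reads: int
    cpm: dict[str, float]
    present: dict[str, bool]
    qc_pass: bool


def profile_samples(
    run_counts: dict[str, tuple[dict[str, int], int]],
    metadata: pd.DataFrame,
    qc_min_reads: int = QC_MIN_READS,
    cpm_threshold: float = CPM_PRESENCE,
) -> list[SampleProfile]:
    """Aggregate per-run counts to biosamples and compute CPM/presence.

    ``run_counts`` maps run id → (per-gene counts, total reads);
    ``metadata`` needs columns run, biosample, group. Counts are summed per
    biosample before QC; samples with total < ``qc_min_reads`` are flagged
    qc_pass=False (they are reported but carry no presence calls).
    """
    meta = metadata.set_index("run")
    orphans = set(run_counts) - set(meta.index)
    if orphans:
        raise ValueError(f"runs without metadata: {sorted(orphans)}")
    dup = meta.index[meta.index.duplicated()]
    if len(dup):
        raise ValueError(f"runs mapped to multiple biosamples: {sorted(set(dup))}")

    by_sample: dict[str, dict] = {}
    for run, (counts, total) in run_counts.items():
        bs = meta.loc[run, "biosample"]
        group = meta.loc[run, "group"]
        slot = by_sample.setdefault(bs, {"group": group, "counts": {}, "total": 0})
        if slot["group"] != group:
            raise ValueError(f"biosample {bs} appears with conflicting groups")
        for g, c in counts.items():
            slot["counts"][g] = slot["counts"].get(g, 0) + c
        slot["total"] += total

    profiles = []
    for bs in sorted(by_sample):
        slot = by_sample[bs]
        total = slot["total"]
        qc = total >= qc_min_reads
        cpm = {g: (c / total * 1e6 if total else 0.0) for g, c in slot["counts"].items()}
        present = {g: (qc and v > cpm_threshold) for g, v in cpm.items()}
        profiles.append(
            SampleProfile(bs, slot["group"], dict(slot["counts"]), total, cpm,
                          present, qc)
        )
    return profiles


def profiles_to_frame(profiles: list[SampleProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for g in p.counts:
            rows.append({
                "biosample": p.biosample, "group": p.group, "gene": g,
                "count": p.counts[g], "total_reads": p.total_reads,
                "cpm": p.cpm[g], "present": int(p.present[g]),
                "qc_pass": int(p.qc_pass),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group tests


@dataclasses.dataclass
class PrevalenceResult:
    n_a: int
    present_a: int
    n_b: int
    present_b: int
    z: float
    p: float
    degenerate: bool = False

    @property
    def prop_a(self) -> float:
        return self.present_a / self.n_a

    @property
    def prop_b(self) -> float:
        return self.present_b / self.n_b


def prevalence_test(
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    continuity: bool = True,
) -> PrevalenceResult:
    """One-sided pooled two-proportion z-test of H1: prevalence(A) > prevalence(B).

    ``group_a``/``group_b`` are (n, n_present). The Yates continuity
    correction is applied by default (mirroring the usual behavior of the
    standard statistical routine); ``continuity=False`` disables it.
    Degenerate pooled proportions (0 or 1) return p=1.0 / p=0.5 by
    convention, flagged.
    """
    n1, x1 = group_a
    n2, x2 = group_b
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs at least one sample")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("present counts must lie in [0, n]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled == 0:
        return PrevalenceResult(n1, x1, n2, x2, 0.0, 1.0, degenerate=True)
    if pooled == 1:
        return PrevalenceResult(n1, x1, n2, x2, 0.0, 0.5, degenerate=True)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    diff = x1 / n1 - x2 / n2
    if continuity and diff != 0:
        corr = 0.5 * (1 / n1 + 1 / n2)
        diff = math.copysign(max(abs(diff) - corr, 0.0), diff)
    z = diff / se
    p = float(stats.norm.sf(z))
    return PrevalenceResult(n1, x1, n2, x2, z, p)


@dataclasses.dataclass
class AbundanceResult:
    n_a: int
    n_b: int
    statistic: float  # rank-sum of group A (midranks)
    p: float
    degenerate: bool = False


_EXACT_CUTOFF = 50  # both groups below this and tie-free → exact distribution


def abundance_test(
    values_a: np.ndarray | list[float],
    values_b: np.ndarray | list[float],
    drop_zeros: bool = False,
    method: str = "auto",
) -> AbundanceResult:
    """One-sided Wilcoxon rank-sum test of H1: values in A are larger.

    ``method="auto"`` follows the convention of the standard R routine:
    the exact rank-sum distribution when both groups have fewer than 50
    tie-free values, otherwise the normal approximation with midranks,
    tie-corrected variance and continuity correction. ``"asymptotic"`` and
    ``"exact"`` force one path. ``drop_zeros`` removes zero values from
    both groups first (plot-style exclusion); by default zeros are kept.
    All-identical pooled values return p=0.5, flagged degenerate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if drop_zeros:
        a, b = a[a > 0], b[b > 0]
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    if method not in ("auto", "asymptotic", "exact"):
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        return AbundanceResult(a.size, b.size, w, 0.5, degenerate=True)
    has_ties = len(np.unique(pooled)) < pooled.size
    if method == "auto":
        small = max(a.size, b.size) < _EXACT_CUTOFF
        method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return AbundanceResult(a.size, b.size, w, float(res.pvalue))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values."""
    return list(stats.false_discovery_control(np.asarray(pvalues), method="bh"))


def group_tests(
    profiles: list[SampleProfile],
    group_a: str,
    group_b: str,
    continuity: bool = True,
    drop_zeros: bool = False,
) -> pd.DataFrame:
    """Per-gene prevalence and abundance comparisons (A > B), with BH
    adjustment across genes. QC-failing samples are excluded."""
    ok = [p for p in profiles if p.qc_pass]
    pa = [p for p in ok if p.group == group_a]
    pb = [p for p in ok if p.group == group_b]
    if not pa or not pb:
        raise ValueError("both groups need at least one QC-passing sample")
    genes = sorted({g for p in ok for g in p.counts})
    rows = []
    for g in genes:
        prev = prevalence_test(
            (len(pa), sum(p.present[g] for p in pa)),
            (len(pb), sum(p.present[g] for p in pb)),
            continuity=continuity,
        )
        ab = abundance_test(
            [p.cpm[g] for p in pa], [p.cpm[g] for p in pb], drop_zeros=drop_zeros
        )
        rows.append({
            "gene": g,
            "n_a": prev.n_a, "present_a": prev.present_a, "prop_a": prev.prop_a,
            "n_b": prev.n_b, "present_b": prev.present_b, "prop_b": prev.prop_b,
            "z": prev.z, "p_prevalence": prev.p,
            "p_abundance": ab.p,
        })
    df = pd.DataFrame(rows)
    df["p_prevalence_bh"] = bh_adjust(list(df["p_prevalence"]))
    df["p_abundance_bh"] = bh_adjust(list(df["p_abundance"]))
    return df


def log_cpm_table(profiles: list[SampleProfile]) -> pd.DataFrame:
    """Natural-log CPM values for plotting; zero-count samples are dropped."""
    rows = []
    for p in profiles:
        if not p.qc_pass:
            continue
        for g, v in p.cpm.items():
            if v > 0:
                rows.append({"biosample": p.biosample, "group": p.group,
                             "gene": g, "ln_cpm": math.log(v)})
    return pd.DataFrame(rows)
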