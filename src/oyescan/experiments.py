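"""Self-contained benchmark experiments on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and measures the outcome against planted truth or an
independent oracle (brute-force enumeration, closed forms, exhaustive
permutation). They back both the acceptance test suite and
``scripts/acceptance.py``.

Problem sizes are chosen for desk-scale runs; in particular the metagenome
recovery experiments use a read depth of 1,000 per sample — at 1% panel
abundance a carried gene yields ~10 mapped reads, so presence detection is
essentially certain and the statistics are driven (as at full depth) by the
Bernoulli carriage sampling. A single higher-depth fidelity run is also
provided.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from . import hmm as hm
from . import metaprof as mp
from . import msa as ms
from . import orthoscreen as ortho
from . import phylo as ph
from . import synthgen as sg
from .seqs import AA, AA_INDEX, mutate_protein, random_dna, random_protein


# ---------------------------------------------------------------------------
# 1. Phenotype screen recovery


def _screen_design(rng: np.random.Generator, n_decoys: int = 10,
                   divergence: float = 0.15) -> sg.PangenomeDesign:
    phenotype = {f"gp{i}": sg.POSITIVE for i in range(1, 4)}
    phenotype |= {f"gn{i}": sg.NEGATIVE for i in range(1, 4)}
    return sg.PangenomeDesign(
        phenotype=phenotype,
        planted_family_id="fam_target",
        decoy_family_ids=tuple(f"decoy_{i:02d}" for i in range(n_decoys)),
        protein_len=150,
        divergence=divergence,
    )


def screen_recovery(n_seeds: int = 100, seed: int = 0, n_decoys: int = 10,
                    divergence: float = 0.15) -> dict:
    """Fraction of seeded pangenomes where screen + label filter return
    exactly the planted family (3 positive + 3 negative genomes)."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    recovered = 0
    for s in child_seeds:
        design = _screen_design(np.random.default_rng(int(s)), n_decoys, divergence)
        genomes, truth = sg.build_pangenome(design, int(s))
        proteomes = {g.genome_id: g.proteins() for g in genomes}
        labels = {gene: "OYE" for _, gene in truth.members[design.planted_family_id]}
        for fam in design.decoy_family_ids[:3]:  # a few decoys share the label
            labels |= {gene: "OYE" for _, gene in truth.members[fam]}
        matrix = ortho.rbh_orthogroups(proteomes, phenotype=design.phenotype)
        candidates = ortho.phenotype_screen(matrix)
        kept = ortho.label_filter(candidates, matrix, labels, "OYE")
        planted = set(truth.members[design.planted_family_id])
        if len(kept) == 1 and set(matrix.groups[kept[0]]) == planted:
            recovered += 1
    return {"n": n_seeds, "recovered": recovered, "rate": recovered / n_seeds}


# ---------------------------------------------------------------------------
# 2. Profile-HMM DP vs brute-force path enumeration


def enumerate_paths(hmm: hm.ProfileHMM, seq: str, viterbi: bool) -> float:
    """Independent oracle: explicit recursion over every begin→end state
    path that emits ``seq``, in nats."""
    K = hmm.nstates
    t = hmm.log_t
    lo = hmm.log_odds
    x = [AA_INDEX[c] for c in seq]
    L = len(x)
    results: list[float] = []

    def succ(state):
        s, k = state
        out = []
        if s == "m":
            if k < K:
                out += [(("m", k + 1), t["mm"][k]), (("d", k + 1), t["md"][k])]
            out += [(("i", k), t["mi"][k])]
            if k == K:
                out += [("E", t["mm"][K])]
        elif s == "i":
            if k < K:
                out += [(("m", k + 1), t["im"][k]), (("d", k + 1), t["id"][k])]
            out += [(("i", k), t["ii"][k])]
            if k == K:
                out += [("E", t["im"][K])]
        else:
            if k < K:
                out += [(("m", k + 1), t["dm"][k]), (("d", k + 1), t["dd"][k])]
            if k == K:
                out += [("E", t["dm"][K])]
        return out

    def rec(state, i, acc):
        if acc < -1e25:
            return
        for nxt, lt in succ(state):
            if nxt == "E":
                if i == L:
                    results.append(acc + lt)
                continue
            s, k = nxt
            if s in ("m", "i"):
                if i == L:
                    continue
                em = lo[k - 1, x[i]] if s == "m" else 0.0
                rec(nxt, i + 1, acc + lt + em)
            else:
                rec(nxt, i, acc + lt)

    rec(("m", 0), 0, 0.0)
    if not results:
        return -math.inf
    arr = np.array(results)
    if viterbi:
        return float(arr.max())
    m = arr.max()
    return float(m + np.log(np.exp(arr - m).sum()))


def _random_small_profile(rng: np.random.Generator, k_states: int) -> hm.ProfileHMM:
    n_rows = int(rng.integers(2, 5))
    rows = []
    for _ in range(n_rows):
        # full-occupancy core plus occasional deletions keeps K = k_states
        row = "".join(
            AA[rng.integers(0, 20)] if rng.random() > 0.2 else "-"
            for _ in range(k_states)
        )
        rows.append(row if row.strip("-") else "A" * k_states)
    # guarantee every column reaches 50% occupancy
    rows.append("".join(AA[rng.integers(0, 20)] for _ in range(k_states)))
    rows.append("".join(AA[rng.integers(0, 20)] for _ in range(k_states)))
    m = ms.MSA([f"r{i}" for i in range(len(rows))], rows)
    return hm.build_profile(m, model_id=f"k{k_states}")


def hmm_dp_max_error(seed: int = 0, max_states: int = 5, max_len: int = 8,
                     seqs_per_model: int = 3) -> dict:
    """Max |DP − enumeration| in nats over a grid of small models/sequences,
    for both forward and Viterbi."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    for k_states in range(1, max_states + 1):
        hmm = _random_small_profile(rng, k_states)
        if hmm.nstates > max_states:
            continue
        for _ in range(seqs_per_model):
            L = int(rng.integers(1, max_len + 1))
            seq = "".join(AA[rng.integers(0, 20)] for _ in range(L))
            for viterbi in (True, False):
                mine, _ = hm._dp_glocal(hmm, seq, viterbi)
                oracle = enumerate_paths(hmm, seq, viterbi)
                worst = max(worst, abs(mine - oracle))
                n_checked += 1
    return {"n": n_checked, "max_error_nats": worst}


# ---------------------------------------------------------------------------
# 3. Fusion decomposition


def fusion_boundary(n_cases: int = 50, seed: int = 0, tolerance: int = 10) -> dict:
    """Planted consensusA⊕consensusB fusions: fraction with a FusionCall
    whose split lies within ±tolerance of the planted junction."""
    rng = np.random.default_rng(seed)
    cases_per_pair = 10
    n_pairs = math.ceil(n_cases / cases_per_pair)
    ok = 0
    done = 0
    max_dev = 0
    for pair_i in range(n_pairs):
        anc_a = random_protein(rng, 130)
        anc_b = random_protein(rng, 150)

        def build(anc, mid):
            fam = sg.FamilyModel(anc, {"c": 10}, per_branch_sub_prob=0.08)
            leaves = sg.build_family_set(fam, int(rng.integers(0, 2**31 - 1)))
            aln = ms.progressive_msa([(sid, s) for sid, _, s in leaves])
            trimmed, _ = ms.trim_msa(aln)
            return hm.build_profile(trimmed, model_id=mid)

        hmm_a = build(anc_a, "A")
        hmm_b = build(anc_b, "B")

        db: dict[str, str] = {}
        junctions: dict[str, int] = {}
        for c in range(cases_per_pair):
            if done + c >= n_cases and pair_i == n_pairs - 1:
                break
            linker = int(rng.integers(0, 9))
            dom_a = mutate_protein(rng, anc_a, 0.1)
            dom_b = mutate_protein(rng, anc_b, 0.1)
            gap = "".join("G" if rng.random() < 0.5 else "S" for _ in range(linker))
            pid = f"fused_{pair_i}_{c}"
            db[pid] = dom_a + gap + dom_b
            junctions[pid] = len(dom_a) + linker // 2
        for i in range(5):
            db[f"bg_{pair_i}_{i}"] = random_protein(rng, 140)

        _, fusions = hm.calibrate_and_search(
            [hmm_a, hmm_b], db, evalue_ceiling=1e-5, null_n=200,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        calls = {f.protein_id: f for f in fusions}
        for pid, junction in junctions.items():
            done += 1
            call = calls.get(pid)
            if call is None or len(call.splits) != 1:
                continue
            order_ok = [h.model_id for h in call.hits] == ["A", "B"]
            dev = abs(call.splits[0] - junction)
            max_dev = max(max_dev, dev)
            if order_ok and dev <= tolerance:
                ok += 1
    return {"n": done, "within_tolerance": ok, "rate": ok / done,
            "max_deviation": max_dev}


# ---------------------------------------------------------------------------
# 4. Neighbor joining on additive distances


def nj_recovery(n_trees: int = 100, seed: int = 0, max_leaves: int = 10) -> dict:
    rng = np.random.default_rng(seed)
    perfect = 0
    for _ in range(n_trees):
        n_leaves = int(rng.integers(4, max_leaves + 1))
        truth = ph.random_additive_tree(rng, n_leaves)
        dist, names = ph.tree_distances(truth)
        rec = ph.nj_tree(dist, names)
        if ph.robinson_foulds(truth, rec) == 0:
            perfect += 1
    return {"n": n_trees, "rf_zero": perfect, "rate": perfect / n_trees}


# ---------------------------------------------------------------------------
# 5. Fitch parsimony vs exhaustive minimization


def _brute_force_parsimony(tree: ph.Node, states: dict[str, str]) -> int:
    internal = [n for n in tree.postorder() if not n.is_leaf]
    alphabet = sorted(set(states.values()))
    best = math.inf
    for assign in itertools.product(alphabet, repeat=len(internal)):
        lookup = {id(n): a for n, a in zip(internal, assign)}
        cost = 0
        for n in tree.postorder():
            if n.parent is None:
                continue
            s = states[n.name] if n.is_leaf else lookup[id(n)]
            if s != lookup[id(n.parent)]:
                cost += 1
        best = min(best, cost)
    return int(best)


def fitch_agreement(n_cases: int = 50, seed: int = 0) -> dict:
    """Fitch score vs brute-force minimum over random 6-leaf, 3-state cases."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        tree = ph.random_additive_tree(rng, 6)
        states = {name: "ABC"[rng.integers(0, 3)] for name in tree.leaf_names()}
        res = ph.fitch_ancestral(tree, {k: v for k, v in states.items()})
        if res.scores[0] == _brute_force_parsimony(tree, states):
            agree += 1
    return {"n": n_cases, "agree": agree, "rate": agree / n_cases}


# ---------------------------------------------------------------------------
# 6. Statistics vs closed form / exact enumeration


def _ztest_oracle(x1, n1, x2, n2) -> float:
    """Independent closed form via erfc (no continuity correction)."""
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return 0.5 * math.erfc(z / math.sqrt(2))


def _wilcoxon_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact one-sided (A greater) rank-sum p by full enumeration of the
    C(n1+n2, n1) group assignments of the pooled values."""
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if ranks[list(combo)].sum() >= obs - 1e-9:
            count += 1
    return count / total


def stats_agreement(seed: int = 0, max_group: int = 8, reps: int = 2) -> dict:
    rng = np.random.default_rng(seed)
    z_worst = 0.0
    for _ in range(200):
        n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
        x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        if x1 + x2 in (0, n1 + n2):
            continue
        mine = mp.prevalence_test((n1, x1), (n2, x2), continuity=False).p
        z_worst = max(z_worst, abs(mine - _ztest_oracle(x1, n1, x2, n2)))

    w_worst = 0.0  # default method vs enumeration, all sizes ≤ max_group
    w_asym_worst = 0.0  # asymptotic path where it is a sensible approximation
    for n1 in range(1, max_group + 1):
        for n2 in range(1, max_group + 1):
            for _ in range(reps):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                a, b = vals[:n1], vals[n1:]
                exact = _wilcoxon_exact(a, b)
                mine = mp.abundance_test(a, b).p
                w_worst = max(w_worst, abs(mine - exact))
                if min(n1, n2) >= 3:
                    asym = mp.abundance_test(a, b, method="asymptotic").p
                    w_asym_worst = max(w_asym_worst, abs(asym - exact))
    return {"ztest_max_abs_diff": z_worst, "wilcoxon_max_abs_diff": w_worst,
            "wilcoxon_asymptotic_max_abs_diff": w_asym_worst}


# ---------------------------------------------------------------------------
# 7. Metagenome parameter recovery and type-I control


def _metagenome_trial(
    trial_seed: int,
    carriage_a: float,
    carriage_b: float,
    n_per_group: int,
    depth: int,
    gene_len: int = 1200,
    read_len: int = 100,
    error_prob: float = 0.005,
) -> tuple[float, float, float]:
    """One seeded end-to-end run: generate → map → profile → z-test.

    Returns (prevalence_a, prevalence_b, one-sided p without continuity).
    """
    rng = np.random.default_rng(trial_seed)
    panel = {"target": random_dna(rng, gene_len)}
    backgrounds = sg.random_background(rng, 5, 10_000)
    design = sg.MetagenomeDesign(
        groups={"A": n_per_group, "B": n_per_group},
        carriage={"A": {"target": carriage_a}, "B": {"target": carriage_b}},
        depth=depth, read_length=read_len, error_prob=error_prob,
    )
    sim = sg.MetagenomeSimulator(design, panel, backgrounds,
                                 seed=int(rng.integers(0, 2**31 - 1)))
    gp = mp.GenePanel(panel)

    batches, sample_ids, groups = [], [], []
    for truth, runs in sim.samples():
        arrs = [reads for _, reads in runs]
        batches.append(np.concatenate(arrs) if len(arrs) > 1 else arrs[0])
        sample_ids.append(truth.biosample)
        groups.append(truth.group)
    sizes = [b.shape[0] for b in batches]
    assigned = mp.assign_reads_encoded(gp, np.concatenate(batches))

    run_counts = {}
    off = 0
    for sid, size in zip(sample_ids, sizes):
        seg = assigned[off : off + size]
        off += size
        run_counts[f"{sid}_run1"] = ({"target": int((seg >= 0).sum())}, size)
    import pandas as pd

    meta = pd.DataFrame({
        "run": [f"{s}_run1" for s in sample_ids],
        "biosample": sample_ids,
        "group": groups,
    })
    profiles = mp.profile_samples(run_counts, meta, qc_min_reads=min(depth, 1000))
    pa = [p for p in profiles if p.group == "A" and p.qc_pass]
    pb = [p for p in profiles if p.group == "B" and p.qc_pass]
    xa = sum(p.present["target"] for p in pa)
    xb = sum(p.present["target"] for p in pb)
    res = mp.prevalence_test((len(pa), xa), (len(pb), xb), continuity=False)
    return xa / len(pa), xb / len(pb), res.p


def prevalence_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    carriage: tuple[float, float] = (0.9, 0.6),
    n_per_group: int = 60,
    depth: int = 1000,
    p_threshold: float = 0.01,
) -> dict:
    """Recovery of designed group prevalences and power of the one-sided
    z-test across seeded synthetic metagenome cohorts."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    rejections = 0
    within = 0
    errs = []
    est_a, est_b = [], []
    for s in seeds:
        pa, pb, p = _metagenome_trial(int(s), carriage[0], carriage[1],
                                      n_per_group, depth)
        est_a.append(pa)
        est_b.append(pb)
        errs.extend([abs(pa - carriage[0]), abs(pb - carriage[1])])
        if abs(pa - carriage[0]) <= 0.1 and abs(pb - carriage[1]) <= 0.1:
            within += 1
        if p < p_threshold:
            rejections += 1
    return {
        "n": n_seeds,
        "rejections": rejections,
        "rejection_rate": rejections / n_seeds,
        "mean_prevalence_a": float(np.mean(est_a)),
        "mean_prevalence_b": float(np.mean(est_b)),
        "within_0.1": within,
        "mean_abs_prevalence_error": float(np.mean(errs)),
        "max_abs_prevalence_error": float(np.max(errs)),
    }


def type_i_rate(
    n_seeds: int = 100,
    seed: int = 0,
    carriage: float = 0.75,
    n_per_group: int = 60,
    depth: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate under equal carriage (null)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    rejections = sum(
        _metagenome_trial(int(s), carriage, carriage, n_per_group, depth)[2] < alpha
        for s in seeds
    )
    return {"n": n_seeds, "rejections": int(rejections),
            "rate": rejections / n_seeds}


def full_depth_fidelity(seed: int = 0, depth: int = 10_000,
                        n_per_group: int = 60) -> dict:
    """One higher-depth run of the same experiment, as a fidelity check that
    the scaled-down depth does not change behavior."""
    pa, pb, p = _metagenome_trial(seed + 977, 0.9, 0.6, n_per_group, depth)
    return {"prevalence_a": pa, "prevalence_b": pb, "p": p, "depth": depth,
            "n_per_group": n_per_group}
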