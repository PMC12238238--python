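"""Profile hidden Markov models: build, score, calibrate, search, and
decompose fused two-domain proteins.

Architecture is the classic match/insert/delete profile topology (Durbin et
al.): match states with 20-letter emission distributions, insert states
emitting the background, and delete states bridging match columns. Scores
are log-odds against a fixed background composition, computed in log space.

Two scoring modes exist:

* **glocal** — the model is traversed begin→end and the whole sequence is
  consumed (terminal inserts absorb flanks); used for scoring a trimmed
  domain window and checked exactly against brute-force path enumeration.
* **local** — the alignment may start at any match state and end at any
  match state (uniform 1/K entry and exit), leaving the rest of the
  sequence unaligned; used for database search and domain-envelope
  detection, which is what fused-gene decomposition needs.

E-values come from a Gumbel null fitted by the method of moments to the
local bit scores of background-sampled sequences: with ``N`` database
sequences, ``E = N · P(S_null ≥ S)``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .msa import MSA
from .seqs import AA, AA_INDEX, BG_FREQS, GAP

_NEG = -1e30
_EULER = 0.5772156649015329
LN2 = math.log(2)


@dataclasses.dataclass
class ProfileHMM:
    """Parameterized profile with optional Gumbel calibration.

    ``log_t`` holds log transition probabilities as arrays indexed by the
    source column (column 0 is the begin state): keys ``mm, mi, md, im, ii,
    id, dm, dd``; entry ``mm[k]`` is M_k→M_{k+1} and the transition out of
    column K targets the end state.
    """

    model_id: str
    match_probs: np.ndarray  # (K, 20)
    log_t: dict[str, np.ndarray]
    column_map: np.ndarray  # (K,) 1-based reference residue positions
    background: np.ndarray = dataclasses.field(default_factory=lambda: BG_FREQS.copy())
    calibration: tuple[float, float] | None = None  # Gumbel (mu, beta), bits

    def __post_init__(self):
        k = self.nstates
        with np.errstate(divide="ignore"):
            self.log_odds = np.where(
                self.match_probs > 0,
                np.log(self.match_probs) - np.log(self.background)[None, :],
                _NEG,
            )
        if np.any(np.diff(self.column_map) <= 0):
            raise ValueError("column_map must be strictly increasing")
        assert self.match_probs.shape == (k, 20)

    @property
    def nstates(self) -> int:
        return self.match_probs.shape[0]

    def consensus(self) -> str:
        return "".join(AA[i] for i in self.match_probs.argmax(axis=1))


def build_profile(
    msa: MSA,
    pseudocount: float = 1.0,
    match_occupancy: float = 0.5,
    ref_id: str | None = None,
    model_id: str = "model",
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a (trimmed) alignment.

    Columns with residue occupancy ≥ ``match_occupancy`` become match
    states. Emissions use Laplace-style pseudocounts (``pseudocount`` added
    per letter: a column with counts {A:2} and α=1 gives P(A) = 3/22).
    Transitions are counted along each row's implied state path with a
    pseudocount of 1 on every legal transition.
    """
    bg = BG_FREQS if background is None else background
    arr = np.array([list(r) for r in msa.rows])
    occupancy = (arr != GAP).mean(axis=0)
    match_cols = np.nonzero(occupancy >= match_occupancy)[0]
    K = len(match_cols)
    if K == 0:
        raise ValueError("no columns meet the match-occupancy rule")

    probs = np.zeros((K, 20))
    for k, j in enumerate(match_cols):
        counts = np.zeros(20)
        for c in arr[:, j]:
            if c != GAP:
                counts[AA_INDEX[c]] += 1
        total = counts.sum() + 20 * pseudocount
        if total == 0:
            raise ValueError(f"empty match column {j}")
        probs[k] = (counts + pseudocount) / total

    # transition counts along each row's path through the column classes
    keys = ("mm", "mi", "md", "im", "ii", "id", "dm", "dd")
    counts_t = {key: np.zeros(K + 1) for key in keys}
    is_match = np.zeros(arr.shape[1], dtype=bool)
    is_match[match_cols] = True
    col_to_state = np.cumsum(is_match)  # match column j -> state index (1-based)
    for row in arr:
        prev = ("m", 0)  # begin behaves as M_0
        for j in range(arr.shape[1]):
            if is_match[j]:
                cur = ("m", col_to_state[j]) if row[j] != GAP else ("d", col_to_state[j])
            else:
                if row[j] == GAP:
                    continue
                cur = ("i", col_to_state[j])
            if cur[0] == "i" and prev == cur:
                counts_t["ii"][cur[1]] += 1
            elif prev[0] == "d" and cur[0] == "i":
                # D→I is not part of the topology; the residue is attributed
                # to a fresh insert and the delete exits via the next match.
                pass
            else:
                counts_t[prev[0] + cur[0]][prev[1]] += 1
            prev = cur
        counts_t[prev[0] + "m"][prev[1]] += 1  # exit to end

    log_t = {}
    grouped = {"m": ("mm", "mi", "md"), "i": ("im", "ii", "id"), "d": ("dm", "dd")}
    totals = {s: sum(counts_t[k] for k in ks) for s, ks in grouped.items()}
    for s, ks in grouped.items():
        denom = totals[s] + len(ks)  # +1 pseudocount per legal transition
        for k in ks:
            with np.errstate(divide="ignore"):
                log_t[k] = np.log((counts_t[k] + 1.0) / denom)
    # begin state has no insert/delete history beyond column 0; delete/insert
    # out of the terminal column cannot target D_{K+1}
    for k in ("md", "id"):
        log_t[k][K] = _NEG
    log_t["dd"][K] = _NEG
    # renormalize the terminal column (D_{K+1} removed)
    for s, ks in grouped.items():
        cols = np.array([log_t[k][K] for k in ks])
        finite = cols > _NEG / 2
        if finite.any():
            z = np.log(np.exp(cols[finite]).sum())
            for k, f in zip(ks, finite):
                log_t[k][K] = log_t[k][K] - z if f else _NEG

    # reference-coordinate map (default reference: first row)
    ref_row = msa.rows[msa.ids.index(ref_id)] if ref_id else msa.rows[0]
    cmap = np.zeros(K, dtype=int)
    pos = 0
    nxt = {}
    res_count = 0
    for j, c in enumerate(ref_row):
        if c != GAP:
            res_count += 1
        nxt[j] = res_count
    for k, j in enumerate(match_cols):
        p = nxt[j]
        if p <= pos:  # reference gapped here; keep the map strictly increasing
            p = pos + 1
        cmap[k] = p
        pos = p

    return ProfileHMM(model_id, probs, log_t, cmap,
                      background=np.asarray(bg, dtype=float))


# ---------------------------------------------------------------------------
# Glocal scoring


def _encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in seq.upper()], dtype=int)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc} in sequence") from exc


def _dp_glocal(hmm: ProfileHMM, seq: str, viterbi: bool):
    """Shared Viterbi/forward DP. Returns (score_nats, matrices)."""
    x = _encode_protein(seq)
    L, K = len(x), hmm.nstates
    t = hmm.log_t
    lo = hmm.log_odds

    def reduce3(*vals):
        out = np.maximum.reduce(vals) if viterbi else _logsumexp_stack(vals)
        return out

    VM = np.full((L + 1, K + 1), _NEG)
    VI = np.full((L + 1, K + 1), _NEG)
    VD = np.full((L + 1, K + 1), _NEG)
    VM[0, 0] = 0.0
    # deletes reachable before any emission
    cd = np.concatenate([[0.0], np.cumsum(t["dd"][1:K])])  # cd[k-1] chain to D_k
    start0 = np.full(K, _NEG)
    start0[0] = t["md"][0]
    VD[0, 1:] = _chain_d(start0, cd, viterbi)

    for i in range(1, L + 1):
        e = lo[:, x[i - 1]]
        VM[i, 1:] = e + reduce3(
            VM[i - 1, :K] + t["mm"][:K],
            VI[i - 1, :K] + t["im"][:K],
            VD[i - 1, :K] + t["dm"][:K],
        )
        VI[i, :] = reduce3(VM[i - 1, :] + t["mi"], VI[i - 1, :] + t["ii"])
        start = reduce3(VM[i, :K] + t["md"][:K], VI[i, :K] + t["id"][:K])
        VD[i, 1:] = _chain_d(start, cd, viterbi)

    finals = (VM[L, K] + t["mm"][K], VI[L, K] + t["im"][K], VD[L, K] + t["dm"][K])
    score = max(finals) if viterbi else _logsumexp_stack([np.array([v]) for v in finals])[0]
    return float(score), (VM, VI, VD)


def _logsumexp_stack(vals):
    stack = np.stack(np.broadcast_arrays(*vals))
    m = stack.max(axis=0)
    safe = np.where(m > _NEG / 2, m, 0.0)
    with np.errstate(divide="ignore"):
        out = safe + np.log(np.exp(stack - safe[None]).sum(axis=0))
    return np.where(m > _NEG / 2, out, _NEG)


def _chain_d(start: np.ndarray, cd: np.ndarray, viterbi: bool) -> np.ndarray:
    """Propagate along the delete chain: out[k] covers D_{k+1}, k=0..K-1.

    ``start[j]`` is the score of entering D_{j+1} directly; ``cd[j]`` is the
    accumulated D→D log probability up to that column.
    """
    vals = start - cd
    if viterbi:
        acc = np.maximum.accumulate(vals)
    else:
        acc = np.logaddexp.accumulate(np.clip(vals, _NEG, None))
    return acc + cd


def score_sequence(hmm: ProfileHMM, seq: str, mode: str = "forward") -> float:
    """Glocal log-odds bit score of ``seq`` under the profile.

    ``mode`` is ``"viterbi"`` (best path) or ``"forward"`` (sum over paths);
    forward ≥ viterbi always holds.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if mode not in ("viterbi", "forward"):
        raise ValueError(f"unknown mode {mode!r}")
    score, _ = _dp_glocal(hmm, seq, viterbi=(mode == "viterbi"))
    return score / LN2


# ---------------------------------------------------------------------------
# Local (envelope) scoring


def viterbi_local(hmm: ProfileHMM, seq: str) -> tuple[float, tuple[int, int]]:
    """Best local hit: bits plus the 1-based envelope of matched residues.

    Entry into any match state and exit from any match state, each at
    probability 1/K; unaligned flanking residues are free (background).
    """
    x = _encode_protein(seq)
    L, K = len(x), hmm.nstates
    t = hmm.log_t
    lo = hmm.log_odds
    entry = -math.log(K)
    exit_lp = -math.log(K)

    M = np.full(K, _NEG)
    I = np.full(K, _NEG)
    D = np.full(K, _NEG)
    # start-position trackers (0-based residue index where the hit begins)
    PM = np.zeros(K, dtype=int)
    PI = np.zeros(K, dtype=int)
    PD = np.zeros(K, dtype=int)
    cd = np.concatenate([[0.0], np.cumsum(t["dd"][1:K])])

    best = -math.inf
    best_env = (1, 1)
    for i in range(L):
        e = lo[:, x[i]]
        cand = np.stack([
            np.concatenate([[_NEG], M[:-1] + t["mm"][1:K]]),
            np.concatenate([[_NEG], I[:-1] + t["im"][1:K]]),
            np.concatenate([[_NEG], D[:-1] + t["dm"][1:K]]),
            np.full(K, entry),
        ])
        starts = np.stack([
            np.concatenate([[0], PM[:-1]]),
            np.concatenate([[0], PI[:-1]]),
            np.concatenate([[0], PD[:-1]]),
            np.full(K, i, dtype=int),
        ])
        choice = cand.argmax(axis=0)
        Mn = e + cand[choice, np.arange(K)]
        PMn = starts[choice, np.arange(K)]

        icand = np.stack([M + t["mi"][1 : K + 1], I + t["ii"][1 : K + 1]])
        istarts = np.stack([PM, PI])
        ich = icand.argmax(axis=0)
        In = icand[ich, np.arange(K)]
        PIn = istarts[ich, np.arange(K)]

        dcand = np.stack([Mn[:-1] + t["md"][1:K], In[:-1] + t["id"][1:K]])
        dstarts = np.stack([PMn[:-1], PIn[:-1]])
        dch = dcand.argmax(axis=0)
        start_d = np.concatenate([[_NEG], dcand[dch, np.arange(K - 1)]])
        pstart_d = np.concatenate([[0], dstarts[dch, np.arange(K - 1)]])
        vals = start_d - cd
        acc = np.maximum.accumulate(vals)
        take_new = vals >= acc - 1e-12
        run_idx = np.maximum.accumulate(np.where(take_new, np.arange(K), 0))
        Dn = acc + cd
        PDn = pstart_d[run_idx]

        M, I, D = Mn, In, Dn
        PM, PI, PD = PMn, PIn, PDn

        scores = M + exit_lp
        k_best = int(scores.argmax())
        if scores[k_best] > best:
            best = float(scores[k_best])
            best_env = (int(PM[k_best]) + 1, i + 1)

    return best / LN2, best_env


# ---------------------------------------------------------------------------
# Calibration, search, fusion


@dataclasses.dataclass(frozen=True)
class DomainHit:
    protein_id: str
    model_id: str
    env_start: int  # 1-based inclusive
    env_end: int
    bits: float
    evalue: float

    def __post_init__(self):
        if self.env_start > self.env_end:
            raise ValueError("envelope start must not exceed end")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


@dataclasses.dataclass(frozen=True)
class FusionCall:
    protein_id: str
    hits: tuple[DomainHit, ...]  # ordered by envelope
    splits: tuple[int, ...]  # one per adjacent pair; domain i spans (prev, split]


def calibrate(
    hmm: ProfileHMM, null_n: int = 300, null_len: int = 300, seed: int = 0
) -> ProfileHMM:
    """Fit the Gumbel null for local bit scores by the method of moments.

    Scores ``null_n`` i.i.d. background-composition sequences of length
    ``null_len``; ``beta = s·√6/π`` and ``mu = mean − γ·beta``. The fitted
    (mu, beta) are stored on the profile and drive E-values.
    """
    if null_n < 200:
        raise ValueError("null_n must be at least 200 for a stable fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(null_n)
    for i in range(null_n):
        idx = rng.choice(20, size=null_len, p=hmm.background)
        seq = "".join(AA[j] for j in idx)
        scores[i], _ = viterbi_local(hmm, seq)
    s = scores.std(ddof=1)
    if s <= 1e-9:
        raise ValueError("degenerate null fit: zero scale")
    beta = s * math.sqrt(6) / math.pi
    mu = scores.mean() - _EULER * beta
    hmm.calibration = (float(mu), float(beta))
    return hmm


def gumbel_sf(bits: float, mu: float, beta: float) -> float:
    z = (bits - mu) / beta
    # survival of the Gumbel (max) distribution
    if z > 30:
        return math.exp(-z)  # asymptotic, avoids underflow to 0 too early
    if z < -30:
        return 1.0
    return -math.expm1(-math.exp(-z))


def evalue(hmm: ProfileHMM, bits: float, db_size: int) -> float:
    if hmm.calibration is None:
        raise ValueError(f"model {hmm.model_id} is not calibrated")
    mu, beta = hmm.calibration
    return db_size * gumbel_sf(bits, mu, beta)


def search(
    hmms: list[ProfileHMM],
    proteins: dict[str, str],
    evalue_ceiling: float = 1e-5,
    db_size: int | None = None,
) -> list[DomainHit]:
    """Score every protein with every calibrated model; keep hits with
    E ≤ ``evalue_ceiling``."""
    n = db_size if db_size is not None else len(proteins)
    hits = []
    for pid, seq in proteins.items():
        for hmm in hmms:
            bits, (s, e) = viterbi_local(hmm, seq)
            ev = evalue(hmm, bits, n)
            if ev <= evalue_ceiling:
                hits.append(DomainHit(pid, hmm.model_id, s, e, bits, ev))
    return hits


def fusion_calls(hits: list[DomainHit]) -> list[FusionCall]:
    """Group per-protein hits into fusion calls.

    A protein with ≥2 non-overlapping hits from distinct models becomes a
    FusionCall; each adjacent pair gets one split at the integer midpoint
    (floor) of the inter-envelope gap.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    calls = []
    for pid in sorted(by_protein):
        hs = sorted(by_protein[pid], key=lambda h: (h.env_start, h.env_end))
        if len(hs) < 2:
            continue
        if len({h.model_id for h in hs}) < 2:
            continue
        ok = all(hs[i].env_end < hs[i + 1].env_start for i in range(len(hs) - 1))
        if not ok:
            continue
        splits = tuple(
            (hs[i].env_end + hs[i + 1].env_start) // 2 for i in range(len(hs) - 1)
        )
        calls.append(FusionCall(pid, tuple(hs), splits))
    return calls


def split_domains(call: FusionCall, seq: str) -> list[tuple[str, str]]:
    """Cut a fused protein at its split coordinates → [(domain_id, subseq)]."""
    bounds = [0, *call.splits, len(seq)]
    out = []
    for i, h in enumerate(call.hits):
        sub = seq[bounds[i] : bounds[i + 1]]
        out.append((f"{call.protein_id}|{h.model_id}", sub))
    return out


def calibrate_and_search(
    hmms: list[ProfileHMM],
    proteins: dict[str, str],
    evalue_ceiling: float = 1e-5,
    null_n: int = 300,
    seed: int = 0,
) -> tuple[list[DomainHit], list[FusionCall]]:
    """Calibrate each model on background-sampled sequences, then search.

    The null length is the median database protein length, so the fitted
    Gumbel matches the score scale of the actual search.
    """
    if not proteins:
        raise ValueError("empty protein database")
    null_len = int(np.median([len(s) for s in proteins.values()]))
    for i, hmm in enumerate(hmms):
        calibrate(hmm, null_n=null_n, null_len=null_len, seed=seed + i)
    hits = search(hmms, proteins, evalue_ceiling)
    return hits, fusion_calls(hits)


# ---------------------------------------------------------------------------
# Plain-text serialization


def write_profile(path, hmm: ProfileHMM):
    with open(path, "w") as fh:
        fh.write(f"#oyescan-profile\t{hmm.model_id}\tK={hmm.nstates}\n")
        fh.write("#column_map\t" + "\t".join(map(str, hmm.column_map)) + "\n")
        if hmm.calibration:
            fh.write(f"#calibration\t{hmm.calibration[0]:.6f}\t{hmm.calibration[1]:.6f}\n")
        fh.write("#background\t" + "\t".join(f"{v:.6e}" for v in hmm.background) + "\n")
        for key in ("mm", "mi", "md", "im", "ii", "id", "dm", "dd"):
            fh.write(f"#logt_{key}\t" + "\t".join(f"{v:.6e}" for v in hmm.log_t[key]) + "\n")
        for k in range(hmm.nstates):
            fh.write("\t".join(f"{v:.6e}" for v in hmm.match_probs[k]) + "\n")


def read_profile(path) -> ProfileHMM:
    meta: dict[str, list[str]] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0].startswith("#"):
                meta[parts[0][1:]] = parts[1:]
            else:
                rows.append([float(v) for v in parts])
    model_id = meta["oyescan-profile"][0]
    cmap = np.array([int(v) for v in meta["column_map"]])
    log_t = {
        key: np.array([float(v) for v in meta[f"logt_{key}"]])
        for key in ("mm", "mi", "md", "im", "ii", "id", "dm", "dd")
    }
    bg = np.array([float(v) for v in meta["background"]])
    hmm = ProfileHMM(model_id, np.array(rows), log_t, cmap, background=bg)
    if "calibration" in meta:
        hmm.calibration = (float(meta["calibration"][0]), float(meta["calibration"][1]))
    return hmm
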