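"""Shared sequence alphabets, background frequencies and small helpers.

The 20-letter amino-acid alphabet is ordered alphabetically by one-letter
code; every module that stores per-residue vectors uses this ordering.
Background amino-acid frequencies are the Robinson & Robinson (1991)
composition commonly used as the null model in profile searches.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP = "-"

# Robinson & Robinson (1991) background composition, ordered as AA.
BG_FREQS = np.array(
    [
        0.07805,  # A
        0.01925,  # C
        0.05364,  # D
        0.06295,  # E
        0.03856,  # F
        0.07377,  # G
        0.02199,  # H
        0.05142,  # I
        0.05744,  # K
        0.09019,  # L
        0.02243,  # M
        0.04487,  # N
        0.05203,  # P
        0.04264,  # Q
        0.05129,  # R
        0.07120,  # S
        0.05841,  # T
        0.06441,  # V
        0.01330,  # W
        0.03216,  # Y
    ]
)
BG_FREQS = BG_FREQS / BG_FREQS.sum()

DNA = "ACGT"
DNA_INDEX = {b: i for i, b in enumerate(DNA)}
_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")

# Minimal standard-code codon choice per amino acid (first codon is the
# deterministic fallback; the full synonym list feeds seeded wobble).
CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
STOP_CODON = "TAA"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_protein(seq: str, allow_x: bool = True) -> None:
    """Raise ValueError on characters outside the standard alphabet."""
    allowed = set(AA) | ({"X"} if allow_x else set())
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"illegal amino-acid character(s): {sorted(bad)}")


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Protein sampled i.i.d. from the background composition."""
    idx = rng.choice(len(AA), size=length, p=BG_FREQS)
    return "".join(AA[i] for i in idx)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=length))


def mutate_protein(
    rng: np.random.Generator,
    seq: str,
    sub_prob: float,
    frozen: set[int] | None = None,
) -> str:
    """Independent per-site substitution, uniform over the 19 alternatives.

    ``frozen`` holds 0-based positions that are never mutated (used for
    clade-diagnostic residues).
    """
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < sub_prob)[0]
    for i in hits:
        if frozen and i in frozen:
            continue
        alternatives = [a for a in AA if a != out[i]]
        out[i] = alternatives[rng.integers(0, 19)]
    return "".join(out)


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Seeded reverse translation with uniform synonymous-codon choice."""
    parts = ["ATG"]
    for aa in protein:
        syn = CODONS[aa]
        parts.append(syn[rng.integers(0, len(syn))])
    parts.append(STOP_CODON)
    return "".join(parts)


def encode_dna(seqs: list[str], length: int | None = None) -> np.ndarray:
    """Encode equal-length DNA strings to a (n, L) uint8 array (A,C,G,T → 0..3,
    anything else → 4)."""
    if length is None:
        length = len(seqs[0])
    lut = np.full(256, 4, dtype=np.uint8)
    for b, i in DNA_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    buf = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return lut[buf].reshape(len(seqs), length)


def kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers per row of an encoded DNA array.

    Returns (n, L-k+1) int64; windows containing a non-ACGT base get code -1.
    Uses a Horner rolling update so cost is O(L) per read, not O(L*k).
    """
    n, L = enc.shape
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    all_valid = bool((enc < 4).all())
    if all_valid:
        eT = np.ascontiguousarray(enc.T, dtype=np.int64)  # (L, n), fast columns
    else:
        valid = enc < 4
        eT = np.ascontiguousarray(np.where(valid, enc, 0).T, dtype=np.int64)
    top = 4 ** (k - 1)
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code *= 4
        code += eT[j]
    out = np.empty((L - k + 1, n), dtype=np.int64)
    out[0] = code
    for j in range(k, L):
        code -= eT[j - k] * top
        code *= 4
        code += eT[j]
        out[j - k + 1] = code
    out = np.ascontiguousarray(out.T)
    if not all_valid:
        # invalidate windows touching a non-ACGT base
        run = np.cumsum(valid.astype(np.int32), axis=1)
        window_ok = np.empty_like(out, dtype=bool)
        window_ok[:, 0] = run[:, k - 1] == k
        if L > k:
            window_ok[:, 1:] = (run[:, k:] - run[:, :-k]) == k
        out[~window_ok] = -1
    return out
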