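"""Progressive multiple sequence alignment and domain trimming.

The aligner is a classic progressive scheme: a 3-mer distance matrix feeds
an average-linkage guide tree (scipy), and profiles are merged bottom-up
with affine-gap global profile–profile alignment under BLOSUM62. Column
scores are expected substitution scores between residue-frequency columns,
so aligning two single sequences reduces exactly to pairwise global
alignment with the same gap convention as :mod:`oyescan.orthoscreen`
(first gap position 12, each further position 1).

Trimming reproduces the family-alignment cleanup used before profile
construction: short sequences are excluded first, columns outside a
reference-coordinate domain window are cut, and columns with strictly more
than the allowed gap fraction are removed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqs import AA, AA_INDEX, GAP

_GAP_OPEN = 12.0  # cost of the first gapped column
_GAP_EXT = 1.0
_NEG = -1e30


def _blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = m[a][b]
    return out


_S = _blosum62()


@dataclasses.dataclass
class MSA:
    """Equal-length aligned rows keyed by sequence id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len({len(r) for r in self.rows} or {0}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def gap_fractions(self) -> np.ndarray:
        arr = np.array([list(r) for r in self.rows])
        return (arr == GAP).mean(axis=0)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _freqs(rows: list[str]) -> np.ndarray:
    """(L, 20) residue frequencies per column; gaps contribute zero weight."""
    L = len(rows[0])
    counts = np.zeros((L, 20))
    for r in rows:
        for j, c in enumerate(r):
            if c != GAP:
                counts[j, AA_INDEX[c]] += 1
    return counts / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two profiles (Gotoh, row-vectorized)."""
    fa, fb = _freqs(rows_a), _freqs(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    s = fa @ _S @ fb.T  # (la, lb) expected column scores

    M = np.full((la + 1, lb + 1), _NEG)
    E = np.full((la + 1, lb + 1), _NEG)  # gap in A (consume B)
    F = np.full((la + 1, lb + 1), _NEG)  # gap in B (consume A)
    M[0, 0] = 0.0
    j = np.arange(1, lb + 1)
    E[0, 1:] = -_GAP_OPEN - _GAP_EXT * (j - 1)
    i_arr = np.arange(1, la + 1)
    F[1:, 0] = -_GAP_OPEN - _GAP_EXT * (i_arr - 1)

    Hprev = np.maximum.reduce([M[0], E[0], F[0]])
    for i in range(1, la + 1):
        M[i, 1:] = s[i - 1, :] + Hprev[:-1]
        F[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] - _GAP_OPEN, E[i - 1, 1:] - _GAP_OPEN, F[i - 1, 1:] - _GAP_EXT]
        )
        A = np.maximum(M[i], F[i])
        A[0] = F[i, 0]
        run = np.maximum.accumulate(A + np.arange(lb + 1))
        E[i, 1:] = run[:-1] - (_GAP_OPEN - _GAP_EXT) - _GAP_EXT * np.arange(1, lb + 1)
        Hprev = np.maximum.reduce([M[i], E[i], F[i]])

    # traceback (prefer diagonal, then gap-in-B, then gap-in-A on ties)
    i, jj = la, lb
    state = int(np.argmax([M[i, jj], F[i, jj], E[i, jj]]))  # 0=M, 1=F, 2=E
    cols: list[tuple[bool, bool]] = []  # (consume A, consume B)
    eps = 1e-9
    while i > 0 or jj > 0:
        if i == 0:
            cols.append((False, True)); jj -= 1; continue
        if jj == 0:
            cols.append((True, False)); i -= 1; continue
        if state == 0:  # M
            cols.append((True, True))
            i, jj = i - 1, jj - 1
            state = int(np.argmax([M[i, jj], F[i, jj], E[i, jj]]))
        elif state == 1:  # F: consumed A column
            cols.append((True, False))
            prev = F[i, jj]
            i -= 1
            if abs(M[i, jj] - _GAP_OPEN - prev) < eps:
                state = 0
            elif abs(F[i, jj] - _GAP_EXT - prev) < eps:
                state = 1
            else:
                state = 2
        else:  # E: consumed B column
            cols.append((False, True))
            prev = E[i, jj]
            jj -= 1
            if abs(M[i, jj] - _GAP_OPEN - prev) < eps:
                state = 0
            elif abs(F[i, jj] - _GAP_OPEN - prev) < eps:
                state = 1
            else:
                state = 2
    cols.reverse()

    def expand(rows: list[str], take_flags: list[bool]) -> list[str]:
        out = [[] for _ in rows]
        pos = 0
        for take in take_flags:
            if take:
                for k, r in enumerate(rows):
                    out[k].append(r[pos])
                pos += 1
            else:
                for o in out:
                    o.append(GAP)
        return ["".join(o) for o in out]

    new_a = expand(rows_a, [a for a, _ in cols])
    new_b = expand(rows_b, [b for _, b in cols])
    return new_a, new_b


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [{s[i : i + k] for i in range(max(len(s) - k + 1, 1))} for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            d[i, j] = d[j, i] = 1.0 - len(sets[i] & sets[j]) / denom
    return d


def progressive_msa(seqs: dict[str, str] | list[tuple[str, str]]) -> MSA:
    """Align protein sequences progressively along a k-mer guide tree.

    Deterministic for a fixed input order. A single sequence is returned as
    a one-row alignment with a warning.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences to align")
    if len(items) == 1:
        warnings.warn("single sequence: returning a one-row alignment")
        return MSA([items[0][0]], [items[0][1]])

    ids = [i for i, _ in items]
    sequences = [s for _, s in items]
    d = _kmer_distance(sequences)
    Z = linkage(squareform(d, checks=False), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [sequences[i]]) for i in range(len(items))
    }
    nxt = len(items)
    for a, b, _, _ in Z:
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _align_profiles(rows_a, rows_b)
        clusters[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (final_ids, final_rows), = clusters.values()
    order = [final_ids.index(i) for i in ids]
    return MSA(ids, [final_rows[k] for k in order])


def trim_msa(
    msa: MSA,
    domain_window: tuple[int, int] | None = None,
    max_gap_frac: float = 0.95,
    min_len: int = 0,
    ref_id: str | None = None,
) -> tuple[MSA, list[str]]:
    """Trim a family alignment before profile construction.

    Sequences whose ungapped length is below ``min_len`` are excluded first
    and reported. ``domain_window`` is a 1-based inclusive interval in
    *reference-sequence residue coordinates* (default reference: first row);
    columns outside it are dropped. Columns whose gap fraction is strictly
    greater than ``max_gap_frac`` are then removed, so a column at exactly
    the threshold is retained.
    """
    excluded = [i for i, r in zip(msa.ids, msa.rows)
                if len(r.replace(GAP, "")) < min_len]
    keep_rows = [(i, r) for i, r in zip(msa.ids, msa.rows) if i not in set(excluded)]
    if not keep_rows:
        raise ValueError("all sequences excluded by the length filter")
    ids = [i for i, _ in keep_rows]
    rows = [r for _, r in keep_rows]
    ncols = len(rows[0])
    col_keep = np.ones(ncols, dtype=bool)

    if domain_window is not None:
        ref = rows[ids.index(ref_id)] if ref_id else rows[0]
        start, end = domain_window
        res_pos = 0
        col_of: dict[int, int] = {}
        for j, c in enumerate(ref):
            if c != GAP:
                res_pos += 1
                col_of[res_pos] = j
        if start < 1 or end > res_pos or start > end:
            raise ValueError(
                f"domain window {start}..{end} outside reference length {res_pos}"
            )
        window = np.zeros(ncols, dtype=bool)
        window[col_of[start] : col_of[end] + 1] = True
        col_keep &= window

    arr = np.array([list(r) for r in rows])
    gap_frac = (arr == GAP).mean(axis=0)
    col_keep &= ~(gap_frac > max_gap_frac)
    if not col_keep.any():
        raise ValueError("no alignment columns remain after trimming")
    trimmed = ["".join(np.array(list(r))[col_keep]) for r in rows]
    return MSA(ids, trimmed), excluded


def consensus(msa: MSA) -> str:
    """Majority residue per column (gap-majority columns omitted);
    ties broken by alphabetical residue order."""
    out = []
    for j in range(msa.ncols):
        col = msa.column(j)
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        residues = {c: n for c, n in counts.items() if c != GAP}
        if not residues:
            continue
        top = max(residues.values())
        if counts.get(GAP, 0) > top:
            continue
        out.append(sorted(c for c, n in residues.items() if n == top)[0])
    return "".join(out)
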