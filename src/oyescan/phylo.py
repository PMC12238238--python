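"""Distance trees, anchor-defined clades, residue frequencies, and Fitch
ancestral states.

Tree inference is classic neighbor joining over Poisson-corrected protein
distances. Clades are delineated by anchors: after rooting on the outgroup
edge, each label's clade is the smallest rooted clade containing all of its
anchor leaves; every other leaf inherits the label of the unique clade it
falls in, or stays "unassigned". Ancestral residues at positions of
interest are reconstructed with two-pass Fitch parsimony (the reported sets
are the preliminary bottom-up sets, which at the root are exactly the
states attainable in some most-parsimonious reconstruction; the score is
the number of union events = parsimony length).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .msa import MSA
from .seqs import GAP

D_MAX = 5.0  # distance cap for saturated pairs


class Node:
    """Minimal rooted-tree node (children + branch length to parent)."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["Node"] | None = None):
        self.name = name
        self.length = length
        self.children = children or []
        self.parent: Node | None = None
        for c in self.children:
            c.parent = self

    def add(self, child: "Node"):
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.leaves()}

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.6f}"
            inner = ",".join(fmt(c) for c in n.children)
            label = n.name or ""
            return f"({inner}){label}:{n.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner}){self.name or ''};"

    def find(self, name: str) -> "Node":
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Distances


def msa_distances(msa: MSA) -> tuple[np.ndarray, list[str]]:
    """Poisson-corrected pairwise distances d = −ln(1−p), capped at D_MAX.

    p is the fraction of mismatches over columns where both rows have a
    residue; pairs with no comparable columns get the cap.
    """
    arr = np.array([list(r) for r in msa.rows])
    n = len(msa.ids)
    d = np.zeros((n, n))
    res = arr != GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = res[i] & res[j]
            m = both.sum()
            if m == 0:
                dij = D_MAX
            else:
                p = (arr[i, both] != arr[j, both]).mean()
                dij = D_MAX if p >= 1 - np.exp(-D_MAX) else -np.log1p(-p)
            d[i, j] = d[j, i] = min(dij, D_MAX)
    return d, list(msa.ids)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: np.ndarray, ids: list[str]) -> Node:
    """Standard neighbor joining; returns a binary tree whose root splits
    the final join edge in half (topologically unrooted).

    Ties in the Q criterion break at the lowest (row, column) index pair.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(ids):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least three taxa")

    nodes = [Node(name) for name in ids]
    D = dist.copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j), i<j, among minimal Q
        iu = np.triu_indices(m, k=1)
        qf = Q[iu]
        k = int(np.argmin(qf))  # argmin returns first = row-major lowest pair
        i, j = int(iu[0][k]), int(iu[1][k])

        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        a, b = nodes[i], nodes[j]
        a.length, b.length = float(li), float(lj)
        new = Node(children=[a, b])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k2 for k2 in range(m) if k2 not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k2] for k2 in keep] + [new]

    a, b = nodes
    # the last-created node is internal; make it the (trifurcating) root and
    # hang the remaining node off it with the full joining edge length
    root, other = (b, a) if b.children else (a, b)
    other.length = float(max(D[0, 1], 0.0))
    root.add(other)
    root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# Rooting and clade assignment


def _unrooted_adjacency(root: Node):
    """Adjacency with the (degree-2) root suppressed."""
    adj: dict[Node, list[tuple[Node, float]]] = {}

    def connect(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    for n in root.postorder():
        for c in n.children:
            if n is root:
                continue
            connect(n, c, c.length)
    if len(root.children) == 2:
        u, v = root.children
        connect(u, v, u.length + v.length)
    else:
        for c in root.children:
            connect(root, c, c.length)
    return adj


def root_on_outgroup(tree: Node, outgroup: set[str]) -> Node:
    """Reroot the (effectively unrooted) tree on the edge separating the
    outgroup leaves from everything else."""
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    all_leaves = tree.leaf_names()
    missing = outgroup - all_leaves
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    adj = _unrooted_adjacency(tree)

    # orient from an arbitrary non-outgroup leaf and find the split edge
    start = next(n for n in adj if n.is_leaf and n.name not in outgroup)
    side: dict[tuple[int, int], set[str]] = {}

    def down_leaves(u: Node, parent: Node | None) -> set[str]:
        if u.is_leaf and all(v is parent for v, _ in adj[u]):
            s = {u.name}
        else:
            s = set()
            if u.is_leaf:
                s.add(u.name)
            for v, _ in adj[u]:
                if v is not parent:
                    s |= down_leaves(v, u)
        side[(id(parent), id(u))] = s
        return s

    down_leaves(start, None)

    target_edge = None
    for (pid, _uid), leafset in side.items():
        if pid == id(None):
            continue
        if leafset == outgroup:
            target_edge = _uid
            break
    if target_edge is None:
        raise ValueError("outgroup is not monophyletic on the unrooted tree")

    # find the actual node pair for the chosen directed edge
    pair = None
    for u in adj:
        for v, w in adj[u]:
            if id(v) == target_edge and side.get((id(u), id(v))) == outgroup:
                pair = (u, v, w)
                break
        if pair:
            break
    og_side, other_side, w = pair[1], pair[0], pair[2]

    # rebuild a rooted tree from the midpoint of that edge
    def build(u: Node, parent: Node, length: float) -> Node:
        kids = [build(v, u, wv) for v, wv in adj[u] if v is not parent]
        n = Node(u.name if u.is_leaf else None, length, kids)
        return n

    left = build(og_side, other_side, w / 2)
    right = build(other_side, og_side, w / 2)
    return Node(children=[left, right])


@dataclasses.dataclass
class CladeTree:
    """Rooted tree plus per-leaf clade labels ('unassigned' where no unique
    labeled clade contains the leaf)."""

    tree: Node
    labels: dict[str, str]
    anchors: dict[str, set[str]]
    outgroup: set[str]

    def members(self, label: str) -> set[str]:
        return {leaf for leaf, lab in self.labels.items() if lab == label}


def assign_clades(
    tree: Node, anchors: dict[str, set[str]], outgroup: set[str]
) -> CladeTree:
    """Root on the outgroup edge and label leaves by anchor-defined clades.

    Each label's clade is the smallest rooted clade (MRCA subtree)
    containing all of its anchors; a leaf inside exactly one labeled clade
    inherits that label, anchors always retain their own label, and leaves
    in nested/overlapping claims or outside every clade are "unassigned".
    """
    for label, aset in anchors.items():
        if not aset:
            raise ValueError(f"anchor set for {label!r} is empty")
        if aset & outgroup:
            raise ValueError(f"anchors of {label!r} overlap the outgroup")
    rooted = root_on_outgroup(tree, outgroup)

    node_of = {n.name: n for n in rooted.postorder() if n.is_leaf}
    missing = {a for s in anchors.values() for a in s} - set(node_of)
    if missing:
        raise ValueError(f"anchor leaves not in tree: {sorted(missing)}")

    def mrca(names: set[str]) -> Node:
        paths = []
        for name in names:
            path = []
            n = node_of[name]
            while n is not None:
                path.append(n)
                n = n.parent
            paths.append(path[::-1])
        out = None
        for level in zip(*paths):
            if all(x is level[0] for x in level):
                out = level[0]
            else:
                break
        return out

    clade_leaves: dict[str, set[str]] = {}
    for label, aset in anchors.items():
        top = mrca(aset)
        if top is rooted:
            raise ValueError(
                f"anchors of {label!r} are not monophyletic under this rooting"
            )
        clade_leaves[label] = top.leaf_names()

    labels: dict[str, str] = {}
    for leaf in rooted.leaf_names():
        claims = [lab for lab, s in clade_leaves.items() if leaf in s]
        anchor_of = [lab for lab, s in anchors.items() if leaf in s]
        if anchor_of:
            labels[leaf] = anchor_of[0]
        elif len(claims) == 1:
            labels[leaf] = claims[0]
        else:
            labels[leaf] = "unassigned"
    for leaf in outgroup:
        labels[leaf] = "outgroup"
    return CladeTree(rooted, labels, anchors, set(outgroup))


# ---------------------------------------------------------------------------
# Residue maps and per-clade column frequencies


@dataclasses.dataclass
class ResidueMap:
    """Positions of interest in reference-residue numbering plus their
    alignment columns (0-based), resolved against an MSA."""

    ref_id: str
    positions: list[int]
    columns: list[int]

    @classmethod
    def from_msa(cls, msa: MSA, ref_id: str, positions: list[int]) -> "ResidueMap":
        if sorted(positions) != list(positions) or len(set(positions)) != len(positions):
            raise ValueError("positions must be strictly increasing")
        ref = msa.row(ref_id)
        col_of: dict[int, int] = {}
        pos = 0
        for j, c in enumerate(ref):
            if c != GAP:
                pos += 1
                col_of[pos] = j
        try:
            cols = [col_of[p] for p in positions]
        except KeyError as exc:
            raise ValueError(f"reference position {exc} beyond reference length") from exc
        return cls(ref_id, list(positions), cols)


ALPHABET21 = "ACDEFGHIKLMNPQRSTVWY-"


def column_frequencies(
    msa: MSA, rmap: ResidueMap, labels: dict[str, str]
) -> dict[str, dict[int, np.ndarray]]:
    """Per-clade, per-position residue+gap frequency vectors (length 21).

    Leaves labeled "unassigned" or "outgroup" are excluded. Raises if a
    clade label has no member sequences in the MSA.
    """
    clades = sorted({v for v in labels.values() if v not in ("unassigned", "outgroup")})
    out: dict[str, dict[int, np.ndarray]] = {}
    idx21 = {c: i for i, c in enumerate(ALPHABET21)}
    for clade in clades:
        member_rows = [
            msa.rows[i] for i, sid in enumerate(msa.ids) if labels.get(sid) == clade
        ]
        if not member_rows:
            raise ValueError(f"clade {clade!r} has no sequences in the alignment")
        out[clade] = {}
        for pos, col in zip(rmap.positions, rmap.columns):
            vec = np.zeros(21)
            for r in member_rows:
                vec[idx21[r[col]]] += 1
            out[clade][pos] = vec / vec.sum()
    return out


# ---------------------------------------------------------------------------
# Fitch parsimony


@dataclasses.dataclass
class FitchResult:
    node_sets: list[list[frozenset]]  # per internal node (postorder), per column
    internal_nodes: list[Node]
    scores: list[int]  # union events per column


def fitch_ancestral(tree: Node, characters: dict[str, str]) -> FitchResult:
    """Two-pass Fitch parsimony over one or more character columns.

    ``characters`` maps each leaf name to its state string (one character
    per column; '-' is an ordinary 21st state). Returns the preliminary
    state sets of every internal node in postorder plus the per-column
    parsimony score (number of union events).
    """
    leaves = tree.leaf_names()
    missing = leaves - set(characters)
    if missing:
        raise ValueError(f"missing leaf states for: {sorted(missing)}")
    ncols = len(next(iter(characters.values())))
    if any(len(v) != ncols for v in characters.values()):
        raise ValueError("all leaves must have the same number of columns")

    internal = [n for n in tree.postorder() if not n.is_leaf]
    sets: dict[int, list[frozenset]] = {}
    scores = [0] * ncols
    for n in tree.postorder():
        if n.is_leaf:
            sets[id(n)] = [frozenset(characters[n.name][c]) for c in range(ncols)]
            continue
        merged = []
        for c in range(ncols):
            child_sets = [sets[id(ch)][c] for ch in n.children]
            inter = frozenset.intersection(*child_sets)
            if inter:
                merged.append(inter)
            else:
                merged.append(frozenset.union(*child_sets))
                scores[c] += len(child_sets) - 1 if len(child_sets) > 2 else 1
        sets[id(n)] = merged
    return FitchResult([sets[id(n)] for n in internal], internal, scores)


# ---------------------------------------------------------------------------
# Robinson–Foulds (split-based, unrooted)


def _splits(tree: Node) -> set[frozenset]:
    all_leaves = frozenset(tree.leaf_names())
    out = set()
    for n in tree.postorder():
        if n.is_leaf or n.parent is None:
            continue
        s = frozenset(n.leaf_names())
        comp = all_leaves - s
        if len(s) > 1 and len(comp) > 1:
            out.add(min(s, comp, key=sorted))
    return out


def robinson_foulds(a: Node, b: Node) -> int:
    """Unrooted RF distance: symmetric difference of nontrivial splits."""
    if a.leaf_names() != b.leaf_names():
        raise ValueError("trees have different leaf sets")
    sa, sb = _splits(a), _splits(b)
    return len(sa ^ sb)


def random_additive_tree(rng: np.random.Generator, n_leaves: int,
                         min_bl: float = 0.05, max_bl: float = 1.0) -> Node:
    """Random binary tree with i.i.d. uniform branch lengths (for testing
    distance-based reconstruction on additive data)."""
    nodes = [Node(f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(min_bl, max_bl))
        b.length = float(rng.uniform(min_bl, max_bl))
        rest = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes = rest + [Node(children=[b, a])]
    a, b = nodes
    a.length = float(rng.uniform(min_bl, max_bl))
    b.length = float(rng.uniform(min_bl, max_bl))
    return Node(children=[a, b])


def tree_distances(tree: Node) -> tuple[np.ndarray, list[str]]:
    """Leaf-to-leaf path-length (additive) distance matrix."""
    leaves = sorted(tree.leaves(), key=lambda n: n.name)
    names = [n.name for n in leaves]
    idx = {id(n): i for i, n in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))
    # distances via per-leaf path to root
    def path(n_: Node):
        out = []
        while n_ is not None:
            out.append(n_)
            n_ = n_.parent
        return out

    paths = {id(l): path(l) for l in leaves}
    for a, b in itertools.combinations(leaves, 2):
        pa = paths[id(a)]
        pb_ids = {id(x) for x in paths[id(b)]}
        lca = next(x for x in pa if id(x) in pb_ids)
        da = 0.0
        for x in pa:
            if x is lca:
                break
            da += x.length
        db = 0.0
        for x in paths[id(b)]:
            if x is lca:
                break
            db += x.length
        D[idx[id(a)], idx[id(b)]] = D[idx[id(b)], idx[id(a)]] = da + db
    return D, names
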