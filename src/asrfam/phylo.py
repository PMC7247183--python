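"""Progressive multiple alignment, distances, neighbor-joining, bootstrap.

The NJ implementation follows Saitou-Nei with the standard Q criterion;
ties are broken by the smallest (i, j) index pair and negative branch
estimates are clamped to zero (and counted), so runs are reproducible.
Distances support p, Poisson-corrected, and maximum-likelihood scalar time
under the JTT model. Bootstrap supports are bipartition frequencies over
column-resampled replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import jtt
from .homology import SubstitutionMatrix, _affine_dp, _traceback
from .seqio import SequenceRecord

__all__ = [
    "MSA",
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "progressive_align",
    "compute_distances",
    "nj_tree",
    "bootstrap_supports",
    "extract_groups",
    "GroupAssignment",
]


@dataclass
class MSA:
    records: list[SequenceRecord]

    def __post_init__(self):
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues)

    def degapped(self, i: int) -> str:
        return self.records[i].residues.replace("-", "")

    def column_sample(self, indices) -> "MSA":
        rows = []
        for r in self.records:
            rows.append(
                SequenceRecord(
                    r.id, "".join(r.residues[j] for j in indices), r.alphabet
                )
            )
        return MSA(rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    model: str = "p"
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


class TreeNode:
    """Node of an unrooted NJ tree, represented rooted at the final join."""

    __slots__ = ("name", "children", "length", "support", "edge_id")

    def __init__(self, name=None, children=None, length=0.0):
        self.name = name
        self.children = children or []
        self.length = length
        self.support = None
        self.edge_id = None

    def is_leaf(self) -> bool:
        return not self.children

    def __iter__(self):
        yield self
        for child in self.children:
            yield from child


@dataclass
class Tree:
    root: TreeNode
    clamped_edges: int = 0

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> list[TreeNode]:
        """Child nodes of internal edges (edges to non-leaf, non-root nodes)."""
        return [n for n in self.root if not n.is_leaf() and n is not self.root]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Map from the leaf set on the child side of each internal edge."""
        out = {}
        for node in self.internal_edges():
            side = frozenset(leaf.name for leaf in node if leaf.is_leaf())
            out[side] = node
        return out

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Path-length metric between all leaf pairs."""
        import networkx as nx

        g = self._graph()
        leaves = self.leaves()
        names = [l.name for l in leaves]
        n = len(leaves)
        d = np.zeros((n, n))
        lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = lengths[id(leaves[i])][id(leaves[j])]
        return DistanceMatrix(names, d, model="tree_metric")

    def _graph(self):
        import networkx as nx

        g = nx.Graph()
        for node in self.root:
            g.add_node(id(node), obj=node)
            for child in node.children:
                g.add_edge(id(node), id(child), weight=child.length, obj=child)
        return g

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def ascii_sketch(self) -> str:
        lines = []

        def walk(node, prefix):
            label = node.name or (f"{node.support:g}" if node.support is not None else "*")
            lines.append(f"{prefix}+- {label} ({node.length:.3g})")
            for c in node.children:
                walk(c, prefix + "   ")

        walk(self.root, "")
        return "\n".join(lines)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a distance matrix.

    Additive matrices are reproduced exactly (the tree metric equals the
    input). Joins with tied Q values pick the smallest (i, j) pair.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    d = dm.d.astype(float).copy()
    active = list(range(n))
    clamped = 0
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            lj, clamped = 0.0, clamped + 1
        nodes[i].length, nodes[j].length = li, lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        # grow matrix with the new node's distances
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, l in ((i, li), (j, lj), (k, lk)):
        if l < 0:
            l, clamped = 0.0, clamped + 1
        nodes[idx].length = l
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    tree = Tree(root, clamped_edges=clamped)
    for eid, node in enumerate(tree.internal_edges()):
        node.edge_id = eid
    return tree


def _encode_msa(msa: MSA) -> np.ndarray:
    idx = {ch: k for k, ch in enumerate(jtt.AA_ORDER)}
    arr = np.full((len(msa.records), msa.n_cols), -1, dtype=np.int8)
    for i, r in enumerate(msa.records):
        for j, c in enumerate(r.residues.upper()):
            arr[i, j] = idx.get(c, -1)
    return arr


def _jtt_ml_distance(counts: np.ndarray) -> float:
    """ML scalar time for a pairwise substitution count matrix under JTT."""
    from scipy.optimize import minimize_scalar

    logpi = np.log(jtt.FREQUENCIES)

    def neg_loglik(t):
        p = jtt.transition_matrix(t)
        return -float(np.sum(counts * (logpi[:, None] + np.log(p))))

    res = minimize_scalar(neg_loglik, bounds=(1e-8, 20.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def compute_distances(msa: MSA, model: str = "p") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap-containing columns."""
    if model not in ("p", "poisson", "jtt_ml"):
        raise ValueError(f"unknown model {model!r}")
    enc = _encode_msa(msa)
    n = enc.shape[0]
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = (enc[i] >= 0) & (enc[j] >= 0)
            comparable = int(mask.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns for pair ({msa.ids[i]}, {msa.ids[j]})"
                )
            diffs = int((enc[i][mask] != enc[j][mask]).sum())
            p = diffs / comparable
            if model == "p":
                dij = p
            elif model == "poisson":
                if p >= 1.0:
                    saturated.append((msa.ids[i], msa.ids[j]))
                    dij = np.inf
                else:
                    dij = -math.log(1.0 - p)
            else:
                counts = np.zeros((20, 20))
                ei, ej = enc[i][mask], enc[j][mask]
                np.add.at(counts, (ei, ej), 0.5)
                np.add.at(counts, (ej, ei), 0.5)
                dij = _jtt_ml_distance(counts)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(msa.ids), d, model, saturated)


# ---------------------------------------------------------------------------
# progressive alignment


def _kmer_distance_matrix(seqs: list[SequenceRecord], k: int = 3) -> DistanceMatrix:
    sets = [
        {s.residues[i : i + k].upper() for i in range(max(1, len(s.residues) - k + 1))}
        for s in seqs
    ]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = len(sets[i] & sets[j])
            d[i, j] = d[j, i] = 1.0 - common / max(1, min(len(sets[i]), len(sets[j])))
    return DistanceMatrix([s.id for s in seqs], d, model="kmer")


class _Profile:
    """Rows of an in-progress alignment plus per-column frequency counts."""

    def __init__(self, ids, rows, alphabet_index):
        self.ids = ids
        self.rows = rows
        self._aidx = alphabet_index
        L = len(rows[0])
        self.freq = np.zeros((L, len(alphabet_index)))
        self.nongap = np.zeros(L)
        for row in rows:
            for j, c in enumerate(row.upper()):
                if c in alphabet_index:
                    self.freq[j, alphabet_index[c]] += 1.0
                    self.nongap[j] += 1.0


def _merge_profiles(pa: _Profile, pb: _Profile, scores, gap_open, gap_extend, aidx):
    denom = np.outer(np.maximum(pa.nongap, 1.0), np.maximum(pb.nongap, 1.0))
    sub = (pa.freq @ scores @ pb.freq.T) / denom
    M, Ix, Iy = _affine_dp(sub, gap_open, gap_extend, local=False)
    _, path = _traceback(M, Ix, Iy, sub, gap_open, gap_extend, local=False)
    rows_a = [[] for _ in pa.rows]
    rows_b = [[] for _ in pb.rows]
    for i, j, state in path:
        if state == "M":
            for r, row in zip(rows_a, pa.rows):
                r.append(row[i - 1])
            for r, row in zip(rows_b, pb.rows):
                r.append(row[j - 1])
        elif state == "Ix":
            for r, row in zip(rows_a, pa.rows):
                r.append(row[i - 1])
            for r in rows_b:
                r.append("-")
        else:
            for r in rows_a:
                r.append("-")
            for r, row in zip(rows_b, pb.rows):
                r.append(row[j - 1])
    return _Profile(
        pa.ids + pb.ids,
        ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b],
        aidx,
    )


def progressive_align(
    seqs: list[SequenceRecord],
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> MSA:
    """Guide-tree (3-mer distance + NJ) progressive multiple alignment."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    aidx = {ch: k for k, ch in enumerate(matrix.alphabet)}
    scores = matrix.scores

    def leaf_profile(s: SequenceRecord) -> _Profile:
        return _Profile([s.id], [s.residues], aidx)

    by_id = {s.id: s for s in seqs}
    if len(seqs) == 2:
        merged = _merge_profiles(
            leaf_profile(seqs[0]), leaf_profile(seqs[1]), scores, gap_open, gap_extend, aidx
        )
    else:
        guide = nj_tree(_kmer_distance_matrix(seqs))

        def build(node) -> _Profile:
            if node.is_leaf():
                return leaf_profile(by_id[node.name])
            prof = build(node.children[0])
            for child in node.children[1:]:
                prof = _merge_profiles(prof, build(child), scores, gap_open, gap_extend, aidx)
            return prof

        merged = build(guide.root)
    rows = dict(zip(merged.ids, merged.rows))
    aligned = [SequenceRecord(s.id, rows[s.id], s.alphabet) for s in seqs]
    msa = MSA(aligned)
    for i, s in enumerate(seqs):
        if msa.degapped(i) != s.residues:
            raise AssertionError(f"alignment altered residues of {s.id}")
    return msa


def bootstrap_supports(
    msa: MSA,
    n_reps: int = 1000,
    seed: int | None = None,
    model: str = "p",
) -> Tree:
    """NJ tree with bootstrap supports from column resampling.

    Support on each internal edge is the percentage of replicate trees
    containing the same leaf bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = nj_tree(compute_distances(msa, model))
    target = tree.bipartitions()
    all_leaves = frozenset(msa.ids)
    counts = {side: 0 for side in target}
    L = msa.n_cols
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_msa = msa.column_sample(idx)
        try:
            rep_tree = nj_tree(compute_distances(rep_msa, model))
        except ValueError:
            continue  # replicate without comparable columns for some pair
        rep_bips = set()
        for side in rep_tree.bipartitions():
            rep_bips.add(side)
            rep_bips.add(all_leaves - side)
        for side in counts:
            if side in rep_bips:
                counts[side] += 1
    for side, node in target.items():
        node.support = 100.0 * counts[side] / n_reps
    return tree


@dataclass
class GroupAssignment:
    groups: dict[str, str]  # gene_id -> group label
    method: str

    def members(self, label: str) -> list[str]:
        return sorted(g for g, l in self.groups.items() if l == label)

    def partition(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, l in self.groups.items():
            out.setdefault(l, []).append(g)
        return {l: sorted(v) for l, v in out.items()}


def extract_groups(tree: Tree, k=None, reference: dict[str, str] | None = None) -> GroupAssignment:
    """Partition leaves into groups.

    ``k`` mode removes the k-1 longest internal edges (ties by edge id),
    yielding k clades. ``reference`` mode assigns each leaf the group of its
    nearest labeled reference leaf by path length.
    """
    import networkx as nx

    leaves = tree.leaves()
    if reference is not None:
        dm = tree.leaf_distance_matrix()
        pos = {n: i for i, n in enumerate(dm.ids)}
        groups = {}
        for leaf in dm.ids:
            ref = min(
                reference,
                key=lambda r: (dm.d[pos[leaf], pos[r]], r),
            )
            groups[leaf] = reference[ref]
        return GroupAssignment(groups, "reference_clades")
    if k is None:
        raise ValueError("either k or reference must be given")
    if k < 1 or k > len(leaves):
        raise ValueError(f"k={k} outside [1, n_leaves]")
    internal = tree.internal_edges()
    if k - 1 > len(internal):
        raise ValueError(f"tree has only {len(internal)} internal edges; cannot cut {k - 1}")
    to_cut = sorted(internal, key=lambda n: (-n.length, n.edge_id))[: k - 1]
    g = tree._graph()
    parent = {}
    for node in tree.root:
        for child in node.children:
            parent[id(child)] = id(node)
    for node in to_cut:
        g.remove_edge(id(node), parent[id(node)])
    groups = {}
    for gi, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: min(
        (n.name for cid in c for n in [g.nodes[cid]["obj"]] if n.is_leaf()), default="~"
    ))):
        label = f"group_{gi + 1}"
        for cid in comp:
            node = g.nodes[cid]["obj"]
            if node.is_leaf():
                groups[node.name] = label
    return GroupAssignment(groups, "cut_k")
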