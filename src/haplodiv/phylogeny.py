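"""Haplotype phylogenies: F84 distances, neighbor-joining, bootstrap,
outgroup rooting and topology-pattern classification.

Haplotype sequences are built from the variant sites of a locus (the usual
VCF-derived alignment), distances use the F84 substitution model with
distinct transition/transversion rates, trees are neighbor-joining
(Saitou & Nei) with deterministic tie-breaks, and supports come from site
bootstrap.  Rooted trees are classified into a compact topology-pattern
vocabulary: maximal clusters are lettered A (African only), E (Eurasian,
i.e. non-African modern, only), C (cosmopolitan / multi-continental),
N (Neanderthal), D (Denisovan), and the nesting is emitted as a
Newick-like pattern string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .core import (
    ARCHAIC_GROUPS,
    GROUP_AFRICAN,
    GROUP_DENISOVAN,
    GROUP_NEANDERTHAL,
    GROUP_OUTGROUP,
    MISSING,
    HaplodivError,
    HaplotypeMatrix,
    group_of,
)

__all__ = [
    "TreeNode",
    "SequenceRecord",
    "TopologyPattern",
    "haplotypes_to_sequences",
    "f84_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "root_with_outgroup",
    "collapse_low_support",
    "classify_topology",
    "encode_sequence",
    "SATURATED",
]

#: Sentinel distance for saturated pairs.
SATURATED = float("inf")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_PURINES = frozenset("AG")


# ----------------------------------------------------------------------
# tree structure
# ----------------------------------------------------------------------
class TreeNode:
    """Node of a (possibly unrooted, possibly multifurcating) tree.

    ``length`` is the branch above the node; ``support`` (0..100) annotates
    the edge above internal nodes.
    """

    __slots__ = ("name", "children", "parent", "length", "support")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: float | None = None):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.support = support

    # -- construction ---------------------------------------------------
    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    # -- traversal ------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> "TreeNode | None":
        for n in self.walk():
            if n.name == name:
                return n
        return None

    # -- output ---------------------------------------------------------
    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            sup = (
                f"{node.support:.0f}"
                if with_support and node.support is not None
                else ""
            )
            return f"({inner}){sup}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.name, self.length, self.support)
        for c in self.children:
            clone.add(c.copy())
        return clone

    # -- metrics --------------------------------------------------------
    def depths(self) -> dict["TreeNode", float]:
        """Root-to-node path lengths."""
        out = {self: 0.0}
        for n in self.walk():
            if n.parent is not None:
                out[n] = out[n.parent] + n.length
        return out

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (order = leaf_names)."""
        leaves = self.leaves()
        names = [l.name for l in leaves]
        depths = self.depths()
        # ancestor sets per leaf
        anc: list[dict[TreeNode, float]] = []
        for leaf in leaves:
            chain = {}
            n = leaf
            while n is not None:
                chain[n] = depths[n]
                n = n.parent
            anc.append(chain)
        m = np.zeros((len(leaves), len(leaves)))
        for i in range(len(leaves)):
            for j in range(i + 1, len(leaves)):
                common = max(
                    (d for n, d in anc[i].items() if n in anc[j]), default=0.0
                )
                m[i, j] = m[j, i] = depths[leaves[i]] + depths[leaves[j]] - 2 * common
        return names, m

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions (as frozensets of leaf names)."""
        all_names = frozenset(self.leaf_names())
        ref = min(all_names)
        out: set[frozenset] = set()
        sides: dict[TreeNode, frozenset] = {}
        for node in reversed(list(self.walk())):  # post-order
            if node.is_leaf:
                sides[node] = frozenset([node.name])
            else:
                sides[node] = frozenset().union(*(sides[c] for c in node.children))
            if node.parent is None:
                continue
            side = sides[node]
            if len(side) < 2 or len(all_names - side) < 2:
                continue
            out.add(side if ref not in side else all_names - side)
        return out


# ----------------------------------------------------------------------
# sequences
# ----------------------------------------------------------------------
@dataclass
class SequenceRecord:
    """One nonredundant haplotype sequence with its multiplicity."""

    id: str
    seq: str
    multiplicity: int = 1
    member_ids: list[str] = field(default_factory=list)


def haplotypes_to_sequences(
    h: HaplotypeMatrix, max_deleted_frac: float = 0.005
) -> list[SequenceRecord]:
    """Nucleotide sequences from the allele matrix, deduplicated.

    Haplotypes whose fraction of deleted/missing sites is ``max_deleted_frac``
    or more are removed; identical sequences collapse into one record keeping
    multiplicity and member haplotype ids.  Alleles map through the site's
    REF (ancestral) / ALT nucleotides; missing alleles become ``N``.
    """
    if h.n_sites == 0:
        raise HaplodivError("cannot build sequences from an empty matrix")
    ref = np.array([b[0] for b in h.ref_alleles])
    alt = np.array([b[0] for b in h.alt_alleles])
    records: dict[str, SequenceRecord] = {}
    for i, hap_id in enumerate(h.hap_ids):
        row = h.alleles[i]
        frac_deleted = np.mean(row == MISSING)
        if frac_deleted >= max_deleted_frac:
            continue
        chars = np.where(row == 1, alt, ref)
        chars[row == MISSING] = "N"
        seq = "".join(chars)
        if seq in records:
            rec = records[seq]
            rec.multiplicity += 1
            rec.member_ids.append(hap_id)
        else:
            records[seq] = SequenceRecord(
                id=hap_id, seq=seq, multiplicity=1, member_ids=[hap_id]
            )
    if not records:
        raise HaplodivError("all haplotypes removed by the deleted-site filter")
    return list(records.values())


# ----------------------------------------------------------------------
# F84 distances
# ----------------------------------------------------------------------
def _f84_params(base_freqs: np.ndarray, ts_tv_ratio: float):
    """F84 (b, K) from base frequencies and the expected ts/tv ratio."""
    pi = np.asarray(base_freqs, dtype=float)
    pi = np.maximum(pi, 1e-9)
    pi = pi / pi.sum()
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    b_term = pa * pg + pc * pt
    a_term = pa * pg / pr + pc * pt / py
    tv_flux = 2 * pr * py
    # ratio = (b_term + K * a_term) / tv_flux  (per unit of the base rate b)
    k = (ts_tv_ratio * tv_flux - 2 * b_term) / (2 * a_term)
    if k < 0:
        warnings.warn(
            "requested ts/tv ratio below the F84 minimum; clamping K to 0",
            stacklevel=3,
        )
        k = 0.0
    # scale b so one unit of t is one expected substitution per site
    rho = np.where([True, False, True, False], pr, py)  # class freq per base
    rate = float(np.sum(pi * ((1 - pi) + k * (1 - pi / rho))))
    return 1.0 / rate, k, pi


def _f84_pmatrix(t: float, b: float, k: float, pi: np.ndarray) -> np.ndarray:
    """Analytic F84 transition probabilities ('three-urn' form)."""
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    rho = np.array([pr, py, pr, py])
    e1 = np.exp(-b * t)
    e2 = np.exp(-b * k * t)
    p = np.tile(pi * (1 - e1), (4, 1))
    # A,G purines (indices 0,2); C,T pyrimidines (1,3)
    purine = np.array([True, False, True, False])
    same_class = purine[:, None] == purine[None, :]
    p += same_class * (pi / rho)[None, :] * e1 * (1 - e2)
    p += np.eye(4) * e1 * e2
    return p


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """4x4 site-pattern counts for two encoded sequences (codes 0..3, <0 = gap)."""
    ok = (a >= 0) & (b >= 0)
    codes = 4 * a[ok] + b[ok]
    return np.bincount(codes, minlength=16).reshape(4, 4).astype(float)


def encode_sequence(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int8)


def f84_distance(
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray,
    ts_tv_ratio: float = 2.0,
    base_freqs: Sequence[float] | None = None,
    method: str = "ml",
    max_distance: float = 50.0,
) -> float:
    """F84 distance between two aligned sequences.

    ``method='ml'`` maximizes the pairwise likelihood over the branch length
    with the transition/transversion ratio fixed (the classic distance-matrix
    program behaviour); ``method='moments'`` is the closed-form estimator from
    transition/transversion proportions (ratio estimated implicitly).  Sites
    with a gap or ambiguous base in either sequence are excluded.  Returns 0
    for identical sequences and ``inf`` (with a warning) on saturation.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    counts = _pair_counts(a, b)
    n = counts.sum()
    if n == 0:
        raise HaplodivError("no jointly observed sites")
    if counts.trace() == n:
        return 0.0
    if base_freqs is None:
        freq = counts.sum(axis=0) + counts.sum(axis=1)
        pi = freq / freq.sum()
    else:
        pi = np.asarray(base_freqs, dtype=float)

    if method == "moments":
        return _f84_moments(counts, pi, max_distance)
    if method != "ml":
        raise ValueError(f"unknown method {method!r}")

    bscale, k, pi = _f84_params(pi, ts_tv_ratio)

    def neg_loglik(t: float) -> float:
        p = _f84_pmatrix(t, bscale, k, pi)
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(pi[:, None] * p, 1e-300))
        return -float(np.sum(counts * lp))

    res = minimize_scalar(
        neg_loglik, bounds=(1e-9, max_distance), method="bounded",
        options={"xatol": 1e-10},
    )
    d = float(res.x)
    if d > 0.98 * max_distance:
        warnings.warn("F84 distance saturated; returning inf", stacklevel=2)
        return SATURATED
    return d


def _f84_moments(counts: np.ndarray, pi: np.ndarray, max_distance: float) -> float:
    n = counts.sum()
    ts = counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1]
    diag = counts.trace()
    tv = n - diag - ts
    p_hat, q_hat = ts / n, tv / n
    pi = np.maximum(pi, 1e-9)
    pi = pi / pi.sum()
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    a = pc * pt / py + pa * pg / pr
    b = pc * pt + pa * pg
    c = pr * py
    x = 1 - p_hat / (2 * a) - (a - b) * q_hat / (2 * a * c)
    y = 1 - q_hat / (2 * c)
    if x <= 0 or y <= 0:
        warnings.warn("F84 distance saturated; returning inf", stacklevel=3)
        return SATURATED
    d = -2 * a * np.log(x) + 2 * (a - b - c) * np.log(y)
    return float(min(max(d, 0.0), max_distance))


def distance_matrix(
    records: Sequence[SequenceRecord],
    ts_tv_ratio: float = 2.0,
    method: str = "moments",
) -> tuple[list[str], np.ndarray]:
    """Pairwise F84 distance matrix over sequence records.

    Uses shared empirical base frequencies; the fast closed-form estimator is
    the default for matrix construction.  Saturated pairs get twice the
    largest finite distance so neighbor-joining stays usable.
    """
    enc = [encode_sequence(r.seq) for r in records]
    labels = [r.id for r in records]
    n = len(records)
    freq = np.zeros(4)
    for e in enc:
        freq += np.bincount(e[e >= 0], minlength=4)
    pi = freq / freq.sum() if freq.sum() else np.full(4, 0.25)
    d = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = f84_distance(
                    enc[i], enc[j], ts_tv_ratio=ts_tv_ratio,
                    base_freqs=pi, method=method,
                )
    if np.isinf(d).any():
        finite_max = np.max(d[np.isfinite(d)], initial=1.0)
        d[np.isinf(d)] = 2.0 * finite_max
    return labels, d


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------
def nj_tree(labels: Sequence[str], d: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaks.

    Q-criterion joins, branch lengths by the standard formulas (negative
    estimates clamped to 0 with the deficit moved to the sister edge), ties
    broken by the lowest index pair.  Returns the unrooted tree as a
    trifurcating root (bifurcating for n = 3 handled the same way).
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape must match labels")
    if n < 3:
        raise HaplodivError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major: first minimum = lowest (i, j)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        ai, aj = active[i], active[j]
        parent = TreeNode()
        nodes[ai].length = vi
        nodes[aj].length = vj
        parent.add(nodes[ai])
        parent.add(nodes[aj])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[ai, active] + d[aj, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        d[new_idx, active] = new_row
        d[active, new_idx] = new_row
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    a, b, c = active
    root = TreeNode()
    nodes[a].length = max(0.0, 0.5 * (d[a, b] + d[a, c] - d[b, c]))
    nodes[b].length = max(0.0, 0.5 * (d[a, b] + d[b, c] - d[a, c]))
    nodes[c].length = max(0.0, 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    for x in (a, b, c):
        root.add(nodes[x])
    return root


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------
def bootstrap_supports(
    records: Sequence[SequenceRecord],
    n_reps: int = 500,
    seed: int = 0,
    ts_tv_ratio: float = 2.0,
    tree: TreeNode | None = None,
) -> TreeNode:
    """Site-bootstrap supports on the NJ tree of the given alignment.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge of the original tree is the percentage of replicate
    NJ trees containing the same leaf bipartition.
    """
    if tree is None:
        labels, d = distance_matrix(records, ts_tv_ratio=ts_tv_ratio)
        tree = nj_tree(labels, d)
    rng = np.random.default_rng(seed)
    enc = np.stack([encode_sequence(r.seq) for r in records])
    ids = [r.id for r in records]
    n_sites = enc.shape[1]
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        enc_s = enc[:, cols]
        labels_r, d_r = _distance_matrix_encoded(enc_s, ids, ts_tv_ratio)
        rep = nj_tree(labels_r, d_r)
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    all_names = frozenset(tree.leaf_names())
    ref = min(all_names)
    for node in tree.walk():
        if node.is_leaf or node.parent is None:
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(all_names - side) < 2:
            continue
        key = side if ref not in side else all_names - side
        node.support = 100.0 * counts.get(key, 0) / n_reps
    return tree


def _distance_matrix_encoded(enc: np.ndarray, ids: Sequence[str], ts_tv_ratio: float):
    n = enc.shape[0]
    freq = np.zeros(4)
    for e in enc:
        freq += np.bincount(e[e >= 0], minlength=4)
    pi = freq / freq.sum() if freq.sum() else np.full(4, 0.25)
    d = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = f84_distance(
                    enc[i], enc[j], base_freqs=pi, method="moments",
                    ts_tv_ratio=ts_tv_ratio,
                )
    if np.isinf(d).any():
        finite_max = np.max(d[np.isfinite(d)], initial=1.0)
        d[np.isinf(d)] = 2.0 * finite_max
    return list(ids), d


# ----------------------------------------------------------------------
# rooting
# ----------------------------------------------------------------------
def _adjacency(root: TreeNode):
    """Undirected adjacency: node -> [(neighbour, length, support)]."""
    adj: dict[TreeNode, list[tuple[TreeNode, float, float | None]]] = {}
    for node in root.walk():
        adj.setdefault(node, [])
        for c in node.children:
            adj[node].append((c, c.length, c.support))
            adj.setdefault(c, []).append((node, c.length, c.support))
    return adj


def root_with_outgroup(tree: TreeNode, outgroup_label: str) -> TreeNode:
    """Root the tree at the midpoint of the outgroup's pendant edge."""
    out_leaf = tree.find(outgroup_label)
    if out_leaf is None:
        raise HaplodivError(f"outgroup {outgroup_label!r} not in tree")
    if out_leaf.parent is None:
        raise HaplodivError("cannot root a single-node tree")
    adj = _adjacency(tree)

    def build(node: TreeNode, came_from: TreeNode | None,
              length: float, support: float | None) -> TreeNode:
        clone = TreeNode(node.name, length, support)
        for nbr, ln, sup in adj[node]:
            if nbr is came_from:
                continue
            clone.add(build(nbr, node, ln, sup))
        return clone

    attach = out_leaf.parent
    pend_len = out_leaf.length
    root = TreeNode()
    root.add(build(out_leaf, attach, pend_len / 2.0, None))
    ingroup = build(attach, out_leaf, pend_len / 2.0, None)
    root.add(_suppress_unary(ingroup))
    return root


def _suppress_unary(node: TreeNode) -> TreeNode:
    """Remove degree-2 internal nodes produced by re-rooting."""
    for c in list(node.children):
        newc = _suppress_unary(c)
        if newc is not c:
            idx = node.children.index(c)
            node.children[idx] = newc
            newc.parent = node
    if len(node.children) == 1 and node.name is None:
        child = node.children[0]
        child.length += node.length
        if node.support is not None and child.support is None:
            child.support = node.support
        child.parent = node.parent
        return child
    return node


def collapse_low_support(tree: TreeNode, min_support: float = 50.0) -> TreeNode:
    """Collapse internal edges with bootstrap support below ``min_support``.

    Nodes without a support value are kept.  Returns a modified copy.
    """
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.walk()):
            if (
                node.parent is not None
                and not node.is_leaf
                and node.support is not None
                and node.support < min_support
            ):
                parent = node.parent
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for c in node.children:
                    c.parent = parent
                    parent.children.append(c)
                changed = True
                break
    return tree


# ----------------------------------------------------------------------
# topology classification
# ----------------------------------------------------------------------
@dataclass
class TopologyPattern:
    """Compact description of a rooted haplotype-tree topology."""

    pattern: str
    typical_ooa: bool
    nd_shared_class: str  # '-', '+', '++'
    pattern_type: str  # FE, Af, Ea, FA, other


def _leaf_letter(groups: set[str]) -> str:
    """Cluster letter for a set of continental groups."""
    if groups == {GROUP_NEANDERTHAL}:
        return "N"
    if groups == {GROUP_DENISOVAN}:
        return "D"
    if groups & set(ARCHAIC_GROUPS):
        return "?"  # mixed archaic/modern: never a single cluster letter
    if groups <= {GROUP_AFRICAN}:
        return "A"
    if GROUP_AFRICAN in groups:
        return "C"
    return "E"


def _normalize_groups(value) -> set[str]:
    if isinstance(value, str):
        return {group_of(value)}
    return {group_of(v) for v in value}


def classify_topology(
    tree: TreeNode,
    leaf_groups: dict[str, Iterable[str] | str],
    grades: dict[str, str] | None = None,
    support_collapse: float = 50.0,
    pattern_rules: Sequence[tuple[str, Callable]] | None = None,
) -> TopologyPattern:
    """Classify a rooted tree into the topology-pattern vocabulary.

    ``leaf_groups`` maps each leaf name to its population code(s) (a
    nonredundant sequence may represent haplotypes from several
    populations); ``grades`` maps leaf names to S* introgression grades
    ('I', 'II' or 'low').  Outgroup leaves are ignored.  Internal edges with
    support below ``support_collapse`` are collapsed first.

    The pattern-type rules (FE / Af / Ea / FA) reconstruct a published
    catalogue that is not available in full; they are supplied as an
    ordered, overridable rule table via ``pattern_rules``.
    """
    grades = grades or {}
    work = collapse_low_support(tree, support_collapse)
    # drop outgroup leaves
    for leaf in list(work.leaves()):
        gs = _normalize_groups(leaf_groups.get(leaf.name, set()))
        if gs == {GROUP_OUTGROUP}:
            parent = leaf.parent
            if parent is not None:
                parent.children.remove(leaf)
    work = _suppress_unary(work)

    def leafset_groups(node: TreeNode) -> set[str]:
        out: set[str] = set()
        for name in node.leaf_names():
            if name not in leaf_groups:
                raise HaplodivError(f"unlabeled leaf {name!r}")
            out |= _normalize_groups(leaf_groups[name])
        return out

    def pattern_of(node: TreeNode) -> str:
        letter = _leaf_letter(leafset_groups(node))
        if node.is_leaf:
            return letter
        if letter in ("A", "E", "N", "D"):
            # collapses only when every leaf maps to the same letter
            leaf_letters = {
                _leaf_letter(_normalize_groups(leaf_groups[n]))
                for n in node.leaf_names()
            }
            if leaf_letters == {letter}:
                return letter
        if letter == "C" and all(c.is_leaf for c in node.children):
            return "C"  # mixed-continent polytomy with no pure substructure
        return "(" + ",".join(pattern_of(c) for c in node.children) + ")"

    pattern = pattern_of(work)

    # --- typical OOA: a non-African-containing subtree whose sibling
    # context is purely African -----------------------------------------
    modern_nonafr = {"EUR", "ASN", "AMR", "UNKNOWN"} - {"UNKNOWN"}
    typical = False
    for node in work.walk():
        if node.parent is None:
            continue
        sib_groups: set[str] = set()
        for sib in node.parent.children:
            if sib is node:
                continue
            sib_groups |= leafset_groups(sib)
        sub = leafset_groups(node)
        if (
            sib_groups
            and sib_groups <= {GROUP_AFRICAN}
            and sub & modern_nonafr
        ):
            typical = True
            break

    # --- Neanderthal-Denisovan sharing ----------------------------------
    nd_class = "-"
    archaic_leaves = [
        l for l in work.leaves()
        if _normalize_groups(leaf_groups[l.name]) & set(ARCHAIC_GROUPS)
    ]
    has_n = any(
        GROUP_NEANDERTHAL in _normalize_groups(leaf_groups[l.name])
        for l in archaic_leaves
    )
    has_d = any(
        GROUP_DENISOVAN in _normalize_groups(leaf_groups[l.name])
        for l in archaic_leaves
    )
    if has_n and has_d:
        mrca = _mrca(work, archaic_leaves)
        if mrca is not None and set(mrca.leaf_names()) <= {
            l.name for l in archaic_leaves
        }:
            sup = mrca.support if mrca.support is not None else 100.0
            if sup >= 99.0:
                nd_class = "++"
            elif sup > 75.0:
                nd_class = "+"

    # --- pattern type ----------------------------------------------------
    def graded(name: str) -> bool:
        return grades.get(name, "low") in ("I", "II")

    def has_graded_nonafrican(node: TreeNode) -> bool:
        for leaf in node.leaves():
            gs = _normalize_groups(leaf_groups[leaf.name])
            if gs & modern_nonafr and graded(leaf.name):
                return True
        return False

    def has_archaic(node: TreeNode) -> bool:
        return any(
            _normalize_groups(leaf_groups[l.name]) & set(ARCHAIC_GROUPS)
            for l in node.leaves()
        )

    def rule_fe(t: TreeNode) -> bool:
        # basal cluster with archaic + graded Eurasian/cosmopolitan members
        return any(
            has_archaic(c) and has_graded_nonafrican(c) for c in t.children
        )

    def rule_af(t: TreeNode) -> bool:
        # archaic haplotypes nested inside an African cluster
        for node in t.walk():
            if node.parent is None or not has_archaic(node):
                continue
            ctx = leafset_groups(node.parent) - set(ARCHAIC_GROUPS)
            if ctx and ctx <= {GROUP_AFRICAN}:
                return True
        return False

    def rule_ea(t: TreeNode) -> bool:
        # basal Eurasian lineage with grades but no archaic member
        return any(
            not has_archaic(c)
            and has_graded_nonafrican(c)
            and not (leafset_groups(c) & {GROUP_AFRICAN})
            for c in t.children
        )

    def rule_fa(t: TreeNode) -> bool:
        return has_archaic(t) and any(graded(n) for n in t.leaf_names())

    rules = pattern_rules or [
        ("FE", rule_fe),
        ("Af", rule_af),
        ("Ea", rule_ea),
        ("FA", rule_fa),
    ]
    ptype = "other"
    for name, rule in rules:
        if rule(work):
            ptype = name
            break

    return TopologyPattern(
        pattern=pattern,
        typical_ooa=typical,
        nd_shared_class=nd_class,
        pattern_type=ptype,
    )


def _mrca(root: TreeNode, leaves: Sequence[TreeNode]) -> TreeNode | None:
    if not leaves:
        return None
    paths = []
    for leaf in leaves:
        chain = []
        n = leaf
        while n is not None:
            chain.append(n)
            n = n.parent
        paths.append(list(reversed(chain)))
    mrca = None
    for nodes in zip(*paths):
        if all(n is nodes[0] for n in nodes):
            mrca = nodes[0]
        else:
            break
    return mrca
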