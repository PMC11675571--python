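"""Representative-OTU selection and reduced median networks.

A large haplotype tree is condensed to a small set of representative OTUs
(one per well-supported cluster, keeping every root-distance outlier), and
the representatives' binary haplotypes are laid out as a reduced median
network: observed haplotypes plus the consensus ("median") vectors needed to
express incompatible site patterns, with edges labelled by the SNP sites
they change.  On fully compatible character sets the network is exactly the
unique perfect phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .core import HaplodivError
from .phylogeny import TreeNode, collapse_low_support

__all__ = [
    "RepresentativeSet",
    "select_representatives",
    "reduced_median_network",
    "annotate_network",
    "write_graphml",
    "write_rdf_table",
]


@dataclass
class RepresentativeSet:
    """Representative OTUs, the clusters they stand for, and outliers."""

    representatives: list[str]
    clusters: dict[str, list[str]]  # representative -> member leaf names
    outliers: list[str] = field(default_factory=list)


def _cluster_nodes(tree: TreeNode, support_collapse: float) -> list[TreeNode]:
    """Initial candidate clusters: children subtrees of the collapsed tree.

    Every maximal subtree hanging off the root spine of the
    support-collapsed tree is one candidate cluster; single leaves count as
    their own cluster.
    """
    work = collapse_low_support(tree, support_collapse)
    out: list[TreeNode] = []

    def descend(node: TreeNode) -> None:
        for c in node.children:
            if c.is_leaf or (c.support is None or c.support >= support_collapse):
                out.append(c)
            else:
                descend(c)

    descend(work)
    return out


def select_representatives(
    tree: TreeNode,
    limit_range: tuple[int, int] = (14, 21),
    support_collapse: float = 50.0,
    outlier_k: float = 2.0,
) -> RepresentativeSet:
    """Choose representative OTUs from a rooted tree.

    Step 1: candidate clusters start at the support-collapsed clusters;
    the candidate whose patristic distance to its nearest remaining
    candidate is smallest is removed repeatedly until at most the upper
    limit remain; each surviving cluster is represented by the member with
    the smallest mean distance to its co-members.  Step 2: any leaf whose
    root distance exceeds mean + ``outlier_k`` * sd over all leaves is added.
    Trees at or below the lower limit are returned whole.
    """
    lower, upper = limit_range
    leaves = tree.leaf_names()
    names, pmat = tree.patristic_distances()
    idx = {n: i for i, n in enumerate(names)}
    depths = tree.depths()
    leaf_depth = {l.name: d for l, d in depths.items() if l.is_leaf}

    if len(leaves) <= lower:
        return RepresentativeSet(
            representatives=list(leaves),
            clusters={l: [l] for l in leaves},
            outliers=[],
        )

    clusters = [set(c.leaf_names()) for c in _cluster_nodes(tree, support_collapse)]
    if not clusters:
        clusters = [set(leaves)]

    def cluster_dist(a: set[str], b: set[str]) -> float:
        return min(pmat[idx[x], idx[y]] for x in a for y in b)

    while len(clusters) > upper:
        best_i, best_d = None, None
        for i, c in enumerate(clusters):
            d = min(
                cluster_dist(c, o) for j, o in enumerate(clusters) if j != i
            )
            if best_d is None or d < best_d:
                best_i, best_d = i, d
        clusters.pop(best_i)

    reps: dict[str, list[str]] = {}
    for c in clusters:
        members = sorted(c)
        if len(members) == 1:
            reps[members[0]] = members
            continue
        mean_d = {
            m: np.mean([pmat[idx[m], idx[o]] for o in members if o != m])
            for m in members
        }
        rep = min(members, key=lambda m: (mean_d[m], m))
        reps[rep] = members

    dvals = np.array([leaf_depth[l] for l in leaves])
    cutoff = dvals.mean() + outlier_k * dvals.std()
    outliers = [l for l in leaves if leaf_depth[l] > cutoff]
    for o in outliers:
        reps.setdefault(o, [o])

    return RepresentativeSet(
        representatives=sorted(reps, key=leaves.index),
        clusters=reps,
        outliers=outliers,
    )


# ----------------------------------------------------------------------
# reduced median network
# ----------------------------------------------------------------------
def _collapse_characters(matrix: np.ndarray, positions: np.ndarray):
    """Group identical (or complemented-identical) informative columns.

    Returns (reduced matrix over character classes, list of position lists,
    class weights).  Invariant columns are dropped.
    """
    classes: dict[bytes, list[int]] = {}
    for s in range(matrix.shape[1]):
        col = matrix[:, s]
        if len(np.unique(col)) < 2:
            continue
        key = col.tobytes()
        alt = (1 - col).tobytes()
        use = key if key in classes or alt not in classes else alt
        classes.setdefault(use, []).append(s)
    if not classes:
        return np.zeros((matrix.shape[0], 0), dtype=np.int8), [], []
    cols = [np.frombuffer(k, dtype=matrix.dtype) for k in classes]
    red = np.stack(cols, axis=1).astype(np.int8)
    pos_lists = [[int(positions[s]) for s in v] for v in classes.values()]
    weights = [len(v) for v in classes.values()]
    return red, pos_lists, weights


def reduced_median_network(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    frequencies: np.ndarray | None = None,
    hap_ids: list[str] | None = None,
    reduction_r: float = 2.0,
) -> nx.Graph:
    """Reduced median network of binary haplotypes.

    ``haplotypes`` is a (n x sites) 0/1 matrix of distinct haplotypes with
    observed ``frequencies``.  Identical columns collapse into character
    classes.  Median (majority-consensus) vectors of triples are added only
    when the triple is pairwise incompatible at the character level and the
    triple's frequency support passes the reduction criterion: the minimum
    frequency among the three generators must be at least max/``reduction_r``.
    Nodes differing at exactly one character class are connected, with the
    edge labelled by the class's site positions; if the graph is left
    disconnected, closest inter-component pairs are bridged with multi-site
    edges.  With fully compatible characters no median is ever needed and
    the result is the unique perfect phylogeny.
    """
    haplotypes = np.asarray(haplotypes)
    if not np.isin(haplotypes, (0, 1)).all():
        raise HaplodivError("median networks require binary 0/1 characters")
    n = haplotypes.shape[0]
    if frequencies is None:
        frequencies = np.ones(n)
    if hap_ids is None:
        hap_ids = [f"H{i}" for i in range(n)]
    red, pos_lists, weights = _collapse_characters(
        haplotypes, np.asarray(positions)
    )

    node_key = {red[i].tobytes(): i for i in range(n)}
    vectors = [red[i].copy() for i in range(n)]
    freqs = {i: float(frequencies[i]) for i in range(n)}
    labels = {i: hap_ids[i] for i in range(n)}
    is_median = {i: False for i in range(n)}

    # Characters are compatible iff no pair shows all four gametes among the
    # observed haplotypes; a compatible set is a perfect phylogeny and needs
    # no median vectors at all.
    def has_conflict(vecs: list[np.ndarray]) -> bool:
        if not vecs or vecs[0].size < 2:
            return False
        mat = np.stack(vecs)
        for i, j in combinations(range(mat.shape[1]), 2):
            gametes = {(int(a), int(b)) for a, b in zip(mat[:, i], mat[:, j])}
            if len(gametes) == 4:
                return True
        return False

    # median closure with frequency-based reduction
    changed = has_conflict(vectors)
    while changed:
        changed = False
        current = list(range(len(vectors)))
        for a, b, c in combinations(current, 3):
            fa, fb, fc = freqs[a], freqs[b], freqs[c]
            gens = [fa, fb, fc]
            if min(gens) < max(gens) / reduction_r:
                continue
            med = np.where(
                vectors[a] + vectors[b] + vectors[c] >= 2, 1, 0
            ).astype(np.int8)
            key = med.tobytes()
            if key in node_key:
                continue
            new_id = len(vectors)
            vectors.append(med)
            node_key[key] = new_id
            freqs[new_id] = min(gens)
            labels[new_id] = f"mv{new_id}"
            is_median[new_id] = True
            changed = True
        if changed and len(vectors) > 4 * n + 64:
            break  # safety valve against pathological closure growth

    g = nx.Graph()
    for i, vec in enumerate(vectors):
        g.add_node(
            labels[i],
            haplotype="".join(str(x) for x in vec),
            frequency=freqs[i],
            median=is_median[i],
        )
    # Hamming-1 edges over character classes
    for i, j in combinations(range(len(vectors)), 2):
        diff = np.flatnonzero(vectors[i] != vectors[j])
        if len(diff) == 1:
            sites = pos_lists[diff[0]] if pos_lists else []
            g.add_edge(
                labels[i], labels[j], sites=tuple(sites),
                n_changes=weights[diff[0]] if weights else 0,
            )
    # bridge remaining components with minimal multi-character edges
    while nx.number_connected_components(g) > 1:
        comps = list(nx.connected_components(g))
        best = None
        for x, y in combinations(range(len(comps)), 2):
            for u in comps[x]:
                for v in comps[y]:
                    iu = next(i for i in range(len(vectors)) if labels[i] == u)
                    iv = next(i for i in range(len(vectors)) if labels[i] == v)
                    diff = np.flatnonzero(vectors[iu] != vectors[iv])
                    if best is None or len(diff) < len(best[2]):
                        best = (u, v, diff)
        u, v, diff = best
        sites = tuple(p for k in diff for p in pos_lists[k])
        g.add_edge(u, v, sites=sites, n_changes=len(sites))
    return g


def annotate_network(
    g: nx.Graph,
    pop_labels: dict[str, str],
    sstar_grades: dict[str, str] | None = None,
    focal_position: int | None = None,
    node_members: dict[str, list[str]] | None = None,
    focal_state: dict[str, int] | None = None,
) -> nx.Graph:
    """Attach population composition, S* grades and focal-allele state.

    ``node_members`` maps network node -> haplotype ids it represents (a
    representative carries its whole cluster); composition is the fraction
    of member haplotypes per population group.  Edges whose site label
    contains the focal SNP are flagged ``focal_edge``.
    """
    sstar_grades = sstar_grades or {}
    node_members = node_members or {}
    grade_rank = {"I": 2, "II": 1, "low": 0}
    for node, data in g.nodes(data=True):
        members = node_members.get(node, [node] if node in pop_labels else [])
        comp: dict[str, float] = {}
        for m in members:
            pop = pop_labels.get(m, "UNKNOWN")
            comp[pop] = comp.get(pop, 0.0) + 1.0
        total = sum(comp.values())
        data["composition"] = (
            {k: v / total for k, v in comp.items()} if total else {}
        )
        best = max(
            (sstar_grades.get(m, "low") for m in members),
            key=lambda x: grade_rank.get(x, 0),
            default="low",
        )
        data["max_grade"] = best
        if focal_state is not None and node in focal_state:
            data["focal_allele"] = focal_state[node]
    if focal_position is not None:
        for u, v, data in g.edges(data=True):
            data["focal_edge"] = focal_position in data.get("sites", ())
    return g


def write_graphml(g: nx.Graph, path) -> None:
    h = g.copy()
    for _, data in h.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, dict):
                data[k] = ";".join(f"{a}:{b:.4g}" for a, b in v.items())
    for _, _, data in h.edges(data=True):
        for k, v in list(data.items()):
            if isinstance(v, tuple):
                data[k] = ",".join(str(x) for x in v)
    nx.write_graphml(h, path)


def write_rdf_table(
    haplotypes: np.ndarray, positions: np.ndarray, hap_ids: list[str], path
) -> None:
    """Site-by-haplotype table in the RDF-like dialect of network software."""
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(hap_ids) + "\n")
        for s, pos in enumerate(positions):
            fh.write(
                f"{int(pos)}\t" + "\t".join(str(int(a)) for a in haplotypes[:, s]) + "\n"
            )
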