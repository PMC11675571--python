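"""Sequences, F84 distances, NJ, bootstrap, rooting, topology patterns."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from haplodiv.core import MISSING, HaplodivError
from haplodiv.phylogeny import (
    SequenceRecord,
    TreeNode,
    bootstrap_supports,
    classify_topology,
    collapse_low_support,
    encode_sequence,
    f84_distance,
    haplotypes_to_sequences,
    nj_tree,
    root_with_outgroup,
)
from haplodiv.phylogeny import _f84_params

from conftest import small_matrix


# ----------------------------------------------------------------------
# sequences
# ----------------------------------------------------------------------
def test_deleted_site_filter_boundary_inclusive():
    # 1000 sites: 5 missing (0.5%) removed, 4 missing kept
    alleles = np.zeros((3, 1000), dtype=np.int8)
    alleles[0, :5] = MISSING
    alleles[1, :4] = MISSING
    alleles[2, 0] = 1  # make row 2 distinct
    m = small_matrix(alleles, positions=np.arange(1, 1001))
    records = haplotypes_to_sequences(m)
    kept = {r.id for r in records}
    assert "h00_0" not in kept
    assert "h00_1" in kept


def test_identical_haplotypes_collapse_with_multiplicity():
    alleles = np.array([[0, 1, 0], [0, 1, 0], [1, 0, 1]], dtype=np.int8)
    m = small_matrix(alleles)
    records = haplotypes_to_sequences(m)
    assert len(records) == 2
    multi = next(r for r in records if r.multiplicity == 2)
    assert set(multi.member_ids) == {"h00_0", "h00_1"}


def test_all_haplotypes_removed_is_an_error():
    alleles = np.full((2, 10), MISSING, dtype=np.int8)
    alleles[:, 0] = [0, 1]
    m = small_matrix(alleles)
    with pytest.raises(HaplodivError):
        haplotypes_to_sequences(m, max_deleted_frac=0.005)


# ----------------------------------------------------------------------
# F84
# ----------------------------------------------------------------------
def _mutate(seq, rng, n_ts, n_tv):
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "C", "G": "T", "C": "A", "T": "G"}
    out = list(seq)
    pos = rng.choice(len(seq), n_ts + n_tv, replace=False)
    for p in pos[:n_ts]:
        out[p] = ts_map[out[p]]
    for p in pos[n_ts:]:
        out[p] = tv_map[out[p]]
    return "".join(out)


def test_f84_identical_sequences_zero():
    assert f84_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_f84_symmetry_on_random_pairs():
    rng = np.random.default_rng(1)
    for _ in range(5):
        a = "".join(rng.choice(list("ACGT"), 200))
        b = _mutate(a, rng, 10, 5)
        assert f84_distance(a, b) == pytest.approx(f84_distance(b, a), abs=1e-8)


def test_f84_ml_matches_independent_numeric_maximization():
    """ML distance agrees with an independent expm-based likelihood
    maximization to 1e-6 (100-site pair, 10 transitions, 5 transversions)."""
    rng = np.random.default_rng(2)
    a = "".join(rng.choice(list("ACGT"), 100))
    b = _mutate(a, rng, 10, 5)
    d = f84_distance(a, b, ts_tv_ratio=2.0)

    ea, eb = encode_sequence(a), encode_sequence(b)
    counts = np.bincount(4 * ea + eb, minlength=16).reshape(4, 4).astype(float)
    freq = counts.sum(0) + counts.sum(1)
    bscale, k, pi = _f84_params(freq / freq.sum(), 2.0)
    purine = np.array([True, False, True, False])
    rho = np.where(purine, pi[0] + pi[2], pi[1] + pi[3])
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = bscale * pi[j] + (
                    bscale * k * pi[j] / rho[j] if purine[i] == purine[j] else 0.0
                )
    np.fill_diagonal(q, -q.sum(axis=1))

    def nll(t):
        p = expm(q * t)
        return -np.sum(counts * np.log(np.maximum(pi[:, None] * p, 1e-300)))

    res = minimize_scalar(nll, bounds=(1e-9, 50), method="bounded",
                          options={"xatol": 1e-12})
    assert d == pytest.approx(res.x, abs=1e-6)


def test_f84_gap_sites_excluded():
    assert f84_distance("ACGTN", "ACGTA") == 0.0


def test_f84_saturation_returns_inf_with_warning():
    with pytest.warns(UserWarning, match="saturated"):
        d = f84_distance("AAAACCCCGGGGTTTT", "CCCCGGGGTTTTAAAA",
                         method="moments")
    assert np.isinf(d)


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------
def _random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths and its leaf metric."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    active = list(nodes)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        parent = TreeNode()
        a.length = float(rng.uniform(0.5, 3.0))
        b.length = float(rng.uniform(0.5, 3.0))
        parent.add(b)
        parent.add(a)
        active = [x for x in active if x not in (a, b)] + [parent]
    root = active[0]
    names, m = root.patristic_distances()
    return root, names, m


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
def test_nj_recovers_random_additive_trees(n_taxa):
    rng = np.random.default_rng(n_taxa)
    for _ in range(10):
        true, names, m = _random_additive_tree(rng, n_taxa)
        est = nj_tree(names, m)
        assert est.bipartitions() == true.bipartitions()
        est_names, est_m = est.patristic_distances()
        order = [est_names.index(n) for n in names]
        assert np.allclose(est_m[np.ix_(order, order)], m, atol=1e-9)


def test_nj_agrees_with_independent_implementation():
    """On additive metrics, an independent NJ (scikit-bio) and ours must
    both recover the generating tree's bipartitions."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(33)
    for _ in range(5):
        true, names, m = _random_additive_tree(rng, 6)
        mine = nj_tree(names, m).bipartitions()
        sk_tree = skbio_nj(DistanceMatrix(m, ids=names))
        sk_bips = set()
        all_names = frozenset(names)
        ref = min(all_names)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(all_names - side) < 2:
                continue
            sk_bips.add(side if ref not in side else all_names - side)
        assert mine == sk_bips == true.bipartitions()


def test_nj_three_taxa_three_point_formulas():
    labels = ["a", "b", "c"]
    m = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
    t = nj_tree(labels, m)
    lens = {l.name: l.length for l in t.leaves()}
    assert lens == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})


def test_nj_identical_rows_give_zero_length_cherry():
    labels = ["a", "b", "c", "d"]
    m = np.array(
        [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
    )
    t = nj_tree(labels, m)
    names, pm = t.patristic_distances()
    i, j = names.index("a"), names.index("b")
    assert pm[i, j] == pytest.approx(0.0)


def test_nj_rejects_small_or_asymmetric_input():
    with pytest.raises(HaplodivError):
        nj_tree(["a", "b"], np.zeros((2, 2)))
    with pytest.raises(ValueError):
        nj_tree(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------
def _records(seqs):
    return [SequenceRecord(id=f"s{i}", seq=s) for i, s in enumerate(seqs)]


def test_bootstrap_conflict_free_alignment_all_supports_100():
    # two nested binary characters, 20 congruent columns each, no conflict
    base = [
        "G" * 20 + "C" * 20,
        "G" * 20 + "C" * 20,
        "A" * 20 + "C" * 20,
        "A" * 20 + "A" * 20,
        "A" * 20 + "A" * 20,
    ]
    # private singleton columns keep taxa distinct without split conflict
    seqs = [
        s + "".join("T" if j == i else "A" for j in range(5))
        for i, s in enumerate(base)
    ]
    tree = bootstrap_supports(_records(seqs), n_reps=100, seed=1)
    sups = [
        n.support
        for n in tree.walk()
        if not n.is_leaf and n.parent is not None and n.support is not None
    ]
    assert sups and all(s == 100.0 for s in sups)


def test_bootstrap_fixed_seed_reproducible():
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(6)]
    t1 = bootstrap_supports(_records(seqs), n_reps=50, seed=9)
    t2 = bootstrap_supports(_records(seqs), n_reps=50, seed=9)
    assert t1.newick() == t2.newick()


def test_bootstrap_fifty_fifty_conflict_near_half_support():
    """Two equally frequent incompatible site classes on 4 taxa: the winning
    split's support behaves like a binomial proportion near 50%."""
    s1 = "A" * 30 + "A" * 30  # class 1 groups (s0,s1) vs (s2,s3)
    seqs = [
        "A" * 30 + "A" * 30,
        "A" * 30 + "C" * 30,
        "C" * 30 + "A" * 30,
        "C" * 30 + "C" * 30,
    ]
    tree = bootstrap_supports(_records(seqs), n_reps=500, seed=3)
    sups = [
        n.support
        for n in tree.walk()
        if not n.is_leaf and n.parent is not None and n.support is not None
    ]
    assert sups
    assert min(abs(s - 50.0) for s in sups) <= 10.0


# ----------------------------------------------------------------------
# rooting
# ----------------------------------------------------------------------
def test_root_on_outgroup_pendant_edge():
    labels = ["a", "b", "out"]
    m = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
    t = nj_tree(labels, m)
    r = root_with_outgroup(t, "out")
    assert len(r.children) == 2
    out_child = next(c for c in r.children if c.name == "out")
    other = next(c for c in r.children if c.name != "out")
    assert out_child.length == pytest.approx(other.length)  # midpoint


def test_rooting_preserves_ingroup_bipartitions():
    rng = np.random.default_rng(12)
    true, names, m = _random_additive_tree(rng, 7)
    unrooted = nj_tree(names, m)
    rooted = root_with_outgroup(unrooted, names[0])
    assert rooted.bipartitions() == unrooted.bipartitions()


def test_rooting_twice_is_idempotent():
    rng = np.random.default_rng(15)
    _, names, m = _random_additive_tree(rng, 6)
    r1 = root_with_outgroup(nj_tree(names, m), names[2])
    r2 = root_with_outgroup(r1, names[2])
    assert r1.bipartitions() == r2.bipartitions()
    assert sorted(r1.leaf_names()) == sorted(r2.leaf_names())


def test_missing_outgroup_raises():
    _, names, m = _random_additive_tree(np.random.default_rng(1), 5)
    with pytest.raises(HaplodivError):
        root_with_outgroup(nj_tree(names, m), "nope")


# ----------------------------------------------------------------------
# topology classification
# ----------------------------------------------------------------------
def _chain(*subtrees):
    root = TreeNode()
    for s in subtrees:
        root.add(s)
    return root


def _leaf(name, length=1.0):
    return TreeNode(name=name, length=length)


def _node(children, support=100.0):
    n = TreeNode(support=support)
    for c in children:
        n.add(c)
    return n


def test_nested_eurasian_within_african_is_typical_ooa():
    # ((AFR,AFR),(AFR,(EUR,ASN)))
    tree = _chain(
        _node([_leaf("a1"), _leaf("a2")]),
        _node([_leaf("a3"), _node([_leaf("e1"), _leaf("e2")])]),
    )
    groups = {"a1": "AFR", "a2": "AFR", "a3": "AFR", "e1": "EUR", "e2": "ASN"}
    pat = classify_topology(tree, groups)
    assert pat.typical_ooa
    assert "E" in pat.pattern and "A" in pat.pattern


def test_all_african_tree_is_not_typical_ooa():
    tree = _chain(_node([_leaf("a1"), _leaf("a2")]), _leaf("a3"))
    pat = classify_topology(tree, {"a1": "AFR", "a2": "AFR", "a3": "AFR"})
    assert pat.pattern == "A" or set(pat.pattern) <= set("(),A")
    assert not pat.typical_ooa


def test_basal_archaic_plus_graded_eurasians_is_type_fe():
    tree = _chain(
        _node([_leaf("nea"), _node([_leaf("e1"), _leaf("e2")])]),
        _node([_leaf("a1"), _leaf("a2")]),
    )
    groups = {"nea": "NEA", "e1": "EUR", "e2": "ASN", "a1": "AFR", "a2": "AFR"}
    grades = {"e1": "I", "e2": "I"}
    pat = classify_topology(tree, groups, grades)
    assert pat.pattern_type == "FE"


def test_archaic_inside_african_cluster_is_type_af():
    tree = _chain(
        _node([_leaf("a1"), _node([_leaf("a2"), _leaf("nea")])]),
        _node([_leaf("e1"), _leaf("e2")]),
    )
    groups = {"a1": "AFR", "a2": "AFR", "nea": "NEA", "e1": "EUR", "e2": "EUR"}
    pat = classify_topology(tree, groups, {"a2": "II"})
    assert pat.pattern_type == "Af"


def test_nd_shared_class_uses_bootstrap_bins():
    def make(support):
        return _chain(
            _node([_leaf("nea"), _leaf("den")], support=support),
            _node([_leaf("a1"), _leaf("e1")]),
        )

    groups = {"nea": "NEA", "den": "DEN", "a1": "AFR", "e1": "EUR"}
    assert classify_topology(make(99.5), groups).nd_shared_class == "++"
    assert classify_topology(make(90.0), groups).nd_shared_class == "+"
    assert classify_topology(make(60.0), groups).nd_shared_class == "-"


def test_collapse_never_increases_cluster_count():
    tree = _chain(
        _node([_leaf("a1"), _node([_leaf("a2"), _leaf("a3")], support=30)]),
        _leaf("e1"),
    )
    collapsed = collapse_low_support(tree, 50)
    n_internal = sum(1 for n in collapsed.walk() if not n.is_leaf)
    n_before = sum(1 for n in tree.walk() if not n.is_leaf)
    assert n_internal <= n_before


def test_unlabeled_leaf_raises():
    tree = _chain(_leaf("x"), _leaf("y"), _leaf("z"))
    with pytest.raises(HaplodivError):
        classify_topology(tree, {"x": "AFR", "y": "EUR"})
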