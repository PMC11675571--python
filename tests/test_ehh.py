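"""EHH curves, regions, bifurcation graphs, AS and CR classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplodiv.core import MISSING, HaplodivError
from haplodiv.ehh import (
    BifurcationGraph,
    BifurcationNode,
    allelic_selection,
    bifurcation_graph,
    constrained_region,
    ehh_curve,
    ehh_profile,
    ehh_regions,
)
from haplodiv.ehh import EHHProfile

from conftest import MODERN_GROUPS, central_focal, small_matrix


def _matrix_with_core(core_alleles, focal_col):
    """Matrix whose focal column is ``focal_col``; other columns given."""
    alleles = np.asarray(core_alleles, dtype=np.int8)
    return small_matrix(alleles)


def test_ehh_is_one_at_focal_site():
    alleles = np.array(
        [[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1], [0, 0, 0]], dtype=np.int8
    )
    m = small_matrix(alleles)
    curve = ehh_curve(m, 200, allele=1)
    f = m.site_index(200)
    assert curve[f] == 1.0


def test_ehh_two_two_split_is_one_third():
    # 4 core haplotypes split 2/2 at the next site: (1 + 1) / C(4,2)
    alleles = np.array(
        [[1, 0], [1, 0], [1, 1], [1, 1], [0, 0]], dtype=np.int8
    )
    m = small_matrix(alleles)
    curve = ehh_curve(m, 100, allele=1)
    assert curve[1] == pytest.approx(1.0 / 3.0)


def test_ehh_three_one_split_is_half():
    alleles = np.array(
        [[1, 0], [1, 0], [1, 0], [1, 1], [0, 1]], dtype=np.int8
    )
    m = small_matrix(alleles)
    curve = ehh_curve(m, 100, allele=1)
    assert curve[1] == pytest.approx(3.0 / 6.0)


def test_ehh_fewer_than_two_core_haplotypes_raises():
    alleles = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.int8)
    m = small_matrix(alleles)
    with pytest.raises(HaplodivError):
        ehh_curve(m, 100, allele=1)


def test_ehh_min_geno_excludes_gappy_haplotypes():
    alleles = np.array(
        [[1, 0, MISSING], [1, 0, 0], [1, 1, 0], [0, 0, 0]], dtype=np.int8
    )
    m = small_matrix(alleles)
    # first haplotype is 66% genotyped: excluded, leaving a 2-hap core
    curve = ehh_curve(m, 100, allele=1, min_geno=99.0)
    assert curve[1] == pytest.approx(0.0)  # remaining two split 1/1


def test_missing_inside_extension_becomes_own_group():
    alleles = np.array(
        [[1, MISSING, 0], [1, 0, 0], [1, 0, 0], [0, 0, 0]], dtype=np.int8
    )
    m = small_matrix(alleles)
    curve = ehh_curve(m, 100, allele=1, min_geno=50.0)
    # 3 cores; after the missing site: groups {h0}, {h1,h2} -> 1/3
    assert curve[1] == pytest.approx(1.0 / 3.0)


def test_ehh_monotone_non_increasing_on_simulation(neutral_locus):
    m, _ = neutral_locus
    rows = m.hap_indices(MODERN_GROUPS)
    sub = m.take_haplotypes(rows)
    focal = central_focal(sub)
    for allele in (0, 1):
        curve = ehh_curve(sub, focal, allele)
        f = sub.site_index(focal)
        assert np.all(np.diff(curve[: f + 1]) >= -1e-12)  # rising toward focal
        assert np.all(np.diff(curve[f:]) <= 1e-12)  # falling away


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    n_hap=st.integers(6, 14),
    n_site=st.integers(5, 25),
    miss=st.floats(0.0, 0.2),
)
def test_ehh_monotone_for_arbitrary_matrices(seed, n_hap, n_site, miss):
    """Partition refinement makes EHH non-increasing outward on any input,
    including matrices with missing alleles."""
    rng = np.random.default_rng(seed)
    alleles = rng.integers(0, 2, size=(n_hap, n_site)).astype(np.int8)
    alleles[rng.random(alleles.shape) < miss] = MISSING
    f = n_site // 2
    allele = 1 if (alleles[:, f] == 1).sum() >= 2 else 0
    if (alleles[:, f] == allele).sum() < 2:
        return
    m = small_matrix(alleles)
    curve = ehh_curve(m, int(m.positions[f]), allele, min_geno=0.0)
    assert curve[f] == 1.0
    assert np.all(np.diff(curve[f:]) <= 1e-12)
    assert np.all(np.diff(curve[: f + 1]) >= -1e-12)


def _profile_from_curves(positions, focal, anc, der):
    return EHHProfile(
        focal_position=focal,
        positions=np.asarray(positions),
        ehh_ancestral=np.asarray(anc, dtype=float),
        ehh_derived=np.asarray(der, dtype=float),
        core_counts={0: 10, 1: 10},
        maf=0.3,
    )


def test_region_is_whole_locus_when_curves_stay_high():
    p = _profile_from_curves([100, 200, 300], 200, [1, 1, 0.9], [0.8, 1, 0.9])
    region, _, length = ehh_regions(p, 0.2)
    assert region == (100, 300)
    assert length == 201


def test_region_bound_set_by_first_allele_to_drop():
    pos = [100, 200, 300, 400, 500]
    anc = [1.0, 1.0, 1.0, 0.5, 0.3]
    der = [1.0, 1.0, 1.0, 0.1, 0.05]  # derived drops below 0.2 at 400
    p = _profile_from_curves(pos, 300, anc, der)
    region, _, _ = ehh_regions(p, 0.2)
    assert region == (100, 300)


def test_region_always_contains_focal():
    p = _profile_from_curves([100, 200, 300], 200, [0, 1, 0], [0, 1, 0])
    region, _, _ = ehh_regions(p, 0.2)
    assert region == (200, 200)


# ----------------------------------------------------------------------
# bifurcation graphs
# ----------------------------------------------------------------------
def test_identical_core_haplotypes_single_unbranched_lineage():
    alleles = np.array(
        [[1, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=np.int8
    )
    m = small_matrix(alleles)
    g = bifurcation_graph(m, 100, 1, (100, 300))
    assert g.root.is_leaf
    assert g.bifurcation_positions == []


def test_single_split_widths():
    alleles = np.array(
        [[1, 0], [1, 0], [1, 1], [1, 1], [0, 0]], dtype=np.int8
    )
    m = small_matrix(alleles)
    g = bifurcation_graph(m, 100, 1, (100, 200))
    widths = sorted(leaf.width for leaf in g.root.leaves())
    assert widths == [2, 2]
    assert g.bifurcation_positions == [200]


def test_multi_branch_bifurcation_position_flagged():
    # two branches (split at site 2) both split again at site 3
    alleles = np.array(
        [
            [1, 0, 0],
            [1, 0, 1],
            [1, 1, 0],
            [1, 1, 1],
        ],
        dtype=np.int8,
    )
    m = small_matrix(alleles)
    g = bifurcation_graph(m, 100, 1, (100, 300))
    assert 300 in g.multi_branch_positions


def test_leaf_widths_sum_to_core_count(introgressed_locus):
    m, _ = introgressed_locus
    rows = m.hap_indices(MODERN_GROUPS)
    sub = m.take_haplotypes(rows)
    focal = central_focal(sub)
    region = (int(sub.positions[0]), int(sub.positions[-1]))
    for allele in (0, 1):
        for direction in ("left", "right"):
            g = bifurcation_graph(sub, focal, allele, region, direction)
            assert sum(l.width for l in g.root.leaves()) == g.core_count


# ----------------------------------------------------------------------
# AS and CR
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "ratio,maf,expected",
    [
        (0.05, 0.3, "++"),
        (0.15, 0.3, "+"),
        (0.3, 0.3, "+/-"),
        (0.5, 0.3, "-"),
        (0.05, 0.08, "n/a"),
    ],
)
def test_allelic_selection_bins(ratio, maf, expected):
    pos = list(range(0, 10_100, 100))
    focal = 5_000
    anc = [1.0 if abs(p - focal) <= 5_000 else 0.0 for p in pos]
    half = ratio * 5_000
    der = [1.0 if abs(p - focal) <= half else 0.0 for p in pos]
    profile = _profile_from_curves(pos, focal, anc, der)
    profile.maf = maf
    assert allelic_selection(profile) == expected


def test_allelic_selection_zero_spans_is_negative():
    pos = [100, 200, 300]
    profile = _profile_from_curves(pos, 200, [0.1, 1, 0.1], [0.1, 1, 0.1])
    assert allelic_selection(profile) == "-"


def _graph_with_positions(positions):
    root = BifurcationNode(position=0, width=2)
    return BifurcationGraph(
        allele=1, direction="right", root=root,
        bifurcation_positions=list(positions),
    )


def test_constrained_region_uniform_positions_negative():
    g = _graph_with_positions(range(1_000, 100_000, 4_000))
    symbol, _ = constrained_region([g], (0, 100_000), seed=1)
    assert symbol == "-"


def test_constrained_region_packed_positions_positive():
    g = _graph_with_positions(list(range(1_000, 30_000, 1_500)))
    symbol, interval = constrained_region([g], (0, 100_000), seed=1)
    assert symbol == "+"
    assert interval is not None and interval[1] - interval[0] > 25_000


def test_constrained_region_few_positions_warns_negative():
    g = _graph_with_positions([10, 20])
    with pytest.warns(UserWarning):
        symbol, interval = constrained_region([g], (0, 1_000), seed=1)
    assert symbol == "-" and interval is None


# ----------------------------------------------------------------------
# full profile
# ----------------------------------------------------------------------
def test_full_profile_on_simulation(neutral_locus):
    m, _ = neutral_locus
    rows = m.hap_indices(MODERN_GROUPS)
    focal = central_focal(m, rows)
    profile = ehh_profile(m, focal, hap_rows=rows, cr_seed=0)
    f = int(np.searchsorted(profile.positions, focal))
    assert profile.ehh_ancestral[f] == 1.0
    assert profile.ehh_derived[f] == 1.0
    hi = profile.high_ehh_region
    lo = profile.ehh_region
    assert lo[0] <= hi[0] <= hi[1] <= lo[1]
    assert profile.selection is not None
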