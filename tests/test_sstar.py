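"""Phased S*: candidate sites, DP scoring, thresholds and grades."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplodiv.core import HaplodivError
from haplodiv.sstar import (
    SStarConfig,
    grade,
    run_sstar,
    select_candidate_sites,
    sstar_score,
    thresholds,
)

from conftest import small_matrix


def brute_force_sstar(positions, carriers, cfg):
    """Exhaustive enumeration over all ordered subsets (the DP oracle)."""
    from haplodiv.sstar import pair_score

    k = len(positions)
    best = 0.0
    found = False
    for size in range(2, k + 1):
        for subset in combinations(range(k), size):
            total = 0.0
            ok = True
            for i, j in zip(subset, subset[1:]):
                ps = pair_score(
                    int(positions[j] - positions[i]), carriers[i], carriers[j], cfg
                )
                if ps == float("-inf"):
                    ok = False
                    break
                total += ps
            if ok:
                best = total if not found else max(best, total)
                found = True
    return best if found else 0.0


# ----------------------------------------------------------------------
# candidate sites
# ----------------------------------------------------------------------
def _panel(ref_col, tgt_col):
    """20 AFR reference + 4 EUR target haplotypes, one site per column pair."""
    ref = np.asarray(ref_col, dtype=np.int8)
    tgt = np.asarray(tgt_col, dtype=np.int8)
    alleles = np.concatenate([ref, tgt])[:, None]
    return small_matrix(alleles, pops=["AFR"] * len(ref) + ["EUR"] * len(tgt))


def test_reference_maf_below_cutoff_included():
    # ref derived freq 1/25 = 0.04 < 0.05; target hap carries minor allele
    m = _panel([1] + [0] * 24, [1, 0, 0, 0])
    assert select_candidate_sites(m, 25) == [0]


def test_reference_maf_at_cutoff_excluded():
    # ref MAF exactly 0.05 fails the strict inequality
    m = _panel([1] + [0] * 19, [1, 0, 0, 0])
    assert select_candidate_sites(m, 20) == []


def test_major_allele_carrier_gets_no_candidates():
    m = _panel([1] + [0] * 24, [0, 0, 0, 0])
    assert select_candidate_sites(m, 25) == []


def test_no_reference_haplotypes_is_an_error():
    m = small_matrix(np.array([[0], [1]], dtype=np.int8), pops=["EUR", "EUR"])
    with pytest.raises(HaplodivError):
        select_candidate_sites(m, 0)


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------
def test_single_candidate_site_scores_zero():
    cfg = SStarConfig()
    assert sstar_score(np.array([1000]), [frozenset({1})], cfg) == 0.0


def test_full_chain_with_identical_carriers():
    cfg = SStarConfig()
    pos = np.array([1_000, 21_000, 61_000])
    carriers = [frozenset({1, 2})] * 3
    # chain of all three: (20,000 + 5,000) + (40,000 + 5,000)
    assert sstar_score(pos, carriers, cfg) == 70_000.0


def test_divergent_middle_site_is_skipped():
    cfg = SStarConfig()
    pos = np.array([1_000, 21_000, 61_000])
    base = frozenset(range(10))
    other = frozenset(range(6, 22))  # symmetric difference 16 > m_max
    carriers = [base, other, base]
    assert sstar_score(pos, carriers, cfg) == 65_000.0


def test_close_pair_below_min_distance_disallowed():
    cfg = SStarConfig()
    pos = np.array([1_000, 1_005])
    carriers = [frozenset({1})] * 2
    assert sstar_score(pos, carriers, cfg) == 0.0


def test_unsorted_sites_rejected():
    cfg = SStarConfig()
    with pytest.raises(ValueError):
        sstar_score(np.array([500, 100]), [frozenset(), frozenset()], cfg)


def test_dp_equals_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    cfg = SStarConfig()
    for _ in range(60):
        k = int(rng.integers(2, 11))
        positions = np.sort(rng.choice(100_000, size=k, replace=False))
        pool = list(range(12))
        carriers = [
            frozenset(rng.choice(pool, size=rng.integers(1, 6), replace=False))
            for _ in range(k)
        ]
        assert sstar_score(positions, carriers, cfg) == pytest.approx(
            brute_force_sstar(positions, carriers, cfg)
        )


def test_appending_congruent_downstream_site_never_decreases_score():
    rng = np.random.default_rng(7)
    cfg = SStarConfig()
    for _ in range(20):
        k = int(rng.integers(2, 8))
        positions = np.sort(rng.choice(50_000, size=k, replace=False))
        carriers = [frozenset({1, 2, 3})] * k
        s0 = sstar_score(positions, carriers, cfg)
        s1 = sstar_score(
            np.append(positions, positions[-1] + 5_000),
            carriers + [frozenset({1, 2, 3})],
            cfg,
        )
        assert s1 >= s0


# ----------------------------------------------------------------------
# thresholds and grades
# ----------------------------------------------------------------------
@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=2, max_value=5000))
def test_threshold_line_properties(n):
    """T1 linear in N with slope 2500/13, T2/T1 = 4/3, grades consistent
    at the exact boundaries for any locus SNP count."""
    t1, t2 = thresholds(n)
    assert t1 == pytest.approx((2500.0 / 13.0) * (n - 1))
    assert t2 == pytest.approx(t1 * 4.0 / 3.0)
    assert grade(t2, t1, t2) == "I"
    assert grade(t1, t1, t2) == ("II" if t1 < t2 else "I")
    assert grade(t1 - 1e-6, t1, t2) == "low" if t1 > 0 else True


def test_threshold_anchor_values():
    t1, t2 = thresholds(313)
    assert t1 == pytest.approx(60_000.0)
    assert t2 == pytest.approx(80_000.0)
    t1, t2 = thresholds(209)
    assert t1 == pytest.approx(40_000.0)
    assert t2 == pytest.approx(53_333.333333, abs=1e-3)


def test_threshold_degenerate_and_errors():
    assert thresholds(1) == (0.0, 0.0)
    with pytest.raises(ValueError):
        thresholds(0)


def test_threshold_linearity_and_ratio():
    for n in (2, 50, 313, 1000):
        t1, t2 = thresholds(n)
        assert t2 / t1 == pytest.approx(4.0 / 3.0) if t1 else t2 == 0
        assert t1 == pytest.approx((2500.0 / 13.0) * (n - 1))


@pytest.mark.parametrize(
    "s,expected",
    [(80_000.0, "I"), (60_000.0, "II"), (59_999.0, "low"), (100_000.0, "I")],
)
def test_grade_boundaries(s, expected):
    assert grade(s, 60_000.0, 80_000.0) == expected


# ----------------------------------------------------------------------
# run_sstar
# ----------------------------------------------------------------------
def test_all_reference_dataset_yields_empty_results():
    m = small_matrix(
        np.array([[0, 1], [1, 0], [0, 0], [1, 1]], dtype=np.int8),
        pops=["AFR"] * 4,
    )
    assert run_sstar(m) == []


def test_sstar_invariant_to_reference_common_sites():
    rng = np.random.default_rng(11)
    n_ref, n_tgt = 20, 6
    base = rng.integers(0, 2, size=(n_ref + n_tgt, 8)).astype(np.int8)
    m1 = small_matrix(
        base,
        positions=np.arange(1, 9) * 3_000,
        pops=["AFR"] * n_ref + ["EUR"] * n_tgt,
    )
    # add a site common in the reference (freq 0.5): never a candidate
    common = rng.permutation(
        np.array([1] * ((n_ref + n_tgt) // 2) + [0] * ((n_ref + n_tgt) // 2))
    ).astype(np.int8)
    withc = np.column_stack([base, common])
    m2 = small_matrix(
        withc,
        positions=list(np.arange(1, 9) * 3_000) + [27_000],
        pops=["AFR"] * n_ref + ["EUR"] * n_tgt,
    )
    s1 = {r.hap_id: r.s_star for r in run_sstar(m1)}
    s2 = {r.hap_id: r.s_star for r in run_sstar(m2)}
    assert s1 == s2
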