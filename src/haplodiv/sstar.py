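"""Phased-haplotype S* introgression scoring with grade thresholds.

S* scores, within one target chromosome, chains of linked alleles that are
rare in the African reference panel; unusually high scores flag candidate
archaic-introgressed haplotypes.  This implementation works directly on
phased haplotypes: the "carrier set" of a candidate site is the set of
target-population chromosomes bearing the minor allele, and the pair score
rewards physically distant site pairs with identical carrier sets while
penalising carrier-set mismatches.

Grades follow locus-specific thresholds linear in the locus SNP count N:

    T1 = (2500 / 13) * (N - 1),      T2 = (4/3) * T1

(the unique line through the two calibration anchors T1 = 60,000 at N = 313
and T1 = 40,000 at N = 209), with grade I for S* >= T2 and grade II for
T1 <= S* < T2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import (
    GROUP_AFRICAN,
    MISSING,
    TARGET_GROUPS,
    HaplodivError,
    HaplotypeMatrix,
)

__all__ = [
    "SStarConfig",
    "SStarResult",
    "select_candidate_sites",
    "pair_score",
    "sstar_score",
    "thresholds",
    "grade",
    "run_sstar",
]

NEG_INF = float("-inf")


@dataclass
class SStarConfig:
    """Scoring constants and population roles for the phased S*."""

    reference_groups: tuple[str, ...] = (GROUP_AFRICAN,)
    target_groups: tuple[str, ...] = tuple(TARGET_GROUPS)
    ref_maf_cutoff: float = 0.05
    bonus: float = 5_000.0
    mismatch_penalty: float = -10_000.0
    max_mismatches: int = 5
    min_pair_distance: int = 10
    pair_score_fn: Callable | None = None  # optional override

    def __post_init__(self) -> None:
        if not (0 < self.ref_maf_cutoff < 0.5):
            raise ValueError("ref_maf_cutoff must be in (0, 0.5)")


@dataclass
class SStarResult:
    hap_id: str
    population: str
    candidate_sites: list[int]  # positions
    s_star: float
    n_snps: int
    t1: float
    t2: float
    grade: str  # 'I', 'II', 'low'


def _site_stats(h: HaplotypeMatrix, cfg: SStarConfig):
    """Vectorized per-site statistics shared by all target haplotypes.

    Returns (minor_allele per site, qualifying-site mask) where a site
    qualifies when it is polymorphic overall and the reference MAF is below
    the cutoff (strict).
    """
    ref_rows = h.hap_indices(cfg.reference_groups)
    if ref_rows.size == 0:
        raise HaplodivError("no reference haplotypes in the matrix")
    alleles = h.alleles
    obs = alleles != MISSING
    with np.errstate(invalid="ignore"):
        n_obs = obs.sum(axis=0)
        p_all = np.where(n_obs > 0, (alleles == 1).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
        ref_obs = obs[ref_rows].sum(axis=0)
        p_ref = np.where(
            ref_obs > 0,
            (alleles[ref_rows] == 1).sum(axis=0) / np.maximum(ref_obs, 1),
            np.nan,
        )
    minor = np.where(p_all <= 0.5, 1, 0).astype(np.int8)
    ref_maf = np.minimum(p_ref, 1.0 - p_ref)
    qualifies = (
        (n_obs > 0)
        & (p_all > 0)
        & (p_all < 1)
        & (ref_obs > 0)
        & (ref_maf < cfg.ref_maf_cutoff)
    )
    return minor, qualifies


def select_candidate_sites(
    h: HaplotypeMatrix, target_hap: int, cfg: SStarConfig | None = None
) -> list[int]:
    """Column indices of S* candidate sites for one target haplotype.

    A site qualifies when the target chromosome carries the locus-wide minor
    allele and the reference-population minor-allele frequency is below the
    cutoff (strict inequality).  Missing alleles never qualify.
    """
    cfg = cfg or SStarConfig()
    minor, qualifies = _site_stats(h, cfg)
    row = h.alleles[target_hap]
    mask = qualifies & (row != MISSING) & (row == minor)
    return [int(s) for s in np.flatnonzero(mask)]


def carrier_set(
    h: HaplotypeMatrix, site: int, rows: np.ndarray
) -> frozenset[int]:
    """Chromosomes among ``rows`` carrying the locus-wide minor allele.

    Missing alleles count as non-carriers (the conservative reading).
    """
    p_all = h.derived_frequency(site)
    minor_allele = 1 if p_all <= 0.5 else 0
    col = h.alleles[rows, site]
    return frozenset(int(r) for r, a in zip(rows, col) if a == minor_allele)


def pair_score(
    d_bp: int,
    carriers_i: frozenset[int],
    carriers_j: frozenset[int],
    cfg: SStarConfig,
) -> float:
    """Score of one ordered candidate-site pair."""
    if cfg.pair_score_fn is not None:
        return cfg.pair_score_fn(d_bp, carriers_i, carriers_j, cfg)
    if d_bp < cfg.min_pair_distance:
        return NEG_INF
    mismatches = len(carriers_i ^ carriers_j)
    if mismatches == 0:
        return d_bp + cfg.bonus
    if mismatches <= cfg.max_mismatches:
        return cfg.mismatch_penalty * mismatches
    return NEG_INF


def sstar_score(
    positions: np.ndarray,
    carriers: list[frozenset[int]],
    cfg: SStarConfig | None = None,
) -> float:
    """Maximum chain score over ordered subsets of candidate sites.

    The score of a chain is the sum of pair scores of consecutive sites;
    the dynamic programme maximises over all chains of length >= 2 and
    equals exhaustive subset enumeration.  Fewer than two candidate sites
    score 0.
    """
    cfg = cfg or SStarConfig()
    positions = np.asarray(positions)
    k = len(positions)
    if k != len(carriers):
        raise ValueError("positions and carrier sets must align")
    if k and np.any(np.diff(positions) < 0):
        raise ValueError("candidate sites must be sorted by position")
    if k < 2:
        return 0.0
    # best[j]: best score of a chain ending at j (chain length >= 2)
    best = np.full(k, NEG_INF)
    for j in range(1, k):
        for i in range(j):
            ps = pair_score(
                int(positions[j] - positions[i]), carriers[i], carriers[j], cfg
            )
            if ps == NEG_INF:
                continue
            start_here = ps  # chain (i, j)
            extend = best[i] + ps if best[i] > NEG_INF else NEG_INF
            best[j] = max(best[j], start_here, extend)
    top = float(best.max())
    return top if top > NEG_INF else 0.0


def thresholds(n_snps: int) -> tuple[float, float]:
    """Locus thresholds (T1, T2) from the locus SNP count."""
    if n_snps < 1:
        raise ValueError("SNP count must be at least 1")
    t1 = (2500.0 / 13.0) * (n_snps - 1)
    return t1, (4.0 / 3.0) * t1


def grade(s_star: float, t1: float, t2: float) -> str:
    """Introgression grade: 'I' (S* >= T2), 'II' (T1 <= S* < T2), else 'low'."""
    if t1 > t2:
        raise ValueError("T1 must not exceed T2")
    if s_star >= t2:
        return "I"
    if s_star >= t1:
        return "II"
    return "low"


def run_sstar(
    h: HaplotypeMatrix, cfg: SStarConfig | None = None
) -> list[SStarResult]:
    """Score every target haplotype, separately per target population group.

    The locus SNP count N (for thresholds) is the number of sites
    segregating among the modern human haplotypes (reference + targets).
    """
    cfg = cfg or SStarConfig()
    modern_rows = h.hap_indices(cfg.reference_groups + cfg.target_groups)
    n_snps = 0
    for s in range(h.n_sites):
        col = h.alleles[modern_rows, s]
        obs = col[col != MISSING]
        if obs.size and 0 < np.mean(obs == 1) < 1:
            n_snps += 1
    if n_snps < 1:
        return []
    t1, t2 = thresholds(n_snps)

    results: list[SStarResult] = []
    groups = h.groups
    minor, qualifies = _site_stats(h, cfg)
    for target_group in cfg.target_groups:
        pop_rows = np.array(
            [i for i, g in enumerate(groups) if g == target_group], dtype=int
        )
        if pop_rows.size == 0:
            continue
        carrier_cache: dict[int, frozenset[int]] = {}

        def carriers_at(s: int) -> frozenset[int]:
            got = carrier_cache.get(s)
            if got is None:
                col = h.alleles[pop_rows, s]
                got = frozenset(
                    int(r) for r, a in zip(pop_rows, col) if a == minor[s]
                )
                carrier_cache[s] = got
            return got

        for row in pop_rows:
            hap_row = h.alleles[row]
            mask = qualifies & (hap_row != MISSING) & (hap_row == minor)
            sites = [int(s) for s in np.flatnonzero(mask)]
            carriers = [carriers_at(s) for s in sites]
            score = sstar_score(h.positions[sites], carriers, cfg)
            results.append(
                SStarResult(
                    hap_id=h.hap_ids[row],
                    population=target_group,
                    candidate_sites=[int(h.positions[s]) for s in sites],
                    s_star=score,
                    n_snps=n_snps,
                    t1=t1,
                    t2=t2,
                    grade=grade(score, t1, t2),
                )
            )
    return results
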