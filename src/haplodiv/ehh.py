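"""Extended haplotype homozygosity, bifurcation graphs and selection calls.

EHH at distance x from a focal SNP is the probability that two randomly
chosen chromosomes carrying the same core allele are identical over the
whole interval from the focal SNP to x; slow decay of EHH around a derived
allele signals a recent selective sweep.  The module also builds haplotype
bifurcation graphs (branch widths = haplotype counts), classifies allelic
selection (AS) from the ratio of the two alleles' EHH spans at EHH = 0.5,
and flags constrained regions (CR) from the skew of bifurcation positions
inside the high-EHH region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, HaplodivError, HaplotypeMatrix

__all__ = [
    "EHHProfile",
    "BifurcationNode",
    "BifurcationGraph",
    "SelectionCall",
    "ehh_curve",
    "ehh_profile",
    "ehh_regions",
    "bifurcation_graph",
    "allelic_selection",
    "constrained_region",
]


@dataclass
class BifurcationNode:
    """One branch of a bifurcation graph: haplotype group at some extent."""

    position: int  # bp where this branch was created
    width: int  # number of core haplotypes in the branch
    children: list["BifurcationNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["BifurcationNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class BifurcationGraph:
    """Per-allele, per-direction haplotype bifurcation structure."""

    allele: int
    direction: str  # 'left' or 'right'
    root: BifurcationNode
    bifurcation_positions: list[int] = field(default_factory=list)
    multi_branch_positions: list[int] = field(default_factory=list)

    @property
    def core_count(self) -> int:
        return self.root.width


@dataclass
class SelectionCall:
    as_symbol: str  # '++', '+', '+/-', '-', 'n/a'
    cr_symbol: str  # '+', '+/-', '-'
    maf: float
    cr_interval: tuple[int, int] | None = None


@dataclass
class EHHProfile:
    """EHH curves for both focal alleles plus derived classifications."""

    focal_position: int
    positions: np.ndarray  # all site positions of the locus
    ehh_ancestral: np.ndarray
    ehh_derived: np.ndarray
    core_counts: dict[int, int]  # allele -> n core haplotypes
    maf: float
    ehh_region: tuple[int, int] = (0, 0)  # both alleles >= 0.05
    high_ehh_region: tuple[int, int] = (0, 0)  # both alleles >= 0.2
    high_ehh_length: int = 0
    bifurcations: list[BifurcationGraph] = field(default_factory=list)
    selection: SelectionCall | None = None


def _core_rows(
    h: HaplotypeMatrix, focal_idx: int, allele: int, min_geno: float
) -> np.ndarray:
    """Rows carrying ``allele`` at the focal site with enough genotyped sites."""
    genotyped = np.mean(h.alleles != MISSING, axis=1) * 100.0
    rows = np.flatnonzero(
        (h.alleles[:, focal_idx] == allele) & (genotyped >= min_geno)
    )
    return rows


def ehh_curve(
    h: HaplotypeMatrix,
    focal_position: int,
    allele: int,
    min_geno: float = 99.999,
    missing_policy: str = "own_group",
) -> np.ndarray:
    """EHH of one core allele at every site of the matrix.

    EHH at site x is sum_g C(n_g, 2) / C(n, 2) where the n core haplotypes
    are partitioned into groups g identical over [focal..x].  Computed
    independently leftward and rightward; EHH at the focal site is 1.
    Haplotypes genotyped at fewer than ``min_geno`` percent of sites are
    excluded.  A missing allele inside the extension makes the haplotype its
    own group from that point (``missing_policy='own_group'``, conservative
    decay) or drops it (``'drop'``).
    """
    f_idx = h.site_index(focal_position)
    rows = _core_rows(h, f_idx, allele, min_geno)
    n = rows.size
    if n < 2:
        raise HaplodivError("EHH undefined: fewer than 2 core haplotypes")
    out = np.zeros(h.n_sites)
    denom = n * (n - 1) / 2.0

    for direction in (-1, 1):
        sites = (
            range(f_idx, -1, -1) if direction == -1 else range(f_idx, h.n_sites)
        )
        # partition refinement with integer group ids
        gid = [0] * n
        alive = [True] * n
        fresh = 1  # next unused group id
        for s in sites:
            col = h.alleles[rows, s]
            remap: dict[tuple[int, int], int] = {}
            for i in range(n):
                if not alive[i]:
                    continue
                a = int(col[i])
                if a == MISSING:
                    if missing_policy == "drop":
                        alive[i] = False
                        continue
                    gid[i] = fresh  # its own group from here on
                    fresh += 1
                    continue
                key = (gid[i], a)
                g = remap.get(key)
                if g is None:
                    g = remap[key] = fresh
                    fresh += 1
                gid[i] = g
            counts: dict[int, int] = {}
            for i in range(n):
                if alive[i]:
                    counts[gid[i]] = counts.get(gid[i], 0) + 1
            if missing_policy == "drop":
                m = sum(counts.values())
                d = m * (m - 1) / 2.0
            else:
                d = denom
            out[s] = (
                sum(c * (c - 1) / 2.0 for c in counts.values()) / d if d else 0.0
            )
    out[f_idx] = 1.0
    return out


def ehh_profile(
    h: HaplotypeMatrix,
    focal_position: int,
    hap_rows: np.ndarray | None = None,
    min_geno: float = 99.999,
    region_threshold: float = 0.05,
    high_threshold: float = 0.2,
    span_threshold: float = 0.5,
    cr_seed: int = 0,
) -> EHHProfile:
    """Full EHH analysis of one focal SNP on (a subset of) the matrix."""
    sub = h if hap_rows is None else h.take_haplotypes(hap_rows)
    f_idx = sub.site_index(focal_position)
    maf = sub.minor_frequency(f_idx)
    curves = {}
    counts = {}
    for allele in (0, 1):
        curves[allele] = ehh_curve(sub, focal_position, allele, min_geno)
        counts[allele] = int(_core_rows(sub, f_idx, allele, min_geno).size)
    profile = EHHProfile(
        focal_position=focal_position,
        positions=sub.positions.copy(),
        ehh_ancestral=curves[0],
        ehh_derived=curves[1],
        core_counts=counts,
        maf=maf,
    )
    profile.ehh_region = ehh_regions(profile, region_threshold)[0]
    high_region, _, high_len = ehh_regions(profile, high_threshold)
    profile.high_ehh_region = high_region
    profile.high_ehh_length = high_len
    for allele in (0, 1):
        for direction in ("left", "right"):
            profile.bifurcations.append(
                bifurcation_graph(
                    sub, focal_position, allele, high_region,
                    direction=direction, min_geno=min_geno,
                )
            )
    as_symbol = allelic_selection(profile, span_threshold)
    cr_symbol, cr_interval = constrained_region(
        profile.bifurcations, high_region, seed=cr_seed
    )
    profile.selection = SelectionCall(
        as_symbol=as_symbol, cr_symbol=cr_symbol, maf=maf, cr_interval=cr_interval
    )
    return profile


def ehh_regions(
    profile: EHHProfile, threshold: float
) -> tuple[tuple[int, int], tuple[int, int], int]:
    """Maximal interval around the focal SNP where both alleles' EHH >= threshold.

    Returns ``(region, region, length)`` where length is end - start + 1 in
    bp between the outermost qualifying variant positions.  The degenerate
    region is the focal site alone.
    """
    pos = profile.positions
    f_idx = int(np.searchsorted(pos, profile.focal_position))
    both = (profile.ehh_ancestral >= threshold) & (profile.ehh_derived >= threshold)
    left = f_idx
    while left - 1 >= 0 and both[left - 1]:
        left -= 1
    right = f_idx
    while right + 1 < len(pos) and both[right + 1]:
        right += 1
    region = (int(pos[left]), int(pos[right]))
    return region, region, int(region[1] - region[0] + 1)


def bifurcation_graph(
    h: HaplotypeMatrix,
    focal_position: int,
    allele: int,
    region: tuple[int, int],
    direction: str = "right",
    min_geno: float = 99.999,
) -> BifurcationGraph:
    """Haplotype bifurcation structure for one core allele and direction.

    Starting from the focal allele and walking outward within ``region``,
    each branch splits whenever the site is polymorphic among the branch's
    haplotypes.  Positions where two or more distinct branches split at the
    same site are recorded as multi-branch bifurcation sites (a
    recombination signature).
    """
    f_idx = h.site_index(focal_position)
    rows = _core_rows(h, f_idx, allele, min_geno)
    if rows.size < 2:
        raise HaplodivError("bifurcation graph needs >= 2 core haplotypes")
    root = BifurcationNode(position=focal_position, width=int(rows.size))
    branches: list[tuple[BifurcationNode, np.ndarray]] = [(root, rows)]
    sites = (
        [s for s in range(f_idx + 1, h.n_sites) if region[0] <= h.positions[s] <= region[1]]
        if direction == "right"
        else [s for s in range(f_idx - 1, -1, -1) if region[0] <= h.positions[s] <= region[1]]
    )
    bif_positions: list[int] = []
    multi: list[int] = []
    for s in sites:
        pos = int(h.positions[s])
        new_branches: list[tuple[BifurcationNode, np.ndarray]] = []
        n_splitting = 0
        for node, members in branches:
            col = h.alleles[members, s]
            parts = []
            for val in (0, 1, MISSING):
                sel = members[col == val]
                if sel.size:
                    parts.append(sel)
            if len(parts) > 1 and members.size > 1:
                n_splitting += 1
                for sel in parts:
                    child = BifurcationNode(position=pos, width=int(sel.size))
                    node.children.append(child)
                    new_branches.append((child, sel))
            else:
                new_branches.append((node, members))
        if n_splitting >= 1:
            bif_positions.append(pos)
        if n_splitting >= 2:
            multi.append(pos)
        branches = new_branches
    return BifurcationGraph(
        allele=allele,
        direction=direction,
        root=root,
        bifurcation_positions=bif_positions,
        multi_branch_positions=multi,
    )


def _span_at(profile: EHHProfile, allele: int, threshold: float) -> float:
    """Two-sided bp span where the allele's EHH stays >= threshold."""
    curve = profile.ehh_derived if allele == 1 else profile.ehh_ancestral
    pos = profile.positions
    f_idx = int(np.searchsorted(pos, profile.focal_position))
    left = f_idx
    while left - 1 >= 0 and curve[left - 1] >= threshold:
        left -= 1
    right = f_idx
    while right + 1 < len(pos) and curve[right + 1] >= threshold:
        right += 1
    return float(pos[right] - pos[left])


def allelic_selection(
    profile: EHHProfile, span_threshold: float = 0.5, maf_min: float = 0.1
) -> str:
    """Allelic-selection symbol from the EHH span ratio at EHH = 0.5.

    ratio = shorter span / longer span; bins (0, 0.1] -> '++',
    (0.1, 0.2] -> '+', (0.2, 0.4] -> '+/-', (0.4, 1] -> '-'.  Not applied
    ('n/a') when the focal MAF is not more than ``maf_min`` (rare alleles
    carry long haplotypes simply because they are young).
    """
    if profile.maf <= maf_min:
        return "n/a"
    spans = [_span_at(profile, a, span_threshold) for a in (0, 1)]
    lo, hi = min(spans), max(spans)
    if hi == 0:
        return "-"
    ratio = lo / hi
    if ratio <= 0.1:
        return "++"
    if ratio <= 0.2:
        return "+"
    if ratio <= 0.4:
        return "+/-"
    return "-"


def constrained_region(
    graphs: list[BifurcationGraph],
    region: tuple[int, int],
    seed: int = 0,
    n_mc: int = 2000,
    p_cut: float = 0.05,
    gap_frac: float = 0.25,
    min_positions: int = 5,
) -> tuple[str, tuple[int, int] | None]:
    """Constrained-region symbol from the skew of bifurcation positions.

    Pools bifurcation positions of both alleles inside the high-EHH region
    and tests their uniformity with a largest-gap statistic against a
    Monte-Carlo null of uniform order statistics.  '+' when the gap is both
    significant (p < ``p_cut``) and wide (> ``gap_frac`` of the region);
    '+/-' when exactly one condition holds; '-' otherwise.  The flagged
    subinterval is the largest gap.
    """
    lo, hi = region
    length = hi - lo
    positions = sorted(
        {
            p
            for g in graphs
            for p in g.bifurcation_positions
            if lo <= p <= hi
        }
    )
    if len(positions) < min_positions or length <= 0:
        warnings.warn(
            "too few bifurcation positions for a constrained-region test",
            stacklevel=2,
        )
        return "-", None
    pts = np.array([lo] + positions + [hi], dtype=float)
    gaps = np.diff(pts)
    g_max = float(gaps.max())
    k = len(positions)
    rng = np.random.default_rng(seed)
    sims = rng.uniform(0.0, float(length), size=(n_mc, k))
    sims.sort(axis=1)
    padded = np.concatenate(
        [np.zeros((n_mc, 1)), sims, np.full((n_mc, 1), float(length))], axis=1
    )
    null_max = np.diff(padded, axis=1).max(axis=1)
    p_val = float(np.mean(null_max >= g_max))
    wide = g_max > gap_frac * length
    signif = p_val < p_cut
    i_max = int(np.argmax(gaps))
    interval = (int(pts[i_max]), int(pts[i_max + 1]))
    if signif and wide:
        return "+", interval
    if signif or wide:
        return "+/-", interval
    return "-", interval
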