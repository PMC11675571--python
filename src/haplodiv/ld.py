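"""LD-based locus definition around a focal SNP.

A locus is the set of SNPs within a window of the focal SNP whose haplotype
r^2 with it meets a threshold; the locus span is the min..max member
position (1-based inclusive, length = end - start + 1).  A one-dimensional
density-based clustering step (DBSCAN semantics) can trim distant
duplicated/spurious members, keeping the cluster that contains the focal
SNP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    MISSING,
    HaplodivError,
    HaplotypeMatrix,
    UndefinedStatisticError,
)

__all__ = [
    "LDParams",
    "LocusDefinition",
    "haplotype_r2",
    "choose_focal_snp",
    "define_locus",
    "density_trim",
    "write_locus_bed",
    "write_locus_json",
]


@dataclass
class LDParams:
    r2_threshold: float = 0.8
    window: int = 200_000  # bp, each side of the focal SNP
    dbscan_eps: float = 50_000.0
    dbscan_minpts: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass
class LocusDefinition:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    focal_position: int
    focal_name: str = "focal"
    member_positions: np.ndarray = field(default_factory=lambda: np.array([], np.int64))
    member_r2: np.ndarray = field(default_factory=lambda: np.array([], float))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if not (self.start <= self.focal_position <= self.end):
            raise ValueError("focal SNP must lie within the locus span")


def haplotype_r2(h: HaplotypeMatrix, site_i: int, site_j: int) -> float:
    """Haplotype-based r^2 between two sites (column indices).

    r^2 = D^2 / (pA(1-pA) pB(1-pB)) with D = p_AB - pA pB, computed on
    haplotypes observed at both sites (pairwise-complete).  Raises
    :class:`UndefinedStatisticError` when either site is monomorphic among
    those haplotypes.
    """
    a = h.alleles[:, site_i]
    b = h.alleles[:, site_j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if a.size == 0:
        raise UndefinedStatisticError("no haplotypes observed at both sites")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise UndefinedStatisticError("monomorphic site: r^2 undefined")
    pab = np.mean(a * b)
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def choose_focal_snp(candidate_positions) -> int:
    """Pick the centrally located SNP among perfectly associated candidates.

    Returns the position closest to the median of the candidate positions;
    ties break to the lower coordinate.
    """
    pos = np.asarray(sorted(candidate_positions), dtype=np.int64)
    if pos.size == 0:
        raise ValueError("candidate set must be non-empty")
    med = np.median(pos)
    dist = np.abs(pos - med)
    return int(pos[np.argmin(dist)])  # argmin takes the first (lower) on ties


def define_locus(
    h: HaplotypeMatrix,
    focal_position: int,
    params: LDParams | None = None,
    focal_name: str = "focal",
) -> LocusDefinition:
    """LD locus around a focal SNP: members have r^2 >= threshold within the window."""
    params = params or LDParams()
    f_idx = h.site_index(focal_position)
    col = h.alleles[:, f_idx]
    obs = col[col != MISSING]
    if obs.size == 0 or len(set(obs.tolist())) < 2:
        raise UndefinedStatisticError("focal SNP is monomorphic")
    members: list[int] = []
    r2s: list[float] = []
    in_window = np.flatnonzero(
        np.abs(h.positions - focal_position) <= params.window
    )
    for s in in_window:
        if s == f_idx:
            members.append(int(h.positions[s]))
            r2s.append(1.0)
            continue
        try:
            r2 = haplotype_r2(h, f_idx, int(s))
        except UndefinedStatisticError:
            continue
        if r2 >= params.r2_threshold:
            members.append(int(h.positions[s]))
            r2s.append(r2)
    order = np.argsort(members)
    member_positions = np.asarray(members, dtype=np.int64)[order]
    member_r2 = np.asarray(r2s, dtype=float)[order]
    return LocusDefinition(
        chrom=h.chrom,
        start=int(member_positions.min()),
        end=int(member_positions.max()),
        focal_position=focal_position,
        focal_name=focal_name,
        member_positions=member_positions,
        member_r2=member_r2,
    )


def density_trim(
    member_positions,
    focal_position: int,
    params: LDParams | None = None,
) -> tuple[tuple[int, int], list[int]]:
    """1-D DBSCAN over member positions; keep the focal SNP's cluster.

    Returns ``((start, end), excluded_positions)`` where the interval spans
    the density cluster containing the focal SNP.  Core points have at least
    ``minpts`` members (themselves included) within ``eps``; clusters are
    eps-chains of core points plus their border points — for sorted 1-D data
    this reduces to a sorted scan.  If the focal SNP is noise, raises
    :class:`HaplodivError` advising a parameter change.
    """
    params = params or LDParams()
    pos = np.asarray(sorted(member_positions), dtype=np.int64)
    if focal_position not in pos:
        raise ValueError("focal SNP must be among the member positions")
    eps, minpts = params.dbscan_eps, params.dbscan_minpts
    n = pos.size
    # neighbour counts within eps (inclusive of self)
    left = np.searchsorted(pos, pos - eps, side="left")
    right = np.searchsorted(pos, pos + eps, side="right")
    is_core = (right - left) >= minpts
    labels = np.full(n, -1, dtype=int)
    cluster = -1
    for i in range(n):
        if not is_core[i] or labels[i] != -1:
            continue
        cluster += 1
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not is_core[j]:
                continue
            for k in range(left[j], right[j]):
                if labels[k] == -1:
                    labels[k] = cluster
                    if is_core[k]:
                        stack.append(k)
    f_i = int(np.searchsorted(pos, focal_position))
    if labels[f_i] == -1:
        raise HaplodivError(
            "focal SNP classified as noise by density clustering; "
            "decrease minpts or increase eps"
        )
    keep = labels == labels[f_i]
    interval = (int(pos[keep].min()), int(pos[keep].max()))
    excluded = [int(p) for p in pos[~keep]]
    return interval, excluded


def write_locus_bed(locus: LocusDefinition, path: str | Path) -> Path:
    """BED-like TSV (chrom, start-1, end, name)."""
    path = Path(path)
    path.write_text(
        f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t{locus.focal_name}\n"
    )
    return path


def write_locus_json(locus: LocusDefinition, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "length": locus.length,
                "focal_position": locus.focal_position,
                "focal_name": locus.focal_name,
                "member_positions": [int(p) for p in locus.member_positions],
                "member_r2": [float(r) for r in locus.member_r2],
            },
            indent=1,
        )
    )
    return path
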