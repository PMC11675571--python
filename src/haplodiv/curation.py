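"""Read- and genotype-level data-validation rules.

Mirrors the curation applied to the short-read and phasing data behind the
analysis panel: masking of reads with locally clustered mismatches, discard
of PCR/optical duplicates, a phase-consistency check of re-phased
heterozygous sites against their nearest heterozygous neighbours, and an
iterative imputation control loop that only accepts rounds which reduce
missingness and phase uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .core import MISSING, HaplotypeMatrix

__all__ = [
    "AlignedRead",
    "PhasingState",
    "mask_read",
    "drop_duplicates",
    "phase_consistency_check",
    "iterate_imputation",
    "nearest_neighbor_imputer",
    "read_reads_tsv",
]

PHASED = "phased"
UNPHASED = "unphased"
UNKNOWN_PHASE = "unknown_phase"
MISSING_STATUS = "missing"


@dataclass(frozen=True)
class AlignedRead:
    """Simplified aligned read: bases, qualities, mismatch offsets, dup flag."""

    start: int  # 1-based reference position of the first base
    bases: str
    quals: tuple[int, ...]
    mismatches: tuple[int, ...] = ()  # 0-based offsets within the read
    duplicate: bool = False
    site_quality: float = 0.0  # informational; sum of supporting qualities

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError("quality string length must equal base length")
        if any(m < 0 or m >= len(self.bases) for m in self.mismatches):
            raise ValueError("mismatch offsets must fall within the read")


def mask_read(
    read: AlignedRead, window: int = 10, max_mismatch: int = 2, whole_read: bool = True
) -> AlignedRead:
    """Mask a read whose mismatches cluster beyond ``max_mismatch`` per window.

    If any ``window``-base stretch holds more than ``max_mismatch`` mismatches
    against the reference, base calls are replaced by ``N`` and qualities by
    0.  By default the whole read is masked (the conservative reading);
    ``whole_read=False`` masks only the offending windows.
    """
    mism = np.zeros(len(read.bases), dtype=bool)
    mism[list(read.mismatches)] = True
    counts = np.convolve(mism.astype(int), np.ones(window, dtype=int), mode="valid") \
        if len(mism) >= window else np.array([int(mism.sum())])
    offending = counts > max_mismatch
    if not offending.any():
        return read
    if whole_read:
        return replace(
            read, bases="N" * len(read.bases), quals=tuple([0] * len(read.bases))
        )
    mask = np.zeros(len(read.bases), dtype=bool)
    for start in np.flatnonzero(offending):
        mask[start : start + window] = True
    bases = "".join("N" if m else b for m, b in zip(mask, read.bases))
    quals = tuple(0 if m else q for m, q in zip(mask, read.quals))
    return replace(read, bases=bases, quals=quals)


def drop_duplicates(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Discard reads whose PCR/optical-duplicate flag is set; order kept."""
    return [r for r in reads if not r.duplicate]


@dataclass
class PhasingState:
    """Phasing state of one site in one sample."""

    position: int
    genotype: tuple[int, int]
    orientation: int = 0  # 0/1: which chromosome copy carries the first allele
    status: str = PHASED

    def __post_init__(self) -> None:
        if self.status == UNKNOWN_PHASE and not self.is_het:
            raise ValueError("unknown_phase applies only to heterozygous sites")

    @property
    def is_het(self) -> bool:
        a, b = self.genotype
        return a != b and a != MISSING and b != MISSING


def _relative_orientation(a: PhasingState, b: PhasingState) -> int:
    """0 if the two het sites are phased cis-identically, 1 otherwise.

    Absolute phase is arbitrary, so only the orientation of one het site
    relative to another is comparable between phasing rounds.
    """
    return a.orientation ^ b.orientation


def phase_consistency_check(
    before: Sequence[PhasingState],
    after: Sequence[PhasingState],
    n_neighbors: int = 3,
) -> list[PhasingState]:
    """Flag re-phased het sites whose neighbourhood phase flipped entirely.

    For each heterozygous site the phase orientation relative to each of its
    ``n_neighbors`` nearest heterozygous neighbours is compared between the
    two phasing rounds; if every compared orientation disagrees, the site's
    status becomes ``unknown_phase``.  Homozygous sites are never touched.
    """
    if len(before) != len(after):
        raise ValueError("before/after must cover identical sites")
    for x, y in zip(before, after):
        if x.position != y.position:
            raise ValueError("before/after must cover identical sites")
    het_idx = [i for i, st in enumerate(after) if st.is_het and before[i].is_het]
    out: list[PhasingState] = []
    for i, st in enumerate(after):
        st = replace(st)
        if i in het_idx:
            others = sorted(
                (j for j in het_idx if j != i),
                key=lambda j: (abs(after[j].position - st.position), after[j].position),
            )[:n_neighbors]
            if others:
                disagree = [
                    _relative_orientation(after[i], after[j])
                    != _relative_orientation(before[i], before[j])
                    for j in others
                ]
                if all(disagree):
                    st.status = UNKNOWN_PHASE
        out.append(st)
    return out


def _missing_unphased_counts(h: HaplotypeMatrix) -> tuple[int, int]:
    missing = int(np.sum(h.alleles == MISSING))
    unphased = int(np.sum(~h.phased & (h.alleles != MISSING)))
    return missing, unphased


def nearest_neighbor_imputer(h: HaplotypeMatrix) -> HaplotypeMatrix:
    """Fill each missing allele from the Hamming-nearest haplotype.

    Distance is computed over sites observed in both haplotypes; ties break
    to the lowest row index.  Filled sites are marked phased.
    """
    alleles = h.alleles.copy()
    phased = h.phased.copy()
    n = h.n_haplotypes
    obs = alleles != MISSING
    for i in range(n):
        miss_sites = np.flatnonzero(~obs[i])
        if miss_sites.size == 0:
            continue
        best, best_d = None, None
        for j in range(n):
            if j == i:
                continue
            both = obs[i] & obs[j]
            if not both.any():
                continue
            d = np.mean(alleles[i, both] != alleles[j, both])
            if best_d is None or d < best_d:
                best, best_d = j, d
        if best is None:
            continue
        for s in miss_sites:
            if obs[best][s]:
                alleles[i, s] = alleles[best, s]
                phased[i, s] = True
    return replace(h, alleles=alleles, phased=phased)


def iterate_imputation(
    h: HaplotypeMatrix,
    imputer: Callable[[HaplotypeMatrix], HaplotypeMatrix] | None = None,
    max_rounds: int = 10,
) -> HaplotypeMatrix:
    """Repeat imputation/re-phasing while it keeps reducing uncertainty.

    A round is accepted only if it strictly decreases the total of missing
    alleles and unphased genotypes; the loop stops at the first rejected
    round (whose output is discarded) or after ``max_rounds``.
    """
    if imputer is None:
        imputer = nearest_neighbor_imputer
    current = h
    cur_counts = _missing_unphased_counts(current)
    for _ in range(max_rounds):
        if sum(cur_counts) == 0:
            break
        candidate = imputer(current)
        cand_counts = _missing_unphased_counts(candidate)
        if sum(cand_counts) >= sum(cur_counts):
            break  # no strict improvement (or regression): reject round
        current, cur_counts = candidate, cand_counts
    return current


def read_reads_tsv(path) -> list[AlignedRead]:
    """Simplified read table: pos, bases, quals, mismatches, dupflag.

    quals are comma-separated integers; mismatches comma-separated 0-based
    offsets (empty field for none); dupflag 0/1.
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pos, bases, quals, mism, dup = line.split("\t")
            reads.append(
                AlignedRead(
                    start=int(pos),
                    bases=bases,
                    quals=tuple(int(q) for q in quals.split(",") if q),
                    mismatches=tuple(int(m) for m in mism.split(",") if m),
                    duplicate=bool(int(dup)),
                )
            )
    return reads
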