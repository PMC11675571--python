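"""Core containers shared by every analysis stage.

The central object is :class:`HaplotypeMatrix`, a phased allele matrix
(haplotypes x SNP sites) with 1-based genomic positions, ancestral/derived
allele coding (0 = ancestral, 1 = derived, ``MISSING`` = -1) and a population
label per haplotype.  Archaic hominin haplotypes and the outgroup used for
rooting travel in the same matrix under reserved labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for a missing (uncalled / deleted) allele.
MISSING: int = -1

#: Continental / reserved group codes.
GROUP_AFRICAN = "AFR"
GROUP_EUROPEAN = "EUR"
GROUP_ASIAN = "ASN"
GROUP_AMERICAN = "AMR"
GROUP_NEANDERTHAL = "NEA"
GROUP_DENISOVAN = "DEN"
GROUP_OUTGROUP = "OUT"

MODERN_GROUPS = (GROUP_AFRICAN, GROUP_EUROPEAN, GROUP_ASIAN, GROUP_AMERICAN)
ARCHAIC_GROUPS = (GROUP_NEANDERTHAL, GROUP_DENISOVAN)
TARGET_GROUPS = (GROUP_EUROPEAN, GROUP_ASIAN, GROUP_AMERICAN)

#: 1000-Genomes-style population code -> continental group.  The African
#: reference grouping (LWK, YRI, ASW) follows common S* practice.
POP_TO_GROUP: dict[str, str] = {
    "LWK": GROUP_AFRICAN, "YRI": GROUP_AFRICAN, "ASW": GROUP_AFRICAN,
    "CEU": GROUP_EUROPEAN, "GBR": GROUP_EUROPEAN, "FIN": GROUP_EUROPEAN,
    "IBS": GROUP_EUROPEAN, "TSI": GROUP_EUROPEAN,
    "CHB": GROUP_ASIAN, "CHS": GROUP_ASIAN, "JPT": GROUP_ASIAN,
    "MXL": GROUP_AMERICAN, "PUR": GROUP_AMERICAN, "CLM": GROUP_AMERICAN,
    # group codes map to themselves so synthetic data can label directly
    GROUP_AFRICAN: GROUP_AFRICAN, GROUP_EUROPEAN: GROUP_EUROPEAN,
    GROUP_ASIAN: GROUP_ASIAN, GROUP_AMERICAN: GROUP_AMERICAN,
    GROUP_NEANDERTHAL: GROUP_NEANDERTHAL, GROUP_DENISOVAN: GROUP_DENISOVAN,
    GROUP_OUTGROUP: GROUP_OUTGROUP,
}


class HaplodivError(Exception):
    """Base class for package errors."""


class ConfigurationError(HaplodivError):
    """Invalid configuration (rates, times, thresholds)."""


class UndefinedStatisticError(HaplodivError):
    """A statistic is undefined for the given input (e.g. monomorphic r^2)."""


def group_of(pop_label: str) -> str:
    """Continental/reserved group for a population code.

    Unknown codes are treated as modern 'UNKNOWN' samples.
    """
    return POP_TO_GROUP.get(pop_label, "UNKNOWN")


@dataclass
class HaplotypeMatrix:
    """Phased allele matrix: ``alleles[h, s]`` for haplotype ``h``, site ``s``.

    Parameters
    ----------
    positions
        1-based genomic coordinates, strictly increasing.
    alleles
        int8 matrix, values in {0, 1, MISSING}.
    hap_ids
        Haplotype identifiers, conventionally ``"<sample>_0"`` / ``"<sample>_1"``.
    pop_labels
        Population code per haplotype.
    phased
        Boolean matrix, same shape as ``alleles``; True where the phase of the
        underlying genotype is known.
    chrom
        Chromosome name.
    """

    positions: np.ndarray
    alleles: np.ndarray
    hap_ids: list[str]
    pop_labels: list[str]
    phased: np.ndarray | None = None
    chrom: str = "1"
    ref_alleles: list[str] | None = None
    alt_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        n_hap, n_site = self.alleles.shape
        if len(self.positions) != n_site:
            raise ValueError("positions length does not match allele columns")
        if len(self.hap_ids) != n_hap or len(self.pop_labels) != n_hap:
            raise ValueError("hap_ids/pop_labels length does not match rows")
        if n_site > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.phased is None:
            self.phased = np.ones_like(self.alleles, dtype=bool)
        else:
            self.phased = np.asarray(self.phased, dtype=bool)
            if self.phased.shape != self.alleles.shape:
                raise ValueError("phased flags must match allele matrix shape")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0, 1 or MISSING")
        if self.ref_alleles is None:
            self.ref_alleles = ["A"] * n_site
        if self.alt_alleles is None:
            self.alt_alleles = ["G"] * n_site

    # ------------------------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def groups(self) -> list[str]:
        return [group_of(p) for p in self.pop_labels]

    def hap_indices(self, groups: Iterable[str]) -> np.ndarray:
        """Row indices of haplotypes whose continental group is in *groups*."""
        want = set(groups)
        return np.array(
            [i for i, g in enumerate(self.groups) if g in want], dtype=int
        )

    def site_index(self, position: int) -> int:
        """Column index of a 1-based genomic position."""
        idx = int(np.searchsorted(self.positions, position))
        if idx >= self.n_sites or self.positions[idx] != position:
            raise KeyError(f"no site at position {position}")
        return idx

    def take_sites(self, site_idx: Sequence[int] | np.ndarray) -> "HaplotypeMatrix":
        site_idx = np.asarray(site_idx, dtype=int)
        return replace(
            self,
            positions=self.positions[site_idx],
            alleles=self.alleles[:, site_idx],
            phased=self.phased[:, site_idx],
            ref_alleles=[self.ref_alleles[i] for i in site_idx],
            alt_alleles=[self.alt_alleles[i] for i in site_idx],
        )

    def take_haplotypes(self, hap_idx: Sequence[int] | np.ndarray) -> "HaplotypeMatrix":
        hap_idx = np.asarray(hap_idx, dtype=int)
        return replace(
            self,
            alleles=self.alleles[hap_idx, :],
            phased=self.phased[hap_idx, :],
            hap_ids=[self.hap_ids[i] for i in hap_idx],
            pop_labels=[self.pop_labels[i] for i in hap_idx],
        )

    def derived_frequency(self, site: int, hap_idx: np.ndarray | None = None) -> float:
        """Derived-allele frequency at a site among non-missing haplotypes."""
        col = self.alleles[:, site] if hap_idx is None else self.alleles[hap_idx, site]
        obs = col[col != MISSING]
        if obs.size == 0:
            return float("nan")
        return float(np.mean(obs == 1))

    def minor_frequency(self, site: int, hap_idx: np.ndarray | None = None) -> float:
        p = self.derived_frequency(site, hap_idx)
        return min(p, 1.0 - p)

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.phased, other.phased)
            and self.hap_ids == other.hap_ids
            and self.pop_labels == other.pop_labels
        )


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated locus.

    ``tracts`` maps a haplotype id to a list of introgressed intervals
    (1-based, inclusive, non-overlapping, sorted).  ``sweep_carriers`` lists
    haplotype ids carrying the swept haplotype; ``ancestral`` holds the
    ancestral allele code per site (always 0 in the simulator's coding).
    """

    tracts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    sweep_carriers: list[str] = field(default_factory=list)
    sweep_site: int | None = None
    ancestral: np.ndarray | None = None

    @property
    def n_tracts(self) -> int:
        return sum(len(t) for t in self.tracts.values())

    def carriers(self) -> set[str]:
        """Haplotype ids with at least one introgressed tract."""
        return {h for h, t in self.tracts.items() if t}

    def to_json_dict(self) -> dict:
        return {
            "tracts": {h: [list(iv) for iv in t] for h, t in self.tracts.items()},
            "sweep_carriers": list(self.sweep_carriers),
            "sweep_site": self.sweep_site,
            "ancestral": None if self.ancestral is None else [int(a) for a in self.ancestral],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthRecord":
        anc = d.get("ancestral")
        return cls(
            tracts={h: [tuple(iv) for iv in t] for h, t in d.get("tracts", {}).items()},
            sweep_carriers=list(d.get("sweep_carriers", [])),
            sweep_site=d.get("sweep_site"),
            ancestral=None if anc is None else np.asarray(anc, dtype=np.int8),
        )
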