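"""Coalescent-style synthetic phased-haplotype data with known truth.

The generator emulates the structure of the study inputs: a phased
African-like reference panel and a Eurasian-like target panel, one or two
archaic (Neanderthal / Denisovan) genomes diverged an order of magnitude
earlier, and a deeply diverged outgroup sequence used for rooting.  Archaic
introgression is modelled as a single pulse into the target population, and
the introgressed tracts carried by each sampled haplotype are recorded as
ground truth.  A partial selective sweep can be overlaid on the target panel
to make extended-haplotype-homozygosity asymmetry detectable.

Demography (backwards in time, all population sizes equal ``Ne``)::

    REF  TGT      NEA  DEN      OUT
      \\  /          \\  /         |
       MOD (t_mod)   ARC (t_nd)  |
         \\            /          |
          HOM (t_arc)            |
              \\                 /
               ROOT (t_out)

with an introgression pulse TGT <- NEA of proportion ``f`` at
``introgression_time < t_mod``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import msprime
import numpy as np

from .core import (
    GROUP_AFRICAN,
    GROUP_DENISOVAN,
    GROUP_EUROPEAN,
    GROUP_NEANDERTHAL,
    GROUP_OUTGROUP,
    MISSING,
    ConfigurationError,
    HaplotypeMatrix,
    TruthRecord,
)

__all__ = ["SweepConfig", "SimulationConfig", "simulate_locus"]


@dataclass
class SweepConfig:
    """Partial selective sweep overlaid on the target panel.

    ``position`` is the selected site (bp, 1-based); ``None`` puts it at the
    locus midpoint.  ``final_freq`` is the derived-allele frequency reached in
    the target population.  ``tract_mean_bp`` is the mean one-sided extent of
    the hitchhiking haplotype copied onto each carrier, i.e. roughly
    1/(r * T_sweep) for a sweep lasting T_sweep generations.
    """

    position: int | None = None
    final_freq: float = 0.8
    tract_mean_bp: float = 100_000.0


@dataclass
class SimulationConfig:
    """Parameters of one simulated locus (scaled-down human-like defaults)."""

    seed: int = 1
    n_ref: int = 100
    n_tgt: int = 100
    n_neanderthal: int = 2
    n_denisovan: int = 2
    n_outgroup: int = 2
    locus_length: int = 200_000
    mutation_rate: float = 1.2e-8
    recombination_rate: float = 1.0e-8
    Ne: float = 10_000.0
    archaic_Ne: float = 2_500.0  # archaic hominin Ne was much smaller
    split_time_modern: float = 3_000.0
    split_time_archaic: float = 30_000.0
    nea_den_split: float | None = None  # default 0.6 * split_time_archaic
    outgroup_split: float | None = None  # default 10 * split_time_archaic
    introgression_fraction: float = 0.0
    # chosen so the mean introgressed tract, 1/(r*t) = 100 kb, is on the
    # scale of the intact archaic haplotypes spanning the studied loci
    introgression_time: float = 1_000.0
    # loci under study are preselected introgression candidates, so by
    # default the simulation conditions on >= 1 introgressed lineage
    condition_on_introgression: bool = True
    sweep: SweepConfig | None = None
    missing_rate: float = 0.0
    unphase_rate: float = 0.0
    chrom: str = "1"
    ref_group: str = GROUP_AFRICAN
    tgt_group: str = GROUP_EUROPEAN

    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")
        for name in ("mutation_rate", "recombination_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0.0 <= self.introgression_fraction <= 1.0):
            raise ConfigurationError("introgression_fraction must be in [0, 1]")
        for name in ("missing_rate", "unphase_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.locus_length <= 0 or self.Ne <= 0 or self.archaic_Ne <= 0:
            raise ConfigurationError("locus_length and Ne must be positive")
        if any(n < 0 or n % 2 for n in (self.n_ref, self.n_tgt, self.n_neanderthal,
                                        self.n_denisovan, self.n_outgroup)):
            raise ConfigurationError("haplotype counts must be even and >= 0")
        if not (self.split_time_archaic > self.split_time_modern):
            raise ConfigurationError("archaic split must predate the modern split")
        if self.introgression_fraction > 0 and not (
            self.introgression_time < self.split_time_modern
        ):
            raise ConfigurationError("introgression must postdate the modern split")
        t_nd = self.nea_den_split_time
        if not (0 < t_nd < self.split_time_archaic):
            raise ConfigurationError("Neanderthal-Denisovan split must predate 0 and "
                                     "postdate the archaic split")
        if self.outgroup_split_time <= self.split_time_archaic:
            raise ConfigurationError("outgroup split must predate the archaic split")
        if self.sweep is not None and not (0 < self.sweep.final_freq <= 1):
            raise ConfigurationError("sweep final frequency must be in (0, 1]")

    @property
    def nea_den_split_time(self) -> float:
        return (
            self.nea_den_split
            if self.nea_den_split is not None
            else 0.6 * self.split_time_archaic
        )

    @property
    def outgroup_split_time(self) -> float:
        return (
            self.outgroup_split
            if self.outgroup_split is not None
            else 10.0 * self.split_time_archaic
        )


def _demography(cfg: SimulationConfig) -> msprime.Demography:
    dem = msprime.Demography()
    for name in ("REF", "TGT", "NEA", "DEN", "OUT", "MOD", "ARC", "HOM", "ROOT"):
        size = cfg.archaic_Ne if name in ("NEA", "DEN", "ARC") else cfg.Ne
        dem.add_population(name=name, initial_size=size)
    if cfg.introgression_fraction > 0:
        dem.add_mass_migration(
            time=cfg.introgression_time,
            source="TGT",
            dest="NEA",
            proportion=cfg.introgression_fraction,
        )
    dem.add_population_split(
        time=cfg.split_time_modern, derived=["REF", "TGT"], ancestral="MOD"
    )
    dem.add_population_split(
        time=cfg.nea_den_split_time, derived=["NEA", "DEN"], ancestral="ARC"
    )
    dem.add_population_split(
        time=cfg.split_time_archaic, derived=["MOD", "ARC"], ancestral="HOM"
    )
    dem.add_population_split(
        time=cfg.outgroup_split_time, derived=["HOM", "OUT"], ancestral="ROOT"
    )
    dem.sort_events()
    return dem


def _hap_labels(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    """(hap_ids, pop_labels) in sampling order REF, TGT, NEA, DEN, OUT."""
    hap_ids: list[str] = []
    pop_labels: list[str] = []
    blocks = [
        (cfg.n_ref, cfg.ref_group, "R"),
        (cfg.n_tgt, cfg.tgt_group, "T"),
        (cfg.n_neanderthal, GROUP_NEANDERTHAL, "N"),
        (cfg.n_denisovan, GROUP_DENISOVAN, "D"),
        (cfg.n_outgroup, GROUP_OUTGROUP, "O"),
    ]
    for n, group, prefix in blocks:
        for ind in range(n // 2):
            for copy in (0, 1):
                hap_ids.append(f"{prefix}{ind:03d}_{copy}")
                pop_labels.append(group)
    return hap_ids, pop_labels


def _introgressed_tracts(
    ts, nea_pop_id: int, tgt_sample_ids: np.ndarray, cfg: SimulationConfig
) -> dict[int, list[tuple[int, int]]]:
    """Per-target-sample introgressed intervals from migration records.

    A lineage that migrates (backwards in time) into the Neanderthal
    population at the pulse time carries archaic ancestry forward; every
    target sample descending from that lineage over the migrated interval is
    a tract carrier there.
    """
    tgt_set = set(int(s) for s in tgt_sample_ids)
    tracts: dict[int, list[tuple[int, int]]] = {int(s): [] for s in tgt_sample_ids}
    pulses = [
        m
        for m in ts.migrations()
        if m.dest == nea_pop_id and abs(m.time - cfg.introgression_time) < 1e-9
    ]
    if not pulses:
        return tracts
    for tree in ts.trees():
        t_left, t_right = tree.interval.left, tree.interval.right
        for m in pulses:
            left = max(m.left, t_left)
            right = min(m.right, t_right)
            if left >= right:
                continue
            for s in tree.samples(m.node) if m.node < ts.num_nodes else ():
                if int(s) in tgt_set:
                    # 1-based inclusive bp interval
                    tracts[int(s)].append((int(left) + 1, int(np.ceil(right))))
    for s, ivs in tracts.items():
        tracts[s] = _merge_intervals(ivs)
    return tracts


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(iv) for iv in out]


def _apply_sweep(
    alleles: np.ndarray,
    positions: np.ndarray,
    tgt_rows: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[int, list[int]]:
    """Overlay a partial sweep; returns (site index, carrier row indices).

    The selected derived allele rises to ``final_freq`` on a logistic
    trajectory; hitchhiking is emulated by copying the founding haplotype
    onto each carrier over an exponentially distributed flanking extent
    (recombination during the sweep shortens the shared core).
    """
    sw = cfg.sweep
    assert sw is not None
    want_pos = sw.position if sw.position is not None else cfg.locus_length // 2
    # a swept allele is a novel beneficial mutation: prefer sites that are
    # (nearly) ancestral outside the target population
    non_tgt = np.setdiff1d(np.arange(alleles.shape[0]), tgt_rows)
    with np.errstate(invalid="ignore"):
        obs = (alleles[non_tgt] != MISSING).sum(axis=0)
        p_out = (alleles[non_tgt] == 1).sum(axis=0) / np.maximum(obs, 1)
    rare_outside = np.flatnonzero((obs > 0) & (p_out < 0.05))
    pool = rare_outside if rare_outside.size else np.arange(len(positions))
    s = int(pool[np.argmin(np.abs(positions[pool] - want_pos))])
    n_car = max(2, int(round(sw.final_freq * len(tgt_rows))))
    carriers = rng.choice(tgt_rows, size=min(n_car, len(tgt_rows)), replace=False)
    template = alleles[carriers[0], :].copy()
    pos_sel = positions[s]
    for c in carriers:
        left = pos_sel - rng.exponential(sw.tract_mean_bp)
        right = pos_sel + rng.exponential(sw.tract_mean_bp)
        mask = (positions >= left) & (positions <= right)
        alleles[c, mask] = template[mask]
        alleles[c, s] = 1
    non_carriers = np.setdiff1d(tgt_rows, carriers)
    alleles[non_carriers, s] = 0
    return s, [int(c) for c in carriers]


def simulate_locus(cfg: SimulationConfig) -> tuple[HaplotypeMatrix, TruthRecord]:
    """Simulate one phased locus; reproducible bit-for-bit under a fixed seed.

    With ``condition_on_introgression`` (the default) and f > 0, the
    simulation is rejection-sampled until at least one sampled target
    haplotype carries an introgressed tract, emulating the preselection of
    candidate loci with introgression signals.
    """
    cfg.validate()
    attempts = (
        20
        if cfg.introgression_fraction > 0 and cfg.condition_on_introgression
        else 1
    )
    for attempt in range(attempts):
        matrix, truth = _simulate_once(cfg, cfg.seed + 1 + attempt * 7919)
        if attempt == attempts - 1 or truth.carriers():
            return matrix, truth
    return matrix, truth  # pragma: no cover


def _simulate_once(
    cfg: SimulationConfig, msp_seed: int
) -> tuple[HaplotypeMatrix, TruthRecord]:
    dem = _demography(cfg)
    samples = []
    for pop, n in (
        ("REF", cfg.n_ref),
        ("TGT", cfg.n_tgt),
        ("NEA", cfg.n_neanderthal),
        ("DEN", cfg.n_denisovan),
        ("OUT", cfg.n_outgroup),
    ):
        if n > 0:
            samples.append(msprime.SampleSet(n // 2, population=pop, ploidy=2))
    if not samples:
        raise ConfigurationError("at least one haplotype must be sampled")
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=cfg.locus_length,
        recombination_rate=cfg.recombination_rate,
        ploidy=2,
        record_migrations=True,
        random_seed=msp_seed,  # msprime requires seed >= 1
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        model=msprime.BinaryMutationModel(),
        random_seed=msp_seed,
    )

    hap_ids, pop_labels = _hap_labels(cfg)
    geno = ts.genotype_matrix()  # sites x samples, 0/1 under the binary model
    positions = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    alleles = np.asarray(geno.T, dtype=np.int8)
    # collapse any >1 mutations stacked at one discrete position (rare)
    keep = np.concatenate([[True], np.diff(positions) > 0]) if len(positions) else np.array([], bool)
    positions, alleles = positions[keep], alleles[:, keep]

    rng = np.random.default_rng(msp_seed)
    truth = TruthRecord(ancestral=np.zeros(len(positions), dtype=np.int8))

    tgt_rows = np.array(
        [i for i, g in enumerate(pop_labels) if g == cfg.tgt_group], dtype=int
    )
    if cfg.introgression_fraction > 0 and len(tgt_rows):
        nea_pop = dem["NEA"].id
        tgt_samples = np.array(
            [s for s in ts.samples() if ts.node(s).population == dem["TGT"].id]
        )
        raw = _introgressed_tracts(ts, nea_pop, tgt_samples, cfg)
        # sample ids are assigned in sampling order, matching matrix rows
        sample_to_row = dict(zip(tgt_samples.tolist(), tgt_rows.tolist()))
        for s, ivs in raw.items():
            if ivs:
                truth.tracts[hap_ids[sample_to_row[s]]] = ivs

    if cfg.sweep is not None and len(tgt_rows) and len(positions):
        s_idx, carrier_rows = _apply_sweep(alleles, positions, tgt_rows, cfg, rng)
        truth.sweep_site = int(positions[s_idx])
        truth.sweep_carriers = [hap_ids[c] for c in carrier_rows]

    phased = np.ones_like(alleles, dtype=bool)
    n_ind = len(hap_ids) // 2
    if cfg.missing_rate > 0 and len(positions):
        miss = rng.random((n_ind, len(positions))) < cfg.missing_rate
        for ind in np.argwhere(miss)[:, 0:2]:
            i, s = int(ind[0]), int(ind[1])
            alleles[2 * i : 2 * i + 2, s] = MISSING
            phased[2 * i : 2 * i + 2, s] = False
    if cfg.unphase_rate > 0 and len(positions):
        unph = rng.random((n_ind, len(positions))) < cfg.unphase_rate
        for ind in np.argwhere(unph):
            i, s = int(ind[0]), int(ind[1])
            a, b = alleles[2 * i, s], alleles[2 * i + 1, s]
            if a != b and a != MISSING and b != MISSING:  # only hets can be unphased
                phased[2 * i : 2 * i + 2, s] = False

    if len(positions) == 0:
        warnings.warn("simulation produced zero variant sites", stacklevel=2)
    matrix = HaplotypeMatrix(
        positions=positions,
        alleles=alleles,
        hap_ids=hap_ids,
        pop_labels=pop_labels,
        phased=phased,
        chrom=cfg.chrom,
    )
    return matrix, truth
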