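"""End-to-end per-locus pipeline and machine-readable summary reports.

Order of stages: curation -> LD locus definition -> haplotype filtering ->
NJ tree + bootstrap -> S* -> topology classification -> EHH -> representative
selection + reduced median network -> report.  Every stage's intermediate is
written to the output directory; a stage failure is recorded in the report
and the partial outputs are kept.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ARCHAIC_GROUPS,
    GROUP_OUTGROUP,
    MISSING,
    HaplotypeMatrix,
    group_of,
)
from .curation import iterate_imputation
from .ehh import EHHProfile, ehh_profile
from .ld import LDParams, define_locus, write_locus_bed, write_locus_json
from .netrep import (
    annotate_network,
    reduced_median_network,
    select_representatives,
    write_graphml,
)
from .phylogeny import (
    SequenceRecord,
    TreeNode,
    bootstrap_supports,
    classify_topology,
    distance_matrix,
    haplotypes_to_sequences,
    nj_tree,
    root_with_outgroup,
)
from .sstar import SStarConfig, SStarResult, run_sstar
from .vcfio import read_pop_map, read_vcf, write_vcf

__all__ = ["PipelineConfig", "LocusReport", "run_pipeline", "colocalization"]


@dataclass
class PipelineConfig:
    """All tunables of the per-locus pipeline (defaults = study settings)."""

    ld: LDParams = field(default_factory=LDParams)
    sstar: SStarConfig = field(default_factory=SStarConfig)
    n_bootstrap: int = 500
    support_collapse: float = 50.0
    max_deleted_frac: float = 0.005
    ts_tv_ratio: float = 2.0
    rep_limit_range: tuple[int, int] = (14, 21)
    reduction_r: float = 2.0
    min_geno: float = 99.999
    ehh_region_threshold: float = 0.05
    ehh_high_threshold: float = 0.2
    ehh_span_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        for key, val in raw.items():
            if key == "ld":
                cfg.ld = LDParams(**val)
            elif key == "sstar":
                cfg.sstar = SStarConfig(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
                })
            elif key == "rep_limit_range":
                cfg.rep_limit_range = tuple(val)
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        return cfg


@dataclass
class LocusReport:
    """Summary-table row for one locus plus per-cluster annotations."""

    chrom: str = ""
    start: int = 0
    end: int = 0
    length: int = 0
    focal_position: int = 0
    focal_maf: float = float("nan")
    n_snps: int = 0
    pattern: str = ""
    typical_ooa: bool | None = None
    nd_shared_class: str = "-"
    pattern_type: str = "other"
    grade_counts: dict = field(default_factory=dict)
    colocalization: bool | None = None
    as_symbol: str = "n/a"
    cr_symbol: str = "-"
    high_ehh_length: int = 0
    ehh_maf_flag: str = ""  # '0.1>=' (rare) or '0.1<'
    clusters: list = field(default_factory=list)
    stages: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


def colocalization(
    clusters: list[set[str]],
    grades: dict[str, str],
    archaic_ids: set[str],
) -> tuple[list[bool], bool]:
    """Per-cluster archaic/S* colocalization flags and the overall flag.

    A cluster colocalizes when it holds at least one archaic haplotype and
    at least one modern haplotype of introgression grade I or II.
    """
    flags = []
    for cluster in clusters:
        has_archaic = bool(cluster & archaic_ids)
        has_grade = any(
            grades.get(m, "low") in ("I", "II")
            for m in cluster
            if m not in archaic_ids
        )
        flags.append(has_archaic and has_grade)
    return flags, any(flags)


def _tree_clusters(
    tree: TreeNode, support_collapse: float, members_of: dict[str, list[str]]
) -> list[set[str]]:
    """Haplotype-id clusters from the support-collapsed rooted tree."""
    from .netrep import _cluster_nodes

    out = []
    for node in _cluster_nodes(tree, support_collapse):
        ids: set[str] = set()
        for leaf in node.leaf_names():
            ids |= set(members_of.get(leaf, [leaf]))
        out.append(ids)
    return out


def run_pipeline(
    vcf: str | Path | HaplotypeMatrix,
    pop_map: str | Path | dict[str, str] | None,
    focal_position: int,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> LocusReport:
    """Run the full locus analysis; returns the populated report.

    ``vcf`` may be a path or an in-memory matrix.  Intermediates are written
    under ``outdir`` when given.
    """
    cfg = config or PipelineConfig()
    report = LocusReport(seed=cfg.seed, focal_position=focal_position)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def save(name: str, writer) -> None:
        if outdir is not None:
            try:
                writer(outdir / name)
            except Exception as exc:  # pragma: no cover - best-effort output
                warnings.warn(f"could not write {name}: {exc}", stacklevel=2)

    # ---------------- load + curation ----------------
    try:
        if isinstance(vcf, HaplotypeMatrix):
            matrix = vcf
        else:
            pm = pop_map if isinstance(pop_map, dict) else read_pop_map(pop_map)
            matrix = read_vcf(vcf, pm)
        matrix = iterate_imputation(matrix)
        report.chrom = matrix.chrom
        report.stages["curation"] = "ok"
        save("curated.vcf", lambda p: write_vcf(matrix, p))
    except Exception as exc:
        report.stages["curation"] = f"failed: {exc}"
        return report

    # ---------------- locus definition ----------------
    try:
        locus = define_locus(matrix, focal_position, cfg.ld)
        in_locus = np.flatnonzero(
            (matrix.positions >= locus.start) & (matrix.positions <= locus.end)
        )
        locus_matrix = matrix.take_sites(in_locus)
        report.start, report.end = locus.start, locus.end
        report.length = locus.length
        f_idx = locus_matrix.site_index(focal_position)
        modern = locus_matrix.hap_indices(
            cfg.sstar.reference_groups + cfg.sstar.target_groups
        )
        report.focal_maf = locus_matrix.minor_frequency(f_idx, modern)
        report.stages["locus"] = "ok"
        save("locus.bed", lambda p: write_locus_bed(locus, p))
        save("locus.json", lambda p: write_locus_json(locus, p))
    except Exception as exc:
        report.stages["locus"] = f"failed: {exc}"
        return report

    # ---------------- haplotype sequences ----------------
    try:
        records = haplotypes_to_sequences(locus_matrix, cfg.max_deleted_frac)
        members_of = {r.id: list(r.member_ids) for r in records}
        report.stages["sequences"] = "ok"
        save("haplotypes.fasta", lambda p: _write_fasta(records, p))
    except Exception as exc:
        report.stages["sequences"] = f"failed: {exc}"
        return report

    # ---------------- tree + bootstrap ----------------
    rooted = None
    try:
        labels, dmat = distance_matrix(records, ts_tv_ratio=cfg.ts_tv_ratio)
        tree = nj_tree(labels, dmat)
        tree = bootstrap_supports(
            records, n_reps=cfg.n_bootstrap, seed=cfg.seed,
            ts_tv_ratio=cfg.ts_tv_ratio, tree=tree,
        )
        out_rec = next(
            (
                r
                for r in records
                if any(
                    group_of(_pop_of(locus_matrix, m)) == GROUP_OUTGROUP
                    for m in r.member_ids
                )
            ),
            None,
        )
        if out_rec is not None:
            rooted = root_with_outgroup(tree, out_rec.id)
        else:
            rooted = tree
        report.stages["tree"] = "ok"
        save("tree.nwk", lambda p: Path(p).write_text(rooted.newick() + "\n"))
    except Exception as exc:
        report.stages["tree"] = f"failed: {exc}"

    # ---------------- S* ----------------
    grades: dict[str, str] = {}
    sresults: list[SStarResult] = []
    try:
        sresults = run_sstar(locus_matrix, cfg.sstar)
        grades = {r.hap_id: r.grade for r in sresults}
        report.n_snps = sresults[0].n_snps if sresults else 0
        tally: dict[str, int] = {"I": 0, "II": 0, "low": 0}
        for r in sresults:
            tally[r.grade] += 1
        report.grade_counts = tally
        report.stages["sstar"] = "ok"
        save("sstar.tsv", lambda p: _write_sstar_tsv(sresults, p))
    except Exception as exc:
        report.stages["sstar"] = f"failed: {exc}"

    # ---------------- topology classification + colocalization ----------
    if rooted is not None:
        try:
            leaf_groups = {
                r.id: {_pop_of(locus_matrix, m) for m in r.member_ids}
                for r in records
            }
            leaf_grades = {
                r.id: _best_grade(grades, r.member_ids) for r in records
            }
            pat = classify_topology(
                rooted, leaf_groups, leaf_grades, cfg.support_collapse
            )
            report.pattern = pat.pattern
            report.typical_ooa = pat.typical_ooa
            report.nd_shared_class = pat.nd_shared_class
            report.pattern_type = pat.pattern_type

            clusters = _tree_clusters(rooted, cfg.support_collapse, members_of)
            archaic_ids = {
                h
                for h, p in zip(locus_matrix.hap_ids, locus_matrix.pop_labels)
                if group_of(p) in ARCHAIC_GROUPS
            }
            flags, overall = colocalization(clusters, grades, archaic_ids)
            report.colocalization = overall
            report.clusters = [
                {
                    "members": sorted(c),
                    "archaic": bool(c & archaic_ids),
                    "colocalized": f,
                }
                for c, f in zip(clusters, flags)
            ]
            report.stages["topology"] = "ok"
        except Exception as exc:
            report.stages["topology"] = f"failed: {exc}"

    # ---------------- EHH ----------------
    profile: EHHProfile | None = None
    try:
        modern_rows = locus_matrix.hap_indices(
            cfg.sstar.reference_groups + cfg.sstar.target_groups
        )
        profile = ehh_profile(
            locus_matrix,
            focal_position,
            hap_rows=modern_rows,
            min_geno=cfg.min_geno,
            region_threshold=cfg.ehh_region_threshold,
            high_threshold=cfg.ehh_high_threshold,
            span_threshold=cfg.ehh_span_threshold,
            cr_seed=cfg.seed,
        )
        report.as_symbol = profile.selection.as_symbol
        report.cr_symbol = profile.selection.cr_symbol
        report.high_ehh_length = profile.high_ehh_length
        report.ehh_maf_flag = "0.1>=" if profile.maf <= 0.1 else "0.1<"
        report.stages["ehh"] = "ok"
        save("ehh.tsv", lambda p: _write_ehh_tsv(profile, p))
    except Exception as exc:
        report.stages["ehh"] = f"failed: {exc}"

    # ---------------- representatives + network ----------------
    if rooted is not None:
        try:
            reps = select_representatives(
                rooted, cfg.rep_limit_range, cfg.support_collapse
            )
            rep_records = [r for r in records if r.id in set(reps.representatives)]
            rep_rows = [locus_matrix.hap_ids.index(r.id) for r in rep_records]
            sub = locus_matrix.take_haplotypes(rep_rows)
            complete = np.flatnonzero(~np.any(sub.alleles == MISSING, axis=0))
            sub = sub.take_sites(complete)
            net = reduced_median_network(
                sub.alleles.astype(np.int8),
                sub.positions,
                frequencies=np.array(
                    [r.multiplicity for r in rep_records], dtype=float
                ),
                hap_ids=[r.id for r in rep_records],
                reduction_r=cfg.reduction_r,
            )
            pop_of = {
                h: p for h, p in zip(locus_matrix.hap_ids, locus_matrix.pop_labels)
            }
            annotate_network(
                net,
                pop_labels=pop_of,
                sstar_grades=grades,
                focal_position=focal_position,
                node_members={
                    r.id: list(reps.clusters.get(r.id, r.member_ids))
                    for r in rep_records
                },
            )
            report.stages["network"] = "ok"
            save("network.graphml", lambda p: write_graphml(net, p))
        except Exception as exc:
            report.stages["network"] = f"failed: {exc}"

    save("report.json", lambda p: Path(p).write_text(report.to_json() + "\n"))
    return report


def _pop_of(matrix: HaplotypeMatrix, hap_id: str) -> str:
    return matrix.pop_labels[matrix.hap_ids.index(hap_id)]


def _best_grade(grades: dict[str, str], member_ids: list[str]) -> str:
    rank = {"I": 2, "II": 1, "low": 0}
    best = "low"
    for m in member_ids:
        g = grades.get(m, "low")
        if rank[g] > rank[best]:
            best = g
    return best


def _write_fasta(records: list[SequenceRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} multiplicity={r.multiplicity}\n{r.seq}\n")


def _write_sstar_tsv(results: list[SStarResult], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("hap_id\tpopulation\tn_candidates\ts_star\tT1\tT2\tgrade\n")
        for r in results:
            fh.write(
                f"{r.hap_id}\t{r.population}\t{len(r.candidate_sites)}\t"
                f"{r.s_star:.1f}\t{r.t1:.1f}\t{r.t2:.1f}\t{r.grade}\n"
            )


def _write_ehh_tsv(profile: EHHProfile, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tehh_ancestral\tehh_derived\n")
        for p, ea, ed in zip(
            profile.positions, profile.ehh_ancestral, profile.ehh_derived
        ):
            fh.write(f"{int(p)}\t{ea:.6f}\t{ed:.6f}\n")
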