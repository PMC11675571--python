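"""VCF 4.1 serialization of phased haplotype matrices.

Writing emits plain-text VCF with one diploid sample per consecutive pair of
haplotype rows; the ancestral allele is written as REF and annotated in
INFO/AA, so the 0/1 coding of the matrix maps directly onto GT indices.
Reading goes through cyvcf2 and restores alleles, phase flags and missing
markers; round-tripping a matrix is the identity.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .core import MISSING, HaplodivError, HaplotypeMatrix, TruthRecord

__all__ = [
    "VcfParseError",
    "write_vcf",
    "read_vcf",
    "read_pop_map",
    "write_pop_map",
    "write_truth",
    "read_truth",
]


class VcfParseError(HaplodivError):
    """Malformed VCF input; carries the 1-based offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


def write_vcf(matrix: HaplotypeMatrix, path: str | Path) -> Path:
    """Write a haplotype matrix as VCF 4.1 with GT fields.

    Haplotype rows 2i and 2i+1 become sample i; phased genotypes use ``|``,
    unphased ``/``; missing alleles are written ``./.``.
    """
    path = Path(path)
    if matrix.n_haplotypes % 2:
        raise ValueError("matrix must have an even number of haplotype rows")
    samples = [hid.rsplit("_", 1)[0] for hid in matrix.hap_ids[::2]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write(f"##contig=<ID={matrix.chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for sample, pop in zip(samples, matrix.pop_labels[::2]):
            fh.write(f"##SAMPLE=<ID={sample},Population={pop}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for s in range(matrix.n_sites):
            ref = matrix.ref_alleles[s]
            alt = matrix.alt_alleles[s]
            fields = [
                matrix.chrom,
                str(int(matrix.positions[s])),
                ".",
                ref,
                alt,
                ".",
                "PASS",
                f"AA={ref}",
                "GT",
            ]
            for i in range(0, matrix.n_haplotypes, 2):
                a, b = matrix.alleles[i, s], matrix.alleles[i + 1, s]
                if a == MISSING or b == MISSING:
                    fields.append("./.")
                else:
                    sep = "|" if (matrix.phased[i, s] and matrix.phased[i + 1, s]) else "/"
                    fields.append(f"{a}{sep}{b}")
            fh.write("\t".join(fields) + "\n")
    return path


def _locate_malformed_line(path: Path) -> int | None:
    """Best-effort scan for the first structurally broken data line."""
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            cols = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                n_cols = len(cols)
                continue
            if n_cols is not None and len(cols) != n_cols:
                return lineno
            if len(cols) > 1:
                try:
                    int(cols[1])
                except ValueError:
                    return lineno
    return None


def read_vcf(path: str | Path, pop_map: dict[str, str] | str | Path) -> HaplotypeMatrix:
    """Read a phased VCF into a haplotype matrix.

    ``pop_map`` maps sample id -> population code (or is a path to a
    two-column TSV).  Samples absent from the map are labelled ``UNKNOWN``
    with a warning.  If INFO/AA equals the ALT allele the site's coding is
    flipped so that 0 remains ancestral.
    """
    path = Path(path)
    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    try:
        vcf = VCF(str(path), gts012=False)
        samples = list(vcf.samples)
        positions: list[int] = []
        cols: list[np.ndarray] = []
        pcols: list[np.ndarray] = []
        refs: list[str] = []
        alts: list[str] = []
        chrom = "1"
        for v in vcf:
            chrom = v.CHROM
            gts = v.genotypes  # [allele0, allele1, phased] per sample
            col = np.empty(2 * len(samples), dtype=np.int8)
            pc = np.empty(2 * len(samples), dtype=bool)
            for i, g in enumerate(gts):
                a, b, ph = g[0], g[1], bool(g[-1])
                col[2 * i] = MISSING if a < 0 else a
                col[2 * i + 1] = MISSING if b < 0 else b
                missing = a < 0 or b < 0
                pc[2 * i] = pc[2 * i + 1] = ph and not missing
            aa = v.INFO.get("AA")
            ref, alt = v.REF, (v.ALT[0] if v.ALT else ".")
            if aa is not None and aa == alt:
                obs = col != MISSING
                col[obs] = 1 - col[obs]
                ref, alt = alt, ref
            positions.append(v.POS)
            cols.append(col)
            pcols.append(pc)
            refs.append(ref)
            alts.append(alt)
    except VcfParseError:
        raise
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad input
        raise VcfParseError(
            f"failed to parse {path}: {exc}", _locate_malformed_line(path)
        ) from exc

    hap_ids: list[str] = []
    pop_labels: list[str] = []
    for s in samples:
        pop = pop_map.get(s)
        if pop is None:
            warnings.warn(f"sample {s!r} absent from population map", stacklevel=2)
            pop = "UNKNOWN"
        hap_ids.extend([f"{s}_0", f"{s}_1"])
        pop_labels.extend([pop, pop])

    n_sites = len(positions)
    alleles = (
        np.stack(cols, axis=1) if n_sites else np.zeros((len(hap_ids), 0), np.int8)
    )
    phased = (
        np.stack(pcols, axis=1) if n_sites else np.ones((len(hap_ids), 0), bool)
    )
    return HaplotypeMatrix(
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        hap_ids=hap_ids,
        pop_labels=pop_labels,
        phased=phased,
        chrom=chrom,
        ref_alleles=refs,
        alt_alleles=alts,
    )


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out


def write_pop_map(matrix: HaplotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for hid, pop in zip(matrix.hap_ids[::2], matrix.pop_labels[::2]):
            fh.write(f"{hid.rsplit('_', 1)[0]}\t{pop}\n")
    return path


def write_truth(truth: TruthRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_json_dict(), indent=1))
    return path


def read_truth(path: str | Path) -> TruthRecord:
    return TruthRecord.from_json_dict(json.loads(Path(path).read_text()))
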