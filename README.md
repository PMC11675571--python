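# haplodiv

Locus-wise analysis of haplotype diversification in modern human
populations: given phased genotypes, a sample→population map and a focal
SNP, `haplodiv` defines the surrounding linkage-disequilibrium (LD) locus,
builds a haplotype phylogeny and a reduced median network, scores archaic
introgression with a phased S\* statistic, and scans for recent positive
selection with extended haplotype homozygosity (EHH). It is aimed at
population geneticists studying individual candidate loci — regions whose
haplotype trees deviate from the out-of-Africa expectation through
introgression, incomplete lineage sorting, inversion polymorphism or
selection — rather than at genome-wide scans.

A first-class synthetic-data module simulates phased African-like
reference and Eurasian-like target panels together with Neanderthal-like
and Denisovan-like genomes, an outgroup for rooting, introgression pulses
with recorded truth tracts, and partial selective sweeps, so the whole
pipeline is testable without any external downloads.

## The statistics at the core

**Phased S\*.** For a target chromosome, candidate sites are those where
it carries the locus-wide minor allele with African reference MAF < 5%.
With carrier set C(s) — the target chromosomes sharing the minor allele at
site s — consecutive pairs in a chain of candidate sites score

    d_bp(i,j) + B                  if C(i) = C(j)
    penalty · |C(i) Δ C(j)|        if 0 < |C(i) Δ C(j)| ≤ m_max
    −∞                             otherwise, or if d_bp < d_min

and S\* is the maximum chain sum (dynamic programming, provably equal to
exhaustive enumeration). Grades use locus thresholds linear in the SNP
count N:

    T1 = (2500/13)(N − 1),   T2 = (4/3) T1
    grade I: S* ≥ T2,   grade II: T1 ≤ S* < T2

so T1(313) = 60,000 and T1(209) = 40,000 at the two calibration loci.

**EHH.** For each focal-SNP allele, EHH(x) = Σ_g C(n_g,2)/C(n,2) over
groups of core haplotypes identical along [focal..x]. Allelic selection
(AS) compares the two alleles' spans at EHH = 0.5 (ratio bins `++`, `+`,
`+/−`, `−`; `n/a` at MAF ≤ 0.1); constrained regions (CR) are flagged from
the skew of bifurcation positions inside the high-EHH (≥ 0.2) region.

**Phylogeny.** F84 distances (distinct transition/transversion rates),
Saitou–Nei neighbor joining with 500-replicate site bootstrap, outgroup
rooting, topology patterns lettered A/E/C/N/D with typical-out-of-Africa
and Neanderthal–Denisovan-sharing flags, 14–21 representative OTUs, and a
reduced median network with frequency-weighted nodes.

See `docs/methods.md` for models, defaults and design choices.

## Worked example

```python
from haplodiv import SimulationConfig, simulate_locus
from haplodiv.sstar import run_sstar

cfg = SimulationConfig(seed=11, introgression_fraction=0.05)
matrix, truth = simulate_locus(cfg)           # 200 kb, 100+100 haplotypes
print("sites:", matrix.n_sites, " introgressed haplotypes:", sorted(truth.carriers()))

results = run_sstar(matrix)
top = max(results, key=lambda r: r.s_star)
print(f"N={top.n_snps}  T1={top.t1:.0f}  T2={top.t2:.0f}")
print(f"top haplotype {top.hap_id}: S*={top.s_star:.0f}  grade {top.grade}")
print("grade-I haplotypes:", sorted(r.hap_id for r in results if r.grade == "I"))
```

prints

```
sites: 2368  introgressed haplotypes: ['T001_0', 'T002_1', 'T003_1', 'T011_0', 'T013_0', 'T016_0', 'T018_1', 'T022_1', 'T025_1', 'T027_1', 'T029_0', 'T037_0', 'T040_0']
N=877  T1=168462  T2=224615
top haplotype T001_0: S*=652817  grade I
grade-I haplotypes: ['T001_0', 'T011_0', 'T022_1', 'T037_0']
```

The locus holds N = 877 modern SNPs, giving thresholds T1 ≈ 168 k and
T2 ≈ 225 k. Thirteen target haplotypes truly carry introgressed tracts
(many of them short); the four whose tracts are long enough to form
rare-allele chains score S\* above T2 and are graded I — all four are true
carriers, and the top scorer reaches S\* ≈ 653 k, nearly three times the
grade-I threshold.

The same analysis is available from the shell:

```
haplodiv simulate --seed 11 --introgression 0.05 --out locus
haplodiv sstar locus.vcf locus.pops.tsv --out sstar.tsv
haplodiv report locus.vcf locus.pops.tsv --focal 100123 --outdir out/
```

`report` (alias `all`) chains curation → LD locus → tree + bootstrap →
S\* → topology classification → EHH → representatives + network and
writes every intermediate plus a machine-readable `report.json` with the
summary-table fields (topology pattern, N–D sharing class, grade tallies,
colocalization, CR/AS symbols, high-EHH length).

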