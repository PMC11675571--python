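# Methods

This note documents the models and procedures implemented in `haplodiv`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Scope and units

All genomic coordinates are 1-based and inclusive, following VCF
convention; a locus spanning `start..end` has length `end − start + 1` bp.
Alleles are coded 0 (ancestral), 1 (derived), −1 (missing). Population
codes map to continental groups: African reference (AFR; the LWK/YRI/ASW
grouping used for S*), European (EUR), Asian (ASN), admixed American
(AMR), plus reserved labels for Neanderthal (NEA), Denisovan (DEN) and the
rooting outgroup (OUT).

## Synthetic data generator

`simulate.simulate_locus` produces phased biallelic haplotypes under a
structured coalescent (msprime) with the demography

    ((REF, TGT)@t_mod, (NEA, DEN)@t_nd)@t_arc, OUT)@t_out

and a single introgression pulse TGT ← NEA of fraction *f* at
`introgression_time`. Defaults (scaled-down, human-like):

| parameter | default | rationale |
|---|---|---|
| Ne (modern) | 10,000 | classical human effective size |
| Ne (archaic) | 2,500 | archaic hominin Ne was several-fold smaller; with equal sizes introgressed lineages often fail to coalesce inside the archaic clade and the emulation loses the deep divergence that defines real archaic tracts |
| μ | 1.2 × 10⁻⁸ /bp/gen | pedigree-based point estimate |
| r | 1.0 × 10⁻⁸ /bp/gen | genome-average crossover rate |
| locus length | 200 kb | on the scale of the analysed LD regions (23–550 kb) |
| n_ref, n_tgt | 100 + 100 haplotypes | a desk-scale stand-in for the hundreds of 1000-Genomes haplotypes per group |
| t_mod | 3,000 gen | out-of-Africa split, scaled |
| t_arc | 30,000 gen | 10 × t_mod, matching the archaic/modern divergence ratio |
| t_nd | 0.6 × t_arc | Neanderthal–Denisova split inside the archaic clade |
| t_out | 10 × t_arc | outgroup (chimpanzee-like) divergence for rooting |
| introgression time | 1,000 gen | chosen so the mean tract, 1/(r·t) = 100 kb, is commensurate with the intact archaic haplotypes spanning the studied loci |

Introgressed tracts are read off the recorded migration events: every
target sample descending from a pulse-migrated lineage over the migrated
interval carries a truth tract there (merged, 1-based, inclusive). Because
the loci this package emulates are *preselected* introgression candidates,
`condition_on_introgression=True` (default) rejection-samples the
simulation until at least one sampled target haplotype carries a tract;
set it to False for unconditional simulations.

The partial sweep is an overlay applied after the neutral simulation: a
site that is (nearly) ancestral outside the target population is chosen as
the selected site — a swept allele is a novel beneficial mutation — and a
`final_freq` fraction of target haplotypes receive copies of the founding
haplotype over exponentially distributed flanking extents (mean
`tract_mean_bp`, default 100 kb, standing in for 1/(r·T_sweep) of a sweep
lasting a few hundred generations). This reproduces the haplotype-level
hitchhiking signature (long shared core around the selected allele on one
allelic background) without a forward simulation; it does not reproduce
the site-frequency-spectrum distortions of a real sweep, so tests based on
EHH asymmetry are meaningful here while SFS-based statistics would not be.

What passing tests on this generator do *not* show about real data: the
generator has clean ancestral-allele assignment, no genotyping error, no
phasing switch errors (unless injected via `missing_rate`/`unphase_rate`,
both default 0, emulating post-imputation data), and a single constant-rate
pulse rather than extended gene flow.

## Curation rules

Reads whose mismatches cluster — more than 2 mismatches within any 10-base
window — are masked (base calls → `N`, qualities → 0). Whether the source
procedure masked the window or the whole read is ambiguous; whole-read
masking is the default (conservative), window-only is available. Reads
flagged as PCR/optical duplicates are discarded.

The phase-consistency check compares each re-phased heterozygous site
against its three nearest heterozygous neighbours. Because absolute phase
is arbitrary, what is compared is the *relative* orientation of site
pairs between the two phasing rounds; a site whose relative orientation
disagrees for **all** compared neighbours (unanimity — the stricter of the
two possible readings) is demoted to `unknown_phase`. Sites with fewer
than three het neighbours are compared against those that exist.

The imputation loop accepts a round only if it strictly decreases
missing + unknown-phase counts and stops otherwise, which guarantees
monotone non-increasing uncertainty and termination. The built-in imputer
copies the allele of the Hamming-nearest haplotype over jointly observed
sites (ties to the lowest row index).

## LD locus definition

Haplotype r² is the standard D²/(p_A(1−p_A)p_B(1−p_B)) on phased
chromosomes, with pairwise-complete deletion of haplotypes missing at
either site. A locus is the focal SNP plus all sites within ±200 kb with
r² ≥ 0.8 to it (thresholds configurable); the span is the min..max member
position. Among perfectly associated candidate focal SNPs (r² = 1) the one
closest to the median coordinate is chosen, ties to the lower coordinate.
The optional density trim runs DBSCAN (ε = 50,000, MinPts = 50) on the 1-D
member positions — implemented as a sorted scan, which is exactly DBSCAN
in one dimension — and keeps the cluster containing the focal SNP; if the
focal SNP is noise the caller is told to relax the parameters.

## Phylogeny

Haplotype sequences are built from the variant sites only (the usual
VCF-derived alignment); haplotypes with ≥ 0.5% deleted/missing sites are
dropped (boundary inclusive) and identical sequences collapse with
multiplicities. Distances use F84 with distinct transition/transversion
rates: `f84_distance(method="ml")` maximises the pairwise likelihood over
the branch length with the ts/tv ratio fixed (default 2.0), using the
analytic "three-urn" transition probabilities; `method="moments"` is the
closed-form estimator, used for whole matrices and bootstrap replicates
where speed matters. Distances are per *variant site*, a monotone
transform of per-bp distance that is adequate for topology. Saturated
pairs return an infinity sentinel; matrices replace them by twice the
largest finite entry so NJ remains usable.

Neighbor joining follows Saitou–Nei with the Q criterion, deterministic
lowest-index tie-breaks, and negative branch-length estimates clamped to
zero with the deficit moved to the sister edge. On additive matrices the
true tree and branch lengths are recovered exactly (tested on random 4–8
taxon metrics). Bootstrap resamples alignment columns (default 500
replicates) and supports are the percentage of replicate NJ trees
containing each original bipartition. Rooting places the root at the
midpoint of the outgroup's pendant edge.

Topology classification collapses edges with support < 50, drops the
outgroup, and letters maximal clusters: A (African only), E (non-African
modern only), C (mixed-continent), N, D. A "typical out-of-Africa"
topology requires some subtree containing non-Africans whose sibling
context is purely African. Neanderthal–Denisovan sharing is classed from
the support of the smallest all-archaic cluster containing both: `++` at
support ≥ 99, `+` at 75 < support < 99, `−` otherwise. The pattern-type
rules (FE: basal cluster with archaic + graded non-African members; Af:
archaics nested in an African context; Ea: basal non-African lineage with
grades but no archaic; FA/other) reconstruct a catalogue whose full
definition is not published; they are an ordered, overridable rule table.

## Representatives and networks

Representative selection starts from the support-collapsed clusters,
repeatedly removes the candidate whose patristic distance to its nearest
remaining candidate is smallest until at most the upper limit (default
14–21) remain, represents each cluster by the member with minimal mean
distance to co-members, then adds every leaf whose root distance exceeds
mean + 2 sd (root-distance outliers). Patristic rather than cophenetic
distances are used; both choices are defensible and this one is explicit.

The reduced median network collapses identical binary characters into
weighted classes, connects haplotypes differing at exactly one class, and
adds majority-consensus (median) vectors of triples only when the observed
characters are incompatible (some pair shows all four gametes) and the
triple passes the frequency-reduction criterion min ≥ max/r (default
r = 2). On compatible character sets no median is ever generated and the
network is the unique perfect phylogeny. Components that remain
disconnected (multi-step gaps) are bridged by minimal multi-site edges so
the output is always connected.

## Phased S*

For one target chromosome, candidate sites are those where it carries the
locus-wide minor allele and the reference (African) minor-allele frequency
is **strictly** below 5%. The carrier set of a site is the set of
target-population chromosomes bearing the minor allele; missing alleles
count as non-carriers. The pair score is

    d_bp + B                       if the carrier sets are identical
    penalty × |symmetric diff|     if 0 < |symmetric diff| ≤ m_max
    −∞                             if |symmetric diff| > m_max
                                    or d_bp < min pair distance

with defaults B = 5,000, penalty = −10,000, m_max = 5, min distance 10 bp;
the function is pluggable because the published description fixes only
"distance and number of chromosomes". S* is the maximum over chains of
candidate sites of the summed consecutive-pair scores, computed by dynamic
programming (proved equal to exhaustive subset enumeration in the tests).

Grade thresholds are linear in the locus SNP count N (sites segregating
among modern haplotypes): T1 = (2500/13)(N − 1), the unique line through
the anchors (313, 60,000) and (209, 40,000), and T2 = (4/3) T1. Grade I:
S* ≥ T2; grade II: T1 ≤ S* < T2; the bounds are closed exactly as stated.
S* is computed separately per target population group.

## EHH and selection calls

EHH of a core allele at site x is Σ C(n_g,2)/C(n,2) over groups of core
haplotypes identical along [focal..x], computed independently in each
direction; haplotypes genotyped at < 99.999% of sites are excluded. A
missing allele inside the extension makes that haplotype its own group
from then on (conservative decay; a drop-haplotype mode exists). EHH is 1
at the focal site and non-increasing outward by partition refinement.

The EHH region is the maximal interval around the focal SNP where both
alleles hold EHH ≥ 0.05; the high-EHH region uses 0.2, and its reported
length is end − start + 1 between the outermost qualifying variant
positions. Bifurcation graphs split branches at each polymorphic site
walking outward within the high-EHH region; positions where ≥ 2 branches
split simultaneously are flagged (a recombination signature). Leaf widths
always sum to the core count.

Allelic selection (AS) compares the two alleles' two-sided bp spans at
EHH = 0.5: ratio = shorter/longer, binned (0,0.1] → `++`, (0.1,0.2] →
`+`, (0.2,0.4] → `+/−`, (0.4,1] → `−`, and `n/a` when the focal MAF ≤ 0.1
(rare alleles are young and carry long haplotypes regardless of
selection). Whether the published spans were one- or two-sided is not
stated; two-sided is assumed, matching two-sided EHH plots.

The constrained-region (CR) call is an explicit reconstruction of a
"bifurcation-position skewness" criterion: bifurcation positions of both
alleles inside the high-EHH region are tested for uniformity with a
largest-gap statistic against a seeded Monte-Carlo null (2,000 draws of
uniform order statistics); `+` needs both p < 0.05 and a gap wider than
25% of the region, `+/−` exactly one of the two, `−` otherwise. Fewer
than five bifurcation positions yield `−` with a warning.

## Pipeline and report

`pipeline.run_pipeline` chains curation → locus definition → haplotype
filtering → NJ + bootstrap → S* → topology classification → EHH →
representatives + network, writes every intermediate (VCF, BED, JSON,
FASTA, Newick, TSV, GraphML) and a JSON report with the summary-table
fields (coordinates, length, focal MAF, topology pattern and flags, N–D
class, grade tallies, colocalization, CR/AS, high-EHH length). A stage
failure is recorded in `stages` and partial outputs are kept.
Colocalization is true for a cluster holding ≥ 1 archaic haplotype and
≥ 1 modern grade-I/II haplotype, and true overall if any cluster
qualifies. All randomness (bootstrap, CR Monte-Carlo) derives from the
single config seed; reports are bit-reproducible.

## Problem sizes used in the checks

The shipped checks run at desk scale by design: 200 kb loci with 100 + 100
modern haplotypes for the S*/EHH detection studies (50 seeds per arm),
50 kb / 60-hap loci for curve invariants, 500 random S* instances with up
to 15 candidate sites for the DP-vs-enumeration proof, and 200 random 4–8
taxon additive metrics for NJ. Real-data-scale runs (thousands of
haplotypes, megabase windows) go through the same code paths but are not
exercised by the test suite.

## Known limitations

- The S* pair score and the CR statistic are explicit reconstructions of
  procedures whose exact published definitions are unavailable; both are
  configurable/pluggable and their defaults are stated above.
- F84 distances are computed on variant sites only; absolute branch
  lengths are therefore not on a per-bp substitution scale.
- The reduced median network uses a frequency-ratio reduction criterion
  that approximates, but is not guaranteed identical to, the behaviour of
  the classic network software; median closure is capped against
  pathological growth.
- The sweep overlay emulates haplotype structure, not allele-frequency
  trajectories; it is unsuitable for SFS-based selection tests.
- X-chromosome ploidy is not modelled; all loci are autosomal-style
  phased pairs.
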