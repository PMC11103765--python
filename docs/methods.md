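# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used at boundaries and in
degenerate cases.

## Candidate SNP selection

Selection operates on called genotypes (individuals × loci), not reads.
Per-locus expected heterozygosity is the biallelic gene diversity
He = 2p(1−p), with p the observed allele frequency among non-missing
calls; missingness counts both depth-based `missing` and dead-zone
`nocall` codes. All thresholds are strict inequalities (a locus with
He exactly at the floor is rejected), and a threshold set to its trivial
bound (`max_missing ≥ 1`, `min_he ≤ 0`, `min_maf ≤ 0`) disables the rule
entirely so that a fully permissive config is the identity.

Rules are applied in a fixed cascade — missingness → He → MAF →
per-genotype depth → spacing → one-per-scaffold — and each rejected
locus is tagged with the first rule it fails. Spacing is enforced
greedily along each scaffold in position order (keep the first locus,
then every locus more than `min_spacing_bp` beyond the last kept one);
greedy-by-position is optimal for this selection and deterministic.
One-per-scaffold keeps the locus with the highest He, breaking ties by
smallest position: the panel should carry the most informative SNP per
scaffold, and the rule must be reproducible. Because relaxing one
threshold can change *which* locus represents a scaffold or spacing
window, monotonicity holds for the survivor count, not the survivor
set. The per-genotype depth rule needs a read-depth table that plain
genotype matrices do not carry; without one it is skipped with a logged
notice.

## Primer screening

Melting temperatures use the unified nearest-neighbor parameter set
(SantaLucia 1998): per-stack ΔH/ΔS, terminal initiation terms, a
symmetry entropy for self-complementary sequences, the sodium entropy
correction 0.368·(N−1)·ln[Na⁺], and Tm = 1000·ΔH/(ΔS + R·ln C_T) − 273.15.
Defaults are 50 mM monovalent salt and 250 nM primer — ordinary
multiplex-PCR conditions — and are configurable. The implementation is
cross-checked in the tests against an independent library implementation
of the same parameter set to ±0.5 °C.

Hairpin and heterodimer screening score the most stable *ungapped,
perfectly complementary* stem of ≥ 4 bp (hairpins additionally require a
loop of ≥ 3 bases), evaluated with the same duplex model. This is a
deliberate desk-scale approximation: full secondary-structure folding
with mismatches and bulges is out of scope for a screening pass, and the
stem bound is conservative in the direction that matters (a structure
with imperfections is less stable than its perfect stem). Two
asymmetric boundary conventions are intentional: a hairpin fails only
*above* the 50 °C bound, while a heterodimer fails at 50 °C *or higher*.

Internal-binding search anchors on the primer's 3'-terminal 15 bases
(the whole primer if shorter) because 3' complementarity is what drives
mispriming extension; the seed is matched exactly on both strands of
every expected amplicon, excluding the primer's own designed site.

Pooled-mix formulation ranks loci by on-target read share: loci strictly
inside the top quartile (rank ≤ ⌊n/4⌋ *and* share strictly above the
boundary share) are diluted to 80 nM, strictly-bottom-quartile loci are
boosted to 320 nM, everything else stays at 160 nM. The strictness
clause makes fully tied panels stay uniform, which is the only sensible
reading of "top 25%" when no locus outperforms any other. With fewer
than four loci quartiles are undefined and all primers stay at 160 nM.

## Allele-ratio genotyping

Probe counting is exact, forward-strand, full-probe substring matching —
no mismatch tolerance and no quality trimming — which keeps the counter
deterministic and auditable. A read that matches probes from more than
one locus indicates a panel defect; it is assigned to the first locus in
sorted-id order and logged. The ratio rule leaves two dead zones,
(0.1, 0.2) and (5, 10]; these become an explicit `nocall` code distinct
from depth-based `missing` rather than being silently forced into a
genotype. Both codes count as missing downstream. A zero denominator is
the limit of the rule: n2 = 0 with adequate depth is hom1 (and
symmetrically n1 = 0 is hom2). Boundary ratios follow the strict
wording: r = 10 and r = 0.1 are no-calls, r = 5.0 and r = 0.2 are
heterozygous.

Matrix-level filtering removes loci missing in ≥ 50% of individuals
first, then individuals missing at ≥ 50% of the surviving loci
(inclusive bounds). Genotyping success is the percentage of loci called
per individual, summarised by sample type.

## Concordance

Two matrices are intersected by individual and locus id; a cell enters
the comparison only when both methods made a diploid call. Discordant
cells fall into exactly one of three categories (A hom / B het, A het /
B hom, A hom / B hom for opposite alleles); het/het disagreement is
impossible at a biallelic locus and is asserted, not filtered. The
default discordance rate is the ratio of means — mean discordant loci
per individual over mean loci called by both — with a mean-of-ratios
alternative behind a flag, since the two aggregations genuinely differ
on unbalanced data and published tables do not always say which was
used. Allele labels are harmonized by locus definition, never by
frequency; matrices with conflicting definitions are a hard error.

## Population genetics

Ho is the observed heterozygote fraction among typed individuals. Hs is
Nei's (1987) within-population gene diversity with sample-size
correction, Hs = ñ/(ñ−1)·(1 − Σp² − Ho/(2ñ)), and is what the toolkit
reports as He — the corrected statistic is the standard output of the
software ecosystem this module is meant to be comparable with, though
the uncorrected 1 − Σp² differs only by O(1/ñ). Fis = 1 − ΣHo/ΣHs as a
ratio of sums over polymorphic loci; monomorphic loci (Hs = 0) carry no
inbreeding information and are excluded from both sums. Populations
with fewer than 8 individuals are excluded by default — below that the
estimator noise dominates any signal.

Pairwise F_ST is the Weir & Cockerham (1984) θ for two populations:
per-locus variance components a (among populations), b (among
individuals within populations), c (within individuals), combined as
Σa / Σ(a+b+c) with the sums taken over loci *before* the ratio — the
estimator's recommended multilocus form. Negative estimates are
retained; loci with zero total variance or fewer than two typed
individuals in either population are skipped. Missing genotypes are
dropped per locus per population (complete case by cell). The bootstrap
resamples loci (not individuals) with replacement, 999 replicates by
default, and reports the 2.5% and 97.5% empirical percentiles; with one
usable locus the CI is undefined and an error is raised rather than a
degenerate interval returned.

## Synthetic data

The generator emulates a two-level study design. Population allele
frequencies follow the Balding–Nichols model: ancestral frequency p
drawn from a configurable distribution (default uniform on [0.1, 0.9],
avoiding near-fixed loci that carry no panel information), population
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target F_ST —
the simplest structured-population model with an exact differentiation
parameter. The default F = 0.10 reflects moderate differentiation
typical of fragmented small-mammal populations. Genotypes are
Binomial(2, p) per individual (Hardy–Weinberg).

Reads are single-end 118-base amplicon copies with the allele base at
the template midpoint and the 15-base probe centred on it; per-cell
depth is Poisson (or negative binomial) with sample-type profiles
hair λ=2, swab λ=30, tissue λ=100 — qualitative stand-ins for the
order-of-magnitude on-target differences seen between those sample
types, not calibrated claims. Heterozygote reads pick an allele with
probability ½; per-allele amplification dropout (optionally restricted
to one allele for forced-failure tests) silences all reads from that
allele; a per-read false-allele error flips the emitted probe. The
idealised low-coverage caller samples a fixed depth d per cell and
miscalls a heterozygote homozygous whenever all d reads agree —
probability 2·(1/2)^d — reproducing the dropout mechanism analytically.

What the generator does *not* emulate: linkage between loci, coalescent
ancestry, PCR duplicates, index hopping, base-quality variation, or
primer-competition dynamics in the pool. Passing tests therefore
demonstrate the correctness of the counting, calling, and estimation
machinery under the stated models — not robustness to every artefact of
real libraries. All stochastic operations take a mandatory seed and are
bit-reproducible.

## Problem sizes and numerical checks

The validation suite runs at desk scale, chosen as the smallest sizes at
which each statistical assertion has comfortable power: caller
calibration uses 10⁵ Monte-Carlo replicates against exact binomial
enumeration (26/4096 hom-calls at depth 12; 0.25 het→hom at depth 3);
F_ST recovery uses 2 populations × 30 individuals × 2000 loci with a
999-replicate bootstrap; bootstrap coverage is checked over 60
simulation replicates of 500 loci at 199 bootstraps; the dropout
mechanism uses ≥ 10⁴ heterozygous cells; and the end-to-end pipeline
(FASTQ generation → probe counting → calling → diversity statistics)
runs 2 × 25 individuals × 150 loci at tissue-grade λ = 100 with a 0.001
error rate, where it recovers every genotype and |Fis| stays below 0.05.

Floating-point conventions: Tm computations are deterministic and
reverse-complement symmetric by construction of the parameter table;
heterodimer symmetry holds to summation order (~1e-12 °C); θ
invariance under allele relabelling and individual permutation is exact.
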