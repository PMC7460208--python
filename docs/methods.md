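# Methods

`popkit` implements the population-genetic analysis chain used in
conservation-oriented resequencing studies of subdivided livestock
populations: site filtering and LD pruning of a genotype matrix,
per-population diversity, pairwise differentiation, partitioning of
metapopulation gene and allelic diversity with leave-one-out and
optimal-pool contributions, deleterious-variant summaries from SIFT
annotations, and a windowed Z-F_ST × Z-θπ-ratio selective-sweep scan.
Everything is exercised end to end on synthetic genotypes with planted
truth, because the statistics themselves — not any one dataset — are the
deliverable.

## The synthetic metapopulation

The generator emulates a design of ten small, geographically isolated
study populations (3–6 diploids each, 50 in total) plus a 15-sample wild
outgroup. Per variant, an ancestral alternate-allele frequency `p` is
drawn from Uniform(0.05, 0.95) (so most sites survive a MAF > 0.05
filter). Each population draws its own frequency from the
Balding–Nichols law

    p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F),

whose single parameter `F` is the expected differentiation of that
population from the ancestral pool; `F = 0` copies `p` exactly. A
coalescent simulator is deliberately avoided: these statistics are
functions of allele frequencies, and Balding–Nichols gives direct,
interpretable control of F_ST. Defaults: `drift_F = 0.10` for the study
populations (measured Nei G_ST between population pairs then sits near
0.08–0.17, the range typical of isolated pig populations) and `0.30` for
the outgroup, which has diverged further.

Genotypes are two allele draws per individual; with probability `F_is`
the second copies the first (the standard inbreeding construction), so
E[H_O] = (1−F_is)·H_E within a population. Default `F_is` varies per
population from 0.01 to 0.35, spanning near-outbred to strongly inbred —
the spread real small herds show. Calls are masked missing at rate 0.02.

Deleterious sites are flagged Bernoulli(`deleterious_fraction`, default
0.01) *before* genotype simulation; flagged sites take their ancestral
frequency from a low-frequency mixture (probability 0.7 of
Uniform(0.002, 0.05), else Uniform(0.05, 0.6)). The 0.7 weight is chosen
so that, after drift diffuses the mass outward, more than half of the
realized pooled frequencies still fall in the first 0.05 bin — the
canonical picture for deleterious spectra. Their SIFT scores are drawn
below the deleterious threshold; all other scored sites above it; ~15%
of variants receive a second, higher-scoring consequence row so the
worst-consequence reduction is exercised.

Sweeps are planted by frequency distortion, not re-simulation: inside a
declared window the target group's genotypes are redrawn from frequency
0.98 toward the group's major allele. This shrinks within-group θπ
roughly ten-fold while leaving it positive (a window fixed to exactly
zero diversity would have an undefined ratio and be masked), and raises
the window's F_ST against the untouched group.

The full demo design covers 18 autosomes × 11.11 Mb (≈20,000 10-kb
windows) with 800,000 SNPs — 4 SNPs/kb, a deliberately scaled-down echo
of real whole-genome density (tens per kb), chosen so that sweep windows
still carry ≥ 10 SNPs after the MAF filter removes roughly half of their
near-fixed sites. All randomness flows from one integer seed through
per-stage substreams; identical configuration gives byte-identical
output files.

What the generator does **not** emulate: linkage disequilibrium between
loci (sites are independent; LD pruning is tested on engineered
duplicate columns), mutation-rate heterogeneity, genotyping error
structure beyond uniform missingness, and any demographic history beyond
the one-level island model. Passing tests therefore demonstrate
correctness of the estimators and calling logic under the model's
assumptions, not robustness to realistic haplotype structure.

## Filtering and LD pruning

Site filters mirror common practice with strict inequalities: biallelic
SNPs on autosomes (autosome = numeric contig name by default,
configurable), call rate > 1 − `max_missing` (default > 90%), pooled
minor-allele frequency > 0.05. Criteria are counted with the precedence
non-biallelic → non-autosome → call rate → MAF so the removal counts sum
to input − retained. Half-calls (`./1`) count as missing.

Two tiers are kept: the MAF tier feeds diversity, partitioning, pruning
and the sweep scan; the call-rate-only tier feeds the deleterious
summaries, because deleterious alleles are predominantly rare and a
MAF > 0.05 cut would empty exactly the spectrum bins of interest.

LD pruning follows the PLINK `--indep-pairwise 50 5 0.2` scheme: 50-SNP
windows advancing by 5; within a window, while any kept pair has
genotype r² above the threshold, the lower-MAF member is removed (tie:
the later variant in position order). r² is the squared Pearson
correlation of dosages on pairwise-complete samples; undefined
(monomorphic) pairs count as 0, and r² is rounded to 12 decimals before
the threshold comparison so pairs whose true r² is a small rational
exactly at the cutoff decide identically under algebraically equivalent
formulas. PLINK bit-parity is not promised; an in-repo brute-force
implementation of the same rule defines correctness.

## Diversity and differentiation

The engine is the molecular coancestry matrix
`f_ij = mean_loci [p_i p_j + (1−p_i)(1−p_j)]` — the probability that two
alleles drawn from populations i and j match in state. From it:

* gene diversity H = 1 − f;
* Nei's minimum distance `D_nei(i,j) = (f_ii + f_jj)/2 − f_ij`;
* pairwise Nei G_ST: `H_S = 1 − (f_ii+f_jj)/2`,
  `H_T = 1 − (f_ii+f_jj+2f_ij)/4`, `F_ST = (H_T − H_S)/H_T`, truncated
  to [0, 1] with the truncation count reported.

These definitions make `F_ST = D_nei / 2H_T` an exact identity, tested
to 1e-12. Under Balding–Nichols with parameter F, the pairwise G_ST from
*true* frequencies has expectation F/(2−F), and computing it from raw
sample frequencies adds an upward small-sample term that partially
cancels this deflation; measured values at n = 6 diploids are ≈ 0.08 /
0.11 / 0.17 for F = 0.05 / 0.10 / 0.20. The matrix is therefore checked
for monotonicity in F, while *parameter recovery* uses the Hudson
ratio-of-averages estimator (below), which is unbiased for F in this
model.

Per-population statistics: H_O (heterozygote fraction averaged over
loci); H_E as the per-site mean of 2p(1−p) with the 2n/(2n−1) unbiased
correction (PLINK convention, disable with `unbiased=False`) — the
coancestry form 1 − f_ii is also reported as `H_E_nei` since both
conventions circulate; allelic richness A_R by hypergeometric
rarefaction, `A_R = mean_loci Σ_a [1 − C(2N−c_a, g)/C(2N, g)]`, with `g`
defaulting to the gene-copy count of the smallest population and
under-covered loci skipped and counted; and the method-of-moments
inbreeding coefficient `F = (O_hom − E_hom)/(L − E_hom)` per individual
(PLINK `--het` style), averaged per population.

## Metapopulation partition and pool optimisation

With equal weights 1/s and the s² double-sum convention (diagonal terms
included — the convention is chosen precisely because it makes the
identities exact):

    H_S = (1/s) Σ_i (1 − f_ii)
    D_G = (1/s²) Σ_ij D_nei(i,j)
    H_T = 1 − (1/s²) Σ_ij f_ij          ⇒  H_T = H_S + D_G

    A_S = (1/s) Σ_i (K_i − 1)
    D_A = (1/s²) Σ_ij (u_ij + u_ji)/2
    A_T = (1/s²) Σ_ij (K_union(i,j) − 1) ⇒  A_T = A_S + D_A

where K_i counts alleles segregating in population i at a locus and u_ij
counts alleles of i absent from j. Both identities hold to machine
precision and are enforced at 1e-10 on every computation. The
pooled-metapopulation allele count (mean K of the union over all
populations, minus one) is also emitted for comparison, since the
pairwise-average A_T and the pooled form differ when alleles are private
to one population. The locus set is restricted to loci covered in every
population so that full and leave-one-out metapopulations are computed
over identical data.

Leave-one-out contribution of population i to component X:
`100·(X_full − X_without_i)/X_full`; positive means removing the
population loses diversity. Sanity structure: ΔH_T = ΔH_S + ΔD_G per
removal, exchangeability (identical populations contribute identically)
and duplicate symmetry are all tested.

Pool optimisation, criterion H: maximise `H(c) = 1 − c'fc` over the
probability simplex. Since f is positive semi-definite this is a concave
maximisation; projected-gradient ascent (step 1/(2λ_max), uniform start
first, then vertex and seeded Dirichlet starts, best objective wins with
ties keeping the earliest start so degenerate instances return uniform
weights) is cross-checked against an exhaustive 0.01-step simplex grid
for s ≤ 4. Criterion K: expected number of distinct alleles in a
rarefied draw of `g` gene copies (default 20) from the c-weighted pool,
`Σ_a (1 − (1 − Σ_i c_i p_{i,a})^g)` averaged over loci, maximised by
greedy weight increments of size `resolution`; ties go to the
lowest-index population.

## Sweep scan

Windows tile each chromosome from position 0 in half-open 0-based 10-kb
steps (1-based inputs are converted; outputs are BED-convention). Per
window and group, θπ is the sum of per-site unbiased heterozygosity
`2p(1−p)·c/(c−1)` (c = called gene copies; identical to the fraction of
differing gene-copy pairs) divided by window length in bp, so SNP-free
windows are 0. Normalising by window length rather than SNP count
matches the "sequence diversity" reading; per-SNP normalisation would
change only the scale of the Z statistics.

F_ST per window is the Hudson ratio of averages:

    N = (p_A − p_B)² − p_A(1−p_A)/(n_A−1) − p_B(1−p_B)/(n_B−1)
    D = p_A(1−p_B) + p_B(1−p_A),      F_ST = ΣN / ΣD over sites,

truncated to [0, 1]; ΣD = 0 masks the window. Hudson is chosen for its
robustness to unequal sample sizes and because it is unbiased for the
Balding–Nichols F; a Weir–Cockerham variant was considered and dropped
as redundant for the scan's ranking purpose.

The diversity ratio is outgroup/study, so a sweep in the study group
raises it. Windows are masked when they carry fewer than `min_snps`
SNPs (default 10), when θπ_study = 0 (infinite ratio), or when F_ST is
undefined; masked windows are excluded from the Z-transformations
((x − mean)/sd, sample sd) and can never be candidates. Z-scores are
computed on the raw ratio; a log2 option exists because raw-ratio Z
distributions are heavy-tailed (a single extreme window can carry a Z in
the hundreds).

Candidates are windows at or above the empirical `quantile` (default
0.99, order statistic, inclusive — ties at the cutoff are admitted) in
*both* Z_FST and Z_ratio; the intersection is the primary rule (a union
flag exists). Under independent null statistics the expected candidate
fraction is ~(1−q)², which the tests verify by Monte-Carlo. Adjacent
candidate windows are merged for reporting, and genes overlap a
candidate when their half-open intervals share ≥ 1 bp.

## Deleterious variants

SIFT scores live in [0, 1]; "close to 0" is operationalised as
score < 0.05 (the standard SIFT deleterious convention) and exposed as a
flag. A variant with several transcript consequences is reduced to its
minimum score (worst consequence). Presence in a population is an
alternate-allele count > 0. The spectrum bins pooled study-sample
frequencies in left-closed 0.05-wide bins; intersection counts are
exact-subset (UpSet-style) and partition the deleterious variants
present in at least one population — enforced against a power-set
enumeration oracle.

## Numerical and degenerate-input choices

* Frequencies and coancestry use pairwise-complete loci; pairs with no
  shared loci raise.
* A population pair with H_T = 0 (identical and fixed) gets F_ST = 0
  with a warning rather than NaN.
* Negative F_ST estimates truncate to 0 (counted); negative Hudson
  window values likewise.
* `zscore` raises on fewer than two finite values or zero spread, naming
  the statistic.
* Leave-one-out contributions to a component whose full-pool value is 0
  are defined as 0 (there is nothing to lose).
* Single-diploid populations are rejected where the 2n/(2n−1) correction
  or the inbreeding denominator would be undefined.
* A sweep window containing no variants is recorded in the truth and
  logged, never an error.

## Problem sizes used by the test suite and acceptance script

Identities run on 100 random metapopulations (2–8 populations, ≤ 2k
loci). Oracle equivalence: 50 LD-pruning instances of 200 SNPs × 20
samples, plus smaller θπ / allele-set / interval / grid checks.
Parameter recovery simulates 10 × 6 diploids + 15 outgroup samples at
50k loci, two seeds per drift level. Sweep recovery runs the full
800k-SNP / ~20k-window demo once; the null rate uses 30 Monte-Carlo
replicates of 20k windows. End-to-end determinism runs the whole
pipeline twice at 3k variants. These sizes keep a full run in the
low tens of seconds while leaving Monte-Carlo error well inside the
asserted tolerances.
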