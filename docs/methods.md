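# Methods

## Setting and scope

`mhagscan` implements a genome-wide scan for minor histocompatibility loci
from transplant cohorts in semi-inbred lines. The design it targets: a few
MHC-homozygous lines genotyped on a ~60k SNP array (18 autosomes, X, and a
set of unplaced SNPs), a small number of grafts between and within lines,
and a binary graft outcome. Genotypes are abstracted to an {A, B} biallelic
alphabet per locus — every downstream quantity (fixation, matching,
association) depends only on allele identity and difference, never on the
nucleotide. Y-chromosome loci are dropped on input; X is analysed like an
autosome.

## Homozygosity profiling

A SNP is *fixed* within a line iff all non-missing calls in that line are
the same homozygote; a site where every animal is heterozygous carries both
alleles and therefore counts as segregating. Missing calls never break
fixation (they are simply excluded), and a SNP with no non-missing call in
a line leaves that line's denominators entirely. Over segregating SNPs the
per-SNP minor allele frequency is min(allele counts)/total alleles (tie at
0.5 resolved toward label B) and heterozygosity is the fraction of
non-missing calls that are heterozygous. No Hardy–Weinberg relationship
between the two is assumed or asserted: real semi-inbred lines show
heterozygote excesses that violate it. The cross-line fixation fraction
conditions on SNPs with data in every requested line and requires the same
fixed homozygote throughout. In homozygosity maps the major allele is
defined within each pig's own line, ties toward label A.

## Mismatch models

Model 1 is directional host-versus-graft logic: a pair is mismatched iff
the donor's allele set is not a subset of the recipient's (the graft
presents an epitope the host has not tolerised to; graft-versus-host
disparities are ignored). Model 2 is symmetric: any genotype difference is
a mismatch. Model-1 mismatches are a strict subset of Model-2 mismatches;
both are verified exhaustively over the 4×4 call-combination table in the
test suite. A missing call on either side yields status *unknown*, which
removes the pair from that locus's table rather than imputing — with
cohorts of ~20 pairs, imputation would manufacture signal. A locus is
*testable* under a model iff both statuses occur among known-status pairs;
the statistic is identically zero otherwise. This pair-level rule (rather
than any line-level segregation criterion) determines which loci enter each
model's scan, which is also why the two models generally scan different
locus counts.

## Association statistic

Each testable locus forms a 2×2 table of outcome × status over the pairs
with known status (so N can vary by locus). The statistic is the standard
G statistic, G = 2·Σ O ln(O/E) with independence expectations E from the
margins; 0·ln 0 ≡ 0, and a zero row or column marginal defines G = 0. The
factor 2 is essential for the claimed χ²(1) asymptotics: without it the
statistic's maximum at 20 pairs would be 20·ln 2 ≈ 13.9 and a genome-wide
threshold near 17 could never be crossed. Direction is read off the
mismatched-rejected cell: above its expectation → *rejection*-associated,
below → *acceptance*-associated. Tests verify the implementation against an
independent multinomial log-likelihood oracle on every 2×2 table with
N ≤ 12 (1,819 tables) and against `scipy.stats.chi2_contingency` with the
log-likelihood lambda on all-positive tables.

At N = 20 the null distribution is discrete; the pointwise 5% exceedance of
the χ²(1) critical value 3.841 was computed exactly for the genotype-based
null used in the calibration test (HWE draws, Beta-distributed MAF,
symmetric coding, 10/10 outcomes) and equals 0.059, hence the test asserts
the band [0.01, 0.07] rather than exact 0.05.

## Permutation threshold

Family-wise significance uses the maxT scheme: outcome labels are permuted
jointly across pairs (unstratified by line combination), all testable-locus
statistics are recomputed, and the per-permutation maximum is recorded; the
genome-wide threshold at level α is the order statistic at
⌈(1−α)·n⌉ of the maxima. Significance is strict (`>` the threshold) — the
conservative convention at ties. When the number of distinct outcome
assignments C(N, n_rejected) does not exceed the requested permutation
count, all assignments are enumerated exactly and the result is flagged
`exact`; this makes small-cohort thresholds deterministic and is verified
against an independent enumeration oracle. Sampled mode is bit-reproducible
given a seed. A stratified permutation option (within line combination) is
a possible extension; it is not implemented because the unstratified scheme
is the standard genome-wide practice and the cohort strata are tiny.

## Blocks and outcome groups

Significant loci are grouped per (model, direction): positioned loci on a
chromosome are sorted and chained while consecutive gaps are ≤ `gap_bp`
(default 5,000,000 bp — chosen because it reproduces the packaged table's
four ≥4-SNP rejection blocks while isolating the distant chromosome-4
singleton; configurable). A locus with known chromosome but unknown
position is attached to the chromosome's block when exactly one block
exists there for the stratum, otherwise reported unassigned; its position
never enters span computations. A locus whose alternative-assembly footnote
moves it to another chromosome is reassigned there *as position-unknown*,
since its printed coordinate belongs to the original chromosome. Loci with
unknown chromosome are singleton "unplaced" groups. Spans are
(max − min positioned)/10⁶, reported to one decimal; undefined below two
positioned members. Outcome-group counts at a locus are taken over
known-status pairs, and predictive accuracy is the concordant fraction
(matched-accepted + mismatched-rejected)/total.

## Synthetic cohorts

The generator's defaults encode the three-line study design: lines of
5/27/11 pigs with marginal fixation probabilities 0.86/0.71/0.78 and grafts
6/10/5 in the bb→cc, dd→cc and cc→cc combinations (a line may donate more
grafts than it has pigs: an animal can donate both corneas; recipients are
never reused).

Per SNP, with probability c (`shared_fixation_prob`) all lines fix the same
allele; otherwise each line independently fixes a random allele with
probability (f_l − c)/(1 − c), making f_l the line's *marginal* fixation
probability — so the homozygosity module should recover the configured f_l
directly. The default c = 0.355 was derived analytically so that the
three-line joint same-allele fixation fraction is 0.40 at the default f
values. Segregating sites draw their MAF from 0.5·Beta(3, 3.25)
(mean 0.24); the shape was chosen analytically so that chance sample
monomorphism at 27 pigs contributes < 0.003 to observed fixation, keeping
recovery within ±0.02 of f_l. Genotypes at segregating sites follow
within-line Hardy–Weinberg proportions — a documented simplification; real
semi-inbred line histories (bottlenecks, non-random mating) are not
modelled.

Linkage disequilibrium is produced by partitioning SNPs into blocks
(geometric sizes, mean 10 SNPs) and giving each line a pool of 4 block
haplotypes; every pig draws two pool haplotypes per block, so neighbouring
SNPs co-segregate and significant loci appear in blocks, as in real data.
Pool haplotypes at a segregating site are conditioned to carry both alleles
(truncated-binomial allele counts), which keeps drawn-as-segregating sites
segregating but biases the realised pool MAF upward — with the default
4-haplotype pool, mean segregating MAF comes out near 0.30 rather than
0.24. Homozygosity-focused simulations therefore use `ld=None`
(independent HWE sites), where the realised MAF mean matches the target.
X is simulated as autosomal.

Outcomes: a pair mismatched (under each causal locus's model) at one or
more planted causal loci is rejected with probability 1 − Π(1 − p_k) over
those loci's penetrances; otherwise with the background rate ε (default
0.05; set to 0 in the deterministic-outcome tests). Causal loci are forced
to segregate in every line. The truth record carries the causal loci, their
LD block ids, every locus's block id and each pair's causal-mismatch flag.

What passing tests on these cohorts do **not** show: robustness to
genotyping error, to departures from within-line HWE, to population
stratification beyond line labels, or to real array ascertainment bias.

## Problem sizes and tolerances

The packaged significant-SNP table analyses run in milliseconds. Simulation
checks use desk scales chosen for the default test run: fixation recovery
at 20,000 SNPs (±0.03, dominated by the binomial sampling of ~n_snps
Bernoulli fixation events, not by pig count), the full-array 59,852-SNP
single-line reproduction in the acceptance script (±0.02 observed across
seeds), null calibration at 2,000 loci, causal-block recovery over 20 seeds
at 2,000 SNPs, and permutation checks at a few hundred to a few thousand
draws (exact enumeration kicks in below C(N, r) ≤ n_perm). Numerical
conventions: float64 throughout; `xlogy` for 0·ln 0; statistics compared to
oracles at 1e-10 absolute.

## Known limitations

* PED/MAP parsing covers the whitespace dialect defined here, not the full
  range of PLINK binary/long formats; no VCF input and no assembly
  lift-over.
* The permutation scan holds the full pairs × loci status grid in memory;
  at 60k loci and 100k permutations it batches permutations (512 at a time)
  but still touches every locus per batch — minutes-scale, not
  seconds-scale, at full array size on one core.
* Printed block spans depend entirely on the coordinate assembly of the
  input map; loci placed only on an older assembly contribute membership
  but no length.
* With ~20 pairs the outcome-group accuracy of the *selected* top block is
  an optimistically biased estimate of predictive accuracy; the package
  reports the counts and leaves cross-validation to the user.
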