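# Methods

## Problem setting

`snpsig` analyses case/control cohorts for *combinatorial* genetic
association: instead of testing SNPs one at a time, it searches for small
sets of exact genotype states (e.g. "heterozygous at SNP a, homozygous
wild type at SNP b, heterozygous at SNP c") whose conjunction is enriched
in cases. Such disease signatures can capture epistatic structure that a
single-marker GWAS misses entirely — each component SNP may be nearly
null marginally (odds ratios 1.0–1.4) while the full combination carries
a several-fold risk. The package was built around post-viral fatigue
cohorts (long COVID / ME-CFS-like phenotypes, ~1,300 samples, ~280k SNPs
after QC), but nothing in it is phenotype-specific.

## Genotype representation and QC

Genotypes are dense samples × SNPs matrices of minor-allele counts
{0, 1, 2} with an explicit missing state that is never imputed. The minor
allele is determined empirically from the loaded cohort; when the
alternate-allele frequency is exactly 0.5 the alternate allele stays
minor, so the orientation is deterministic. QC removes samples below a
call-rate floor (default 0.95), then SNPs with call rate below 0.98 or
MAF strictly below 0.05 (a SNP at exactly the boundary is retained; the
exclusion rule is "< 5%"). Sample filtering runs first so that every
surviving SNP provably satisfies the MAF floor on the analysis cohort.
The call-rate defaults are conventional array-QC values and are
configurable; the MAF floor is the substantive filter, since signatures
built on rare genotypes cannot reach the prevalence threshold below.

## Symptom scoring and cohort construction

Per sample, the change score is the sum over symptoms of
(post-illness − pre-illness) integer severity, with scales oriented so
higher = worse. The "severe" cohort uses all symptoms; the "fatigue
dominant" cohort restricts the sum to fatigue-group symptoms. Cases are
samples with score ≥ the upper quartile; controls have 0 ≤ score < median;
everyone else — including samples that improved (negative change) — is
excluded from both groups, which is why cases + controls < full cohort.
Quantiles use linear interpolation between order statistics (numpy
default, "type 7"); ties at the Q3 boundary are cases. A distribution
with Q3 == median, or with no scores in [0, median), is rejected with an
error rather than silently producing a degenerate cohort.

## Signature mining

A candidate of order k is a set of k (SNP, state) features at distinct
SNPs; a sample is a member iff every component genotype matches exactly;
a missing component genotype makes the sample *incomplete* and it is
excluded from counts. Three filters define a reported candidate:

* case prevalence = case members / total cases ≥ 0.05;
* odds ratio relative to the cohort's mean odds,
  (a/b) / (A/B) with a/b the member case/control counts and A/B the
  cohort totals, > 1 (a zero control cell gets a Haldane–Anscombe +0.5,
  flagged);
* two-sided Fisher exact p < 0.05 on [[a, A−a], [b, B−b]].

The search is layered: all prevalence-eligible single features form
layer 1; layer k extends a beam of the most promising order-(k−1)
combinations (ranked by Fisher p, ties by odds ratio then a canonical
feature order) by one feature each. Crucially, *eligibility for
extension requires only the prevalence filter*, which is monotone under
conjunction — therefore with an unlimited beam the layered search
provably enumerates every combination that could pass the filters, and
equals brute-force enumeration (a tested oracle equivalence). The p and
odds-ratio filters decide what is reported, not what is extended; this
also means component SNPs are never required to be individually
significant, which is the entire point of combinatorial search.
Candidates whose feature sets are nested with identical membership
collapse to the smaller set. Results are deterministic given the
configuration seed and invariant to row/column order of the input (the
internal feature order is canonical by SNP id, and permutation streams
run over samples sorted by id).

Fisher p-values in the hot path come from a per-cohort cache: for fixed
case/control totals, the two-sided exact p for every possible case count
at a given membership size is tabulated once from the hypergeometric pmf
(same "sum of outcomes no more likely than observed" convention as
scipy, against which the cache is tested).

## Permutation validation (FDR)

Mined candidates are the extreme tail of ~10⁴–10⁶ examined combinations,
so any valid null model must reproduce the *selection*, not just the
test. Validation therefore randomizes whole datasets: the case/control
labels are shuffled and the entire layered search re-run per
permutation, collecting the p-values of all null discoveries. The
estimated false discovery rate at threshold t is

    FDR(t) = [(1 + Σ_perm #{null p ≤ t}) / (1 + n_perm)] / #{observed p ≤ t}

monotonized over t into per-candidate q-values (a plug-in/empirical-FDR
estimator with add-one smoothing); candidates with q ≤ 0.05 are
validated. On null data the observed and null discovery distributions
coincide and q ≈ 1, so essentially nothing validates; a planted
interaction has observed p orders of magnitude below any null discovery
and validates immediately. The per-seed realized FDP is binary in
practice (a dataset either yields a false validation or none), so the
nominal level is checked as a mean over repeated simulations with
Monte-Carlo slack.

The classic per-candidate route — empirical p =
(1 + #{perm p ≤ observed p}) / (1 + n_perm) with Benjamini–Hochberg
across candidates — is provided separately (`mining.permutation_fdr`)
and is appropriate only for candidate lists fixed *before* seeing the
data; applied to search-selected candidates it would validate everything
by construction.

A per-SNP allelic Fisher test (`single_snp_association`) provides the
GWAS baseline, with the conventional 5 × 10⁻⁸ flag.

## Disease architecture and critical SNPs

Validated signatures merge into a weighted graph over features: each
signature induces a clique (edge weight = cases carrying a signature
containing both endpoints), and features of different signatures are
linked when their signatures share case members (weight = shared case
count). Communities come from greedy modularity maximization with a
pinned tie-break (node insertion in canonical feature order). SNPs in
multiple signatures are *critical SNP* candidates; each is scored two
ways: (1) mean stratified 5-fold CV accuracy of a 100-tree Random Forest
on the SNP's one-hot genotype states, by default together with its
signature partners' states (both modes available, partners on by
default since the signature — not the lone SNP — carries the signal);
(2) a permutation test on how many of the SNP's signatures survive the
mining filters under label shuffling, restricted to the SNP's observed
partner space for tractability. The critical call couples permutation
p ≤ 0.05 with an RF accuracy above the majority-class baseline.

## Gene mapping

Cascade mapping: a SNP inside an annotated CDS interval maps directly to
that gene (class `coding_direct`, distance 0; overlapping genes all
map). Otherwise the SNP maps to the nearest gene whose strand-aware
window — 2 kb upstream of the transcription start through 0.5 kb
downstream of the gene end, including the gene body — contains it
(class `proximal`; distance is the bp gap to the gene span, 0 for an
intronic SNP). "Coding region" is read as CDS, so intronic SNPs fall
through to the proximal rule; ties at equal distance return all tied
genes. The 10 kb gene-window selector used to pick seed SNPs for
cross-cohort analyses is strand-agnostic on both sides with inclusive
boundaries.

## Expanded genotypes analysis (EGA)

For a k-SNP signature (k ≤ 3), all 3^k full genotype assignments are
enumerated with case/control counts over complete-genotype samples;
assignments carried by fewer than 15 patients are excluded from
comparisons but retained in the partition (counts always sum to the
complete-genotype cohort). Orders 4–5 are rejected outright — 81 or 243
cells leave too few patients per cell. For a chosen critical SNP,
assignments sharing the same interacting genotypes form a block: the
EGA odds ratio divides the disease odds at critical state 1 (or 2,
separately) by the odds at critical state 0, with a Woolf (log-normal)
95% interval. No continuity correction: a zero cell marks the block
incomplete rather than inventing a finite ratio.

The per-SNP pattern over complete blocks is classified with rules that
formalize the seven descriptive categories (this package's
operationalization, since no formal definitions were published):

1. < 2 complete blocks → ambiguous (insufficient data);
2. all blocks one direction (OR = 1 is neutral) → universally
   causative/protective;
3. blocks where one interacting SNP — or any interacting SNP — carries
   a minor allele share direction D and all remaining blocks are
   opposite or neutral → SNP-specific, labelled by D;
4. with ≥ 2 interacting SNPs, exactly one block carries direction D and
   more than one block is opposite → combination-specific, labelled by
   D (with a single interactor a one-cell effect is not a "combination"
   and falls to ambiguous);
5. otherwise ambiguous.

A pooled carrier test (critical minor-allele carriers vs homozygous wild
type, two-sided Fisher) is available within any stratum expressible over
interacting genotypes, for the common "pool all carriers" summary.

## Ancestry screening, enrichment, seeded mining

Each signature is refit separately in a maximum-likelihood logistic
regression case ~ intercept + membership + binary ancestry; the Wald p
of the membership coefficient is Bonferroni-corrected across signatures
(BH available by flag; Bonferroni is the default as specified, despite
being family-wise rather than FDR control) and the signature fails when
the adjusted p ≥ 0.05. Perfect separation or non-convergence falls back
to a small-ridge penalized Newton fit with Hessian-based standard
errors, flagged in the output. Phenotype enrichment compares carriers
against the *rest of the cases* (never against controls): pooled
two-proportion Z for categorical variables, two-sided Mann–Whitney U
(asymptotic, tie-corrected) for continuous ones, BH across phenotypes;
groups under 5 are flagged underpowered but reported. Seeded mining
reuses the identical search and validation with layer 1 restricted to
features at seed SNPs, so every candidate contains at least one seed;
FDR is computed within that reduced space.

## Synthetic data generator

Per SNP an ancestral allele frequency is uniform on [0.05, 0.5];
population structure uses the Balding–Nichols model (per-population
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with a single divergence
parameter per population); genotypes are Hardy–Weinberg Binomial(2, p);
missing calls are uniform at rate 0.01 by default. Disease follows a
multiplicative odds model: baseline odds 0.2 (≈17% prevalence, so that
upper-quartile case selection can capture essentially all diseased
samples), optionally multiplied per population (to create genuine
ancestry confounding) and by the multiplier of every planted genotype
combination the sample carries. Planting is interaction-only: the
multiplier applies to the full combination, leaving component SNPs
individually near-null. The default planted signature is three
heterozygotes at frequency-0.4 SNPs (carrier prevalence 0.48³ ≈ 11%)
with multiplier 5, matching the motif of individually weak SNPs
combining to a strongly elevated signature odds ratio. Symptoms: 7
symptoms in 3 groups on a 0–10 integer scale; pre scores Binomial(10,
0.15); a per-sample integer total deterioration (normal, mean 10 for
diseased vs 1 for healthy, SD 2, multinomially spread over symptoms)
is added and clipped to the scale.

What the generator does *not* emulate: linkage disequilibrium (SNPs are
independent given population), realistic chromosome maps, genotyping
batch effects, informative missingness, covariate structure beyond
binary ancestry, and symptom scales with heterogeneous ranges. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to LD-induced redundancy or
array artefacts in real data.

## Standard problem sizes

The reference experiments (shared by the validation suite and
`scripts/acceptance.py`) use: null FDR — 1,000 samples × 500 SNPs, pair
search with beam 30, 199 permutations; planted recovery — 2,000 × 500,
triplet search with beam 150, 49 permutations; EGA classification —
5,000 samples; confounder screen — 2,000 samples, two populations at
divergence 0.05. Beam widths were chosen so that a marginally weak but
genuine component feature (single-SNP p ≈ 0.05 among 1,500 features)
reliably stays in the extension beam; permutation counts so that the
smallest resolvable q (≈ 1/(n_perm+1) per observed discovery) sits well
below the 0.05 validation threshold.

## Numerical and degenerate-input choices

Fisher two-sided ties use scipy's 1+1e−7 relative tolerance so the
cached and direct routes agree exactly. Odds ratios relative to mean
odds use Haldane +0.5 only on the signature's cells and only when the
control cell is zero. Undefined quantities are NaN, never 0 or 1: MAF of
an all-missing SNP, r² of a constant genotype vector, an EGA ratio with
a zero cell. Monomorphic SNPs report association p = 1. All stochastic
procedures take explicit seeds and are reproducible bit-for-bit;
ranking ties anywhere in the search break on a canonical
(snp_id, state) order so results cannot depend on input layout.

## Known limitations

Beam search with a finite beam is heuristic above order 2: a combination
whose lower-order projections are all weak can be missed (the unlimited
beam is exhaustive but exponential). The dataset-randomization FDR
estimate is conditional on the search configuration — changing beam
width or max order changes the null discovery distribution and must be
mirrored in the permutations (the implementation does this
automatically). The EGA category rules are a formalization of
descriptive category names and can disagree with other reasonable
operationalizations in edge cases (e.g. one-cell effects). Logistic
screening assumes a binary ancestry summary; it is not a substitute for
full population-structure correction in cohorts with continuous
admixture.
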