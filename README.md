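# snpsig

Combinatorial SNP-genotype disease-signature analysis for case/control
cohorts: mining, permutation validation, network scoring, gene mapping
and expanded-genotypes causality assessment — plus a synthetic-data
generator that plants known epistatic signatures so the whole pipeline
is verifiable without access to private study genotypes.

## Who this is for

Statistical geneticists and bioinformaticians studying complex,
heterogeneous phenotypes (the package grew out of post-viral fatigue /
long-COVID-type cohorts) where single-marker GWAS finds nothing: no SNP
reaches 5 × 10⁻⁸, yet risk may be carried by *combinations* of common
genotypes. `snpsig` searches for those combinations directly.

## The model

A **disease signature** is a set of 1–5 features, each an exact genotype
state at a SNP (0/1/2 minor-allele copies). For a signature with `a`
case and `b` control carriers in a cohort of `A` cases and `B` controls,
its odds ratio is measured against the cohort's mean odds,

    OR = (a / b) / (A / B),

with a two-sided Fisher exact p on `[[a, A−a], [b, B−b]]`. Signatures
are mined in layers of increasing order (singletons → pairs → triplets …)
under three filters: case prevalence ≥ 5%, OR > 1, p < 0.05 — and then
validated by re-running the *entire search* on label-permuted datasets,
which yields selection-aware q-values (an empirical FDR; see
`docs/methods.md`). Validated signatures merge into a disease-architecture
network whose recurrent hub SNPs ("critical SNPs") are scored by
Random-Forest 5-fold CV and a permutation test, then cascade-mapped to
genes (CDS containment first, else a 2 kb-upstream / 0.5 kb-downstream
window).

The **expanded genotypes analysis (EGA)** probes causality: a k-SNP
signature defines 3ᵏ full genotype assignments; holding the interacting
SNPs' genotypes fixed, the EGA odds ratio

    EGA OR = odds(critical state 1 or 2) / odds(critical state 0)

isolates the critical SNP's own contribution, and the pattern of
directions across assignments classifies its minor allele as
universally / SNP-specifically / combination-specifically causative or
protective (or ambiguous).

## Worked example

```python
import snpsig as sg

# a published severe-cohort example: 459 cases / 864 controls,
# 3-SNP signature carried by 57 cases and 23 controls
a, b, orr, p = sg.signature_stats_from_counts(57, 23, 459, 864)
print(f"signature OR = {orr:.2f}")          # signature OR = 4.66
for counts in [(396, 703), (164, 226), (141, 186)]:
    print(f"component OR = {sg.signature_stats_from_counts(*counts, 459, 864)[2]:.2f}")
# component OR = 1.06 / 1.37 / 1.43 — individually near-null SNPs

# EGA block: heterozygous 17:19 vs wild type 74:160
orr, (lo, hi) = sg.ega_odds_ratio(17, 19, 74, 160)
print(f"EGA OR = {orr:.2f} (95% CI {lo:.2f}-{hi:.2f})")
# EGA OR = 1.93 (95% CI 0.95-3.93)
```

End-to-end on synthetic data:

```python
cfg = sg.SimulationConfig(random_seed=1)      # 2,000 x 500, one planted
ds = sg.simulate_dataset(cfg)                 # 3-SNP signature, odds x5
cohort = sg.CohortAssignment.from_labels(ds.disease.to_numpy(),
                                         ds.matrix.sample_ids)
mcfg = sg.MiningConfig(max_order=3, n_permutations=49, random_seed=1)
validated = [s for s in sg.mine_signatures(ds.matrix, cohort, mcfg)
             if s.validated]
print(sg.recovery_fraction(ds.truth, validated))   # 1.0
print(sorted(validated[0].features))
# [('snp00000', 1), ('snp00001', 1), ('snp00002', 1)]  <- the planted triple
```

There is also a small CLI (`snpsig simulate`, `snpsig qc`,
`snpsig mine`) over the same functions.

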