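# Methods

## Scope and model

The package analyses the transferability of established quantitative-trait
GWAS loci across populations. The canonical workflow is:

1. per-cohort association of the trait (HbA1c, %) on allele dosage,
   adjusted for age, sex and optional principal components;
2. SNP QC and per-cohort genomic control;
3. fixed-effect inverse-variance (IVW) meta-analysis across cohorts,
   optionally two-stage (cohorts of one ethnicity first, then across
   ethnicities);
4. replication classification of literature index SNPs, direction
   concordance, and analytic power;
5. population-differentiation metrics (regional F_ST, haplotype entropy)
   around each index SNP, compared between replicated and failed loci;
6. T2D-stratified logistic association of the index SNPs with binary
   complications (CKD, retinopathy), meta-analysed within and across
   strata.

## Association tests

`linear_assoc` is OLS with intercept; the dosage P value is the two-sided
Wald test against the t reference. `logistic_assoc` is ML logistic
regression; separation is detected (non-convergence or exploding SE) and
flagged with absent estimates rather than raised, since a genome-wide
screen must survive degenerate SNPs. Dosages are continuous in [0, 2];
rows with any missing value are deleted list-wise and the used n is
reported.

The Hardy–Weinberg test is the exact conditional test: all heterozygote
counts compatible with the observed allele counts are enumerated (in log
space, so counts in the thousands are fine) and the P value is the summed
probability of configurations no more probable than the observed one. The
exact test rather than the chi-square is the right tool for the 10⁻⁶ tail
used in QC. QC boundary semantics are inclusive/exclusive exactly as
conventionally stated: MAF < 1% removed, missingness > 5% removed, HWE
P ≤ 10⁻⁶ removed, INFO ≥ 0.5 retained; genotyped SNPs (absent INFO) skip
the INFO rule.

## Meta-analysis, SE recovery, genomic control

IVW: $w_i = SE_i^{-2}$, $\hat\beta = \sum w_i \beta_i / \sum w_i$,
$SE = (\sum w_i)^{-1/2}$, P from the normal reference (large-sample,
matching standard GWAS meta tools). Two-stage IVW without inter-stage
adjustment is algebraically identical to the flat combination; the
identity is asserted to 10⁻¹² in tests.

Published tables often print only (beta, P). `recover_se` inverts the
two-sided normal test, $SE = |\beta| / \Phi^{-1}(1 - P/2)$. Because
printed values carry ~3 significant digits, reproduction of combined
betas is asserted to ±0.001 and combined P values are not asserted. A
printed beta of exactly 0 has no recoverable SE; such component studies
are omitted from re-combinations, which preserves the sign but not the
exact magnitude of the printed combined estimate (the omitted study's
weight is redistributed).

Genomic control: $\lambda = \mathrm{median}(\chi^2_1)/0.4549$ (the 1-df
chi-square median at 4-decimal precision). Because meta-analysis consumes
(beta, SE) pairs, the adjustment is implemented as SE inflation by
$\sqrt{\max(\lambda, 1)}$, equivalent to dividing the chi-square by
lambda. λ < 1 is reported as a diagnostic but never used to deflate, per
standard practice.

## Transferability

Replication is P ≤ α (inclusive), α = 0.05 by default. Direction
concordance is a sign comparison with the reported (European) effect; an
exactly zero target estimate is discordant by convention and flagged.
"Similar effect size" is deliberately operationalised as direction
concordance only — no magnitude-similarity threshold is invented.

Analytic power uses the 1-df non-central chi-square with
NCP = n·2p(1−p)·β²/σ², i.e. the dosage variance under Hardy–Weinberg
proportions times the squared standardised effect. β is the effect
*estimated in the target population* (the question being whether the
cohort could detect the association at the size it locally shows), p the
target-population EAF, and σ the trait SD (default 0.4%, configurable;
one studied cohort shows 0.3%). Meta power sums the per-cohort
non-centralities with cohort-specific EAFs. Empirical rejection
frequencies on cohorts simulated at the assumed model match this formula
within binomial error at powers 0.2/0.5/0.9 (500 replicates each, tested
in the acceptance suite).

## Population differentiation

SNP-level F_ST uses Hudson's estimator,

    [(p_a − p_b)² − p_a(1−p_a)/(n_a−1) − p_b(1−p_b)/(n_b−1)]
    / [p_a(1−p_b) + p_b(1−p_a)],

chosen for its lack of sample-size/MAF bias; Weir–Cockerham is available
behind a flag. Regional F_ST defaults to the unweighted mean of per-site
estimates over the shared sites within ±50 kb (inclusive) of the index
SNP, with undefined sites (both populations fixed for the same allele)
skipped. The ratio-of-sums aggregation (summed numerators over summed
denominators) is available via `method="ratio"`; it is the recommended
multi-SNP combination because the mean of per-site ratios is a ratio
estimator whose expectation falls measurably below the simulation truth
at strong differentiation (in our Balding–Nichols recovery runs the mean
mode under-estimates F = 0.3 by ~30% while ratio-of-sums is within ~2–4%
across F = 0.01–0.3). Parameter-recovery validation therefore uses the
ratio mode; both modes are strictly ordered in F.

Haplotype metrics: haplotypes are formed over the window's sites shared
by the two panels and polymorphic in at least one (monomorphic-in-both
sites are dropped from the string). A haplotype is retained when its
frequency reaches 2% in *at least one* population (union rule); the
strict both-populations reading would exclude every private haplotype and
force the entropy toward 0, defeating the metric's purpose. The
intersection rule is available for sensitivity analysis. For haplotype i,
RMI(i) = 1 + (F_A log F_A + F_B log F_B)/log 2 with
F_j = f_ij/(f_iA + f_iB) and 0·log 0 ≡ 0; the regional entropy is the
f_i•-weighted mean of RMI, where f_i• may be the sum or the mean of the
pair — the weighting normalises, so the two definitions provably
coincide (asserted to 10⁻¹² on random tables).

The replicated-vs-failed comparison is a pooled-variance two-sample t
test, one-tailed for mean(replicated) < mean(failed). A zero-pooled-
variance degenerate input yields P ∈ {0, 0.5, 1} by sign convention with
a warning.

## Complication analysis

T2D case: HbA1c ≥ 6.5% or self-reported history. T2D control: HbA1c < 6%
and no history (fasting-glucose cohorts: FG ≤ 6 mmol/L and no history).
The 6.0–6.5% band without history is excluded — the case and control
definitions are asserted never to overlap. CKD case: 0 ≤ eGFR < 60;
control ≥ 60. DR cases: grade ≥ 30 (moderate/severe) or ≥ 14 (any);
controls < 14 under both. eGFR is an input field; its derivation from
creatinine is out of scope.

The stratified analysis fits per-cohort logistic models within each T2D
stratum, IVW-combines log-ORs across cohorts within stratum, and forms
the "combined" row as the IVW of the two stratum results (rather than a
pooled regression): the combined OR is therefore always between the
stratum ORs on the log scale. Cells with a single outcome class or a
separated fit are dropped with a diagnostic. The default covariate policy
is none (PCs optional), matching the convention for these analyses.
Bonferroni control uses α/(n_snps × n_phenotypes); the default
0.05/(15×4) = 8.3×10⁻⁴.

## Synthetic data: what it emulates and what it does not

`draw_population_freqs` implements the Balding–Nichols model — population
frequency ~ Beta with mean p and variance F·p(1−p) — chosen because its
F parameter is also the expected SNP-level F_ST, giving the estimators an
analytic target. `simulate_panel` builds haplotypes as mosaics of a
founder set with switch points on a `block_length` grid; when
`n_founders == n_haplotypes` founders are assigned by per-block
permutation so site frequencies are exactly binomial around the drawn
population frequencies (used for frequency-level validation), while a
small founder count (8–16) creates the shared multi-site haplotypes the
entropy metrics need.

`simulate_panel_pair` has two modes. The default draws independent
founder sets per population: SNP-level divergence follows the analytic
F_ST target exactly, but the populations share no multi-site haplotypes —
appropriate for allele-frequency metrics only. `shared_founders=True`
draws one common founder pool used by both populations with
population-specific Dirichlet(α) weights, α = (1−F)/(K·F) for K founders,
so each founder's usage frequency has mean 1/K and Balding–Nichols
variance F·(1/K)(1−1/K): haplotype sharing then decays smoothly with F
(measured mean entropy ≈ 0.05/0.20/0.38/0.51 at F = 0.01/0.05/0.15/0.3
with K = 12), which is the structure the entropy metric measures.

Quantitative cohorts: HbA1c = intercept (5.71%) + β·dosage + small age
and sex effects + N(0, 0.4²), dosage ~ Binomial(2, EAF); the defaults
mirror the demographic scale of the studied cohorts (age ≈ 52 ± 11). 
Complication cohorts draw the binary outcome from a logistic model in
dosage with the intercept solved so the dosage-averaged prevalence hits
the target (22.1% CKD among T2D cases, 6.9% among controls at the
studied scale), then populate eGFR/grade so the threshold classifiers
reproduce the drawn labels exactly; `t2d_mixture` controls the fraction
meeting the T2D-case definition, with the remainder clean controls.

Not emulated: realistic recombination maps or coalescent genealogies,
imputation uncertainty (INFO is carried but not generated from a model),
cryptic relatedness and population stratification within a cohort, and
any correlation between the complication outcome and HbA1c beyond the
stratum labels. Passing tests therefore demonstrate estimator
correctness and calibration under the stated generative model, not
robustness to those real-data complications.

## Problem sizes and numerical choices

Stochastic validations use sizes chosen to make Monte-Carlo error small
relative to the asserted tolerances: 10⁴ haplotypes × 100 sites × 20
seeds for F_ST recovery (recovery asserted within 10%), 10⁵ SNPs for
genomic-control calibration (λ within [0.98, 1.02]), 500 replicates per
power point at n = 800, and 200 replicates at the published stratum
sizes (2072/5201) for interval coverage (≥ 90% observed against the
nominal 95%). Seeds are fixed throughout; all generators are
deterministic under a seed and record it in output metadata.

Ties and degeneracies: the exact HWE P sums probabilities ≤ the observed
one with a 1+10⁻¹² relative tie guard; IVW with a single study is a
passthrough; `count_significant` treats P = α as significant (inclusive
throughout); regional windows are inclusive on both ends; 1-based
coordinates everywhere.
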