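# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the verification experiments behind `prsgxe`.

## The analysis

The pipeline estimates how an ordinal cannabis-use exposure relates to four
self-reported psychotic-experience items (auditory hallucinations, visual
hallucinations, persecutory delusions, delusions of reference, plus a derived
"any" outcome), and whether schizophrenia polygenic risk modulates that
relationship.

**Polygenic risk score (P+T).** The score is built by pruning and
thresholding. Cohort variants pass QC when they are non-duplicate autosomal
SNPs with call rate > 0.95, exact Hardy–Weinberg p > 1e-10, minor allele
frequency > 0.001 and imputation info > 0.8 (all strict inequalities; a value
sitting exactly on a bound fails). The allele-frequency bound is interpreted
as a minor-allele-frequency bound: filtering only the alt-allele frequency
would wave through monomorphic variants whose reference allele happens to be
the minor one. External GWAS records are matched to the panel by chrom:pos
with allele verification (IDs are labels only, robust to ID-version drift),
oriented by exact allele match first and strand complement second, and
dropped when palindromic (A/T, C/G) — strand is unresolvable from the alleles
alone. An effect reported on the reference allele is stored as weight `-beta`
plus a per-variant offset `2*beta`, the identity `beta*(2-d) = -beta*d +
2*beta`. The p-value cutoff is chosen from {0.05, 0.005, 0.0005, 0.00005} by
case/control AUC for the schizophrenia label, ties to the less strict
candidate; by default each candidate is pruned before its AUC is computed (a
flag gives the pre-prune alternative, since either order is defensible).
Pruning is a greedy genome-order scan to r² < 0.5 within a 500 kb window
(inclusive endpoints, pairwise-complete correlations); when two variants
conflict the one with the larger GWAS p-value is dropped — keeping the
stronger association signal, the common practice — with position as the tie
break. Scores are weight-times-dosage sums with per-variant mean imputation
of missing genotypes over the scoring cohort.

The Hardy–Weinberg filter uses the exact conditional test (sum of
probabilities of heterozygote counts, with the observed allele margins and
parity, no more probable than the observed count), which stays well defined
at the rare-genotype counts where the chi-square approximation fails.
Fractional (imputed) dosages are rounded to hard calls when every call is
within 0.1 of an integer; otherwise the variant is exempted from the HWE
filter and logged.

**Association models.** Each outcome is regressed on the exposure and
covariates by maximum-likelihood logistic regression. Exposure codings:
ever/never binary; ordinal risk units (never=0, ever=1, monthly=2, weekly=3,
daily=4); or per-category indicators against never-use, fitted as one model
so all categories share a single covariate adjustment (a pairwise alternative
can be assembled from the same pieces). Categorical covariates expand to k−1
indicators against their most frequent level — deterministic and never a
sparse reference. Effects are reported as AOR = exp(β) with Wald 95%
intervals exp(β ± 1.96·SE). Differences between two log odds ratios use
D/√(SE₁²+SE₂²) against the standard normal. Rows missing any required value
are dropped listwise per model; per-item missingness is preserved so each
outcome keeps its own denominator.

The likelihood is maximized by Newton/IRLS (statsmodels `Logit`,
gradient tolerance 1e-8, 100 iterations); standard errors come from the
inverse observed information. Non-convergence and apparent separation (any
|β| > 15) are flagged on the result rather than raised, since stratified and
small-cell fits legitimately produce them; flagged rows are reported as such.

**Interaction test.** The gene–environment test compares nested logistic
models by a 1-df likelihood-ratio chi-square: the full model adds the
exposure-by-PRS product to a reduced model containing exposure, PRS,
covariates, and — in both models — covariate-by-exposure and
covariate-by-PRS products (the Keller adjustment, which stops confounder
interactions from loading onto the genetic product term). The PRS is
standardized to mean 0, SD 1 over the analysis rows before any product is
formed; by the affine invariance of nested comparisons this changes no
p-value (verified to 1e-6) but keeps the information matrix well scaled.
Collinear columns are removed by incremental Gram–Schmidt (relative
tolerance 1e-8) identically from both designs, with the exposure-by-PRS term
protected so a covariate that duplicates it is dropped instead and the test
keeps its single degree of freedom. BH step-up FDR
(adj₍ᵢ₎ = min over j≥i of p₍ⱼ₎·n/j, capped at 1) is applied within each
exposure's five outcome tests, mirroring how the five-test families are
corrected in the target analysis; a flag switches to one joint family.
"Additive interaction" here means the product term on the log-odds scale —
no additive-risk-scale (RERI) measure is computed.

**Quintile stratification.** PRS quintiles are assigned positionally from a
stable argsort, so bin sizes never differ by more than one and tied values
split by input order. Within a quintile the ever-use AOR is fitted with the
usual covariates but no PRS terms — the PRS is the stratifier.

## The synthetic cohort generator

The generator produces the three inputs the pipeline needs with the
statistical structure the analysis assumes. It is a testing substrate, not a
model of any real population.

*Genotypes.* Each individual carries two independent haplotypes. Within an
LD block the latent Gaussian follows an AR(1) with parameter `ld_rho`, and
the allele is the indicator z < Φ⁻¹(MAF). Independence of the haplotypes
gives exact Hardy–Weinberg proportions per variant. The realized dosage
correlation is the tetrachoric attenuation of the latent correlation —
(2/π)·asin(ρ) at MAF 0.5, so ρ = 0.9 yields dosage r ≈ 0.71 — which a
Monte-Carlo check in the test suite confirms; `ld_rho` should therefore be
read as a latent, not a dosage, correlation. Blocks never span chromosomes;
positions step 2–20 kb so a default block sits well inside the 500 kb
pruning window. A configurable fraction of variants gets palindromic
ref/alt pairs and a fraction gets info scores below 0.8, so harmonization
and QC have real work to do.

*GWAS summary statistics.* True per-allele log odds ratios are
spike-and-slab (zero with probability 1−`causal_fraction`, else
N(0, `effect_sd`²)). The reported estimate adds N(0, se²) noise with
se = 1/√(2f(1−f)·`gwas_n`), and the p-value is the two-sided Wald test.
Records are reported with randomly swapped effect/other alleles (sign
follows the effect allele) and randomly flipped strand.

*Phenotypes.* Genetic liability is the standardized true-weight score. The
schizophrenia label thresholds liability + N(0,1) at the (1−prevalence)
quantile. The exposure comes from ordered thresholds on a latent normal
correlated with liability at `gec_rho` (default 0 — the null is kept simple,
one parameter probes gene–environment correlation when wanted). Each
psychotic-experience item is Bernoulli with logit
β₀ + β_exposure·X + β_prs·L + β_gxe·X·L + covariates, X being the risk-unit
coding. `pe_any` is derived — 1 if any non-missing item is endorsed, missing
only when all four are — and onset age, distress and help-seeking exist only
for individuals with an experience, drawn independently given that (no joint
model is attempted).

Defaults are the cohort conditions the pipeline targets: exposure category
probabilities from the observed frequency counts (87,010 / 14,642 / 2,671 /
3,582 / 1,403 over 109,308, i.e. ~80% never-users), per-item intercepts at
the logit of the never-user prevalences (1.3%, 2.8%, 0.6%, 0.6%), per-item
exposure slopes at the published per-risk-unit AORs (≈ln 1.2), and per-item
outcome missingness of ~0.5%, matching the observed non-missing ranges.
β_prs = ln 1.3 per SD and β_gxe = 0.05 are generator choices of plausible
magnitude — the default interaction is deliberately subtle; the `power`
preset uses β_gxe = 0.25, the value the recovery experiments target.
GWAS architecture defaults (30% causal, effect SD 0.02, N = 100,000) give a
strongly informative score; they are architecture knobs, not estimates.

One global seed feeds named substreams (genotypes, sumstats, phenotypes) via
`SeedSequence` spawn keys, so any stage can be regenerated independently and
serialized bundles are byte-identical per seed.

What the generator does **not** emulate: real human LD maps and allele
frequency spectra, ancestry structure and relatedness, genotype-imputation
error (info scores are metadata only), correlated psychotic-experience items
beyond their shared linear predictors, and any gene–environment correlation
unless asked for. Passing tests therefore demonstrate that the machinery is
correct under its stated assumptions, not that the pipeline's estimates on
real biobank data would be unbiased.

## Verification experiments

Problem sizes were chosen so every study answers its question with clear
Monte-Carlo margins on a single CPU.

- **Type-I error.** 1,000 replicates at n = 2,000 with β_gxe = 0, testing
  the visual-hallucination item (a directly generated item gives a correctly
  specified null; the derived `pe_any` is non-collapsible — combining items
  whose logits are additive in X and L yields an "any" outcome whose logit
  is not, which manifests as genuine spurious interaction). The replicate
  panel is 150 variants with no missingness: the LRT operates on the cohort
  table, so the panel only has to furnish a liability. Measured rejection at
  α = 0.05 sits near 0.053; larger side-runs put the true rate around
  0.05–0.06, i.e. the asymptotic test is mildly anticonservative at ~70
  events and 10 parameters, a known small-sample effect.
- **Recovery.** β_gxe = 0.25, 100 replicates at n = 5,000, fitted with the
  true standardized liability as the PRS column: the experiment certifies
  the estimator, and a GWAS-estimated score would attenuate the coefficient
  by its measurement error — a property of PRS estimation, not of the test.
  Mean estimate lands within a few thousandths of truth; CI coverage ~0.96.
- **Threshold selection.** Dense weak architecture (30% causal, effect SD
  0.008 against a GWAS SE of ~0.007 at N = 50,000) so stricter cutoffs
  discard real signal; the AUC evaluation cohort is case-enriched
  (prevalence 0.2, n = 5,000 → ~1,000 cases) so the AUC's Monte-Carlo error
  is small against the between-threshold differences, as in case-control
  tuning panels. The least strict cutoff wins and the profile declines in
  ≥9 of 10 seeds.
- **Power.** One genotype panel at n = 20,000 × 2,000 variants with
  β_gxe = 0.25; the PRS is built once (its correlation with true liability
  is ~0.83–0.86), then 20 phenotype replicates are drawn over the fixed
  panel — the phenotype process is the replication unit — and the full
  10-test suite runs on each. Detection (any BH-FDR ≤ 0.10) occurs in
  every replicate.

## Numerical conventions and edge cases

- Missing token in every TSV is `NA` (empty string accepted on read);
  positions are 1-based as in VCF; pruning windows include both endpoints.
- Constant-dosage variants have undefined correlation; pruning treats them
  as r² = 0 and logs them. Variants entirely missing in a scoring cohort are
  dropped with a warning — a mean-imputed value would be unidentified.
- `lrt` tolerates chi-square down to −1e-6 (rounded to 0) before declaring a
  convergence failure; BH inputs must lie in (0, 1].
- Cohort assembly applies exclusions in a fixed order (diagnosis flag →
  missing ever-use answer → all items missing) and attributes each row to
  its first failing rule, so the assembly report reconciles exactly.
- Never-users with a missing frequency answer get frequency 0: they are
  never asked the frequency question.
- Onset dichotomies use strict "< 18" for early onset; the boundary age 18
  is adult onset, and each quality-split analysis excludes the complementary
  cases rather than treating them as controls.

## Known limitations

- The logistic LRT inherits the asymptotics of maximum likelihood: with rare
  outcomes and small cohorts it runs slightly hot (see above). No Firth or
  exact correction is applied; separation is flagged, not repaired.
- Quintile assignment is positional, so heavily tied scores are split by
  input order rather than kept together; bin sizes are guaranteed within one
  of each other, at the cost of arbitrary assignment inside a tie block.
- The harmonizer resolves orientation from alleles alone and therefore must
  discard palindromic variants even when an allele-frequency comparison
  might rescue them.
- The AUC-based threshold selection reuses the same cohort for selection and
  reporting; no cross-validation is attempted.
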