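# Methods

## Liability-threshold simulation

Disease status is generated under a liability-threshold model. Each sample's
latent liability is

```
L = Σ_j z_j β_j  +  e4·b4 + e2·b2 (standardized)  +  ε,   ε ~ N(0, 1 − h² − V_APOE)
```

where `z_j` are standardized dosages, the polygenic effects `β_j` are i.i.d.
N(0, h²/m_causal) on a random causal subset (probability `pi_causal` per
variant), and the two APOE-like ε-defining sites carry fixed per-allele
effects `apoe_beta_e4`/`apoe_beta_e2` converted to the standardized scale.
`V_APOE` is the liability variance of the ε terms computed from the
haplotype frequencies (including the negative covariance between ε2 and ε4
alleles, which never share a haplotype). A sample is a case iff
`L > Φ⁻¹(1 − K)` for prevalence `K`; cohorts are ascertained by rejection
sampling until the requested case and control counts are reached (cap 10⁷
population draws).

### LD model

Haplotype alleles within a block are produced by thresholding a latent AR(1)
Gaussian (parameter `block_rho`) at each variant's allele-frequency quantile;
dosage is the sum of two independent haplotypes, so every variant is
marginally Binomial(2, MAF) while neighbours show geometrically decaying r².
Blocks are mutually independent. This is deliberately simple — no
recombination maps, no population structure, no imputation uncertainty — but
gives a tunable, analytically transparent LD decay, which is what clumping
needs to be exercised against.

### APOE-like locus

One block on its own chromosome (19) holds two designated biallelic sites
playing the rs429358/rs7412 roles. Haplotypes are drawn from a three-class
(ε2/ε3/ε4) frequency model, defaults 0.08/0.72/0.20, which yields ~36% ε4
carriers in the population and ~30% in ascertained controls. Additional tag
variants copy the ε4 haplotype indicator with probability `apoe_tag_prob`
(default 0.6), creating the high-LD region that the region-exclusion analyses
target. The default per-allele liability effects (+0.7 for ε4, −0.3 for ε2 on
the probit scale) were chosen to reproduce the carrier enrichment seen in
real AD case/control tables (ε4 roughly doubling in cases, ε2 halving); the
generated cohorts show, e.g., 71% vs 36% ε4 carriers in cases vs controls at
the default configuration.

### Paired discovery GWAS

Trait A's marginal truth is the LD-convolution `R β` of the causal effects,
with `R` the population dosage correlation estimated per block on an
independent unascertained reference sample (4000 samples, child seed). Trait
B's truth is `rg·bm_A + √(1−rg²)·bm_ind` where the independent component is a
fresh polygenic draw of the same law **without** the fixed ε-site effects:
those are deterministic configuration values, so re-drawing them would make
the "independent" component perfectly shared at the major locus and push the
cross-trait correlation above `rg`. A consequence, accepted deliberately, is
that trait B's APOE signal scales with `rg` — an attenuated major locus, as
observed in proxy-phenotype GWAS. Reported effects are per-allele:
`β̂ = bm/sd + N(0, SE²)` with the standardized-trait approximation
`SE = 1/√(2p(1−p)·n_gwas)`; `n_gwas = inf` is the noiseless limit. P-values
are two-sided Wald. Default discovery sizes are 63,926 (trait A,
clinical-scale) and 487,511 (trait B, proxy-scale); default `rg` is 0.8, a
configuration choice in the realistic range for a clinical trait vs its
family-history proxy, not an estimate.

### Microglia-like annotation

Contiguous regions are placed to cover ≈`microglia_fraction` (default 3%) of
the panel, always including a sub-interval of the APOE block that contains
tag variants but excludes both ε-defining sites — mirroring annotations in
which the APOE region is regulatory-active but the coding risk sites
themselves fall outside the called regions.

### What the generator does not emulate

Real recombination and reference-panel LD, ancestry structure and admixture,
imputation error (INFO is carried as metadata, not modelled), X chromosome,
age/sex effects on liability (they default to covariate-only). Passing tests
therefore demonstrate correctness of the *pipeline machinery* and the
qualitative orderings, not transferability of any absolute AUC to real
cohorts; in-sample AUCs on small simulated panels run higher than published
cohort values.

## QC

Variant filters run in the fixed attribution order INFO < 0.7, MAF < 0.05,
missingness > 5%, HWE p ≤ 10⁻⁶, each variant charged to the first failing
filter so reports are deterministic. The HWE test is the exact conditional
test (sum of probabilities, over heterozygote counts of the observed parity,
not exceeding the observed table's). Hard-calling for HWE/kinship rounds
dosages to the nearest integer, leaving dosages in (0.4, 0.6) ∪ (1.4, 1.6)
missing as an uncertainty guard. Relatedness uses the KING-robust kinship
`(N_het,het − 2N_opp-hom)/(N_het(i)+N_het(j))` with greedy pruning (drop the
member with more over-threshold partners; ties by missingness then later
sample order); a pi-hat style threshold t maps to kinship t/2. PCA
standardizes at 2p̂, √(2p̂q̂), mean-imputes missing dosages, skips
monomorphic sites, and fixes each PC's sign by its largest-magnitude loading;
the pipeline excludes the APOE region from PCA (standard long-range-LD
exclusion), since on a small panel a single dense block can otherwise
masquerade as structure and absorb the locus signal.

## PRS engine

Harmonization matches on (chrom, pos): effect allele = alt keeps β, = ref
flips the sign, anything else is dropped; A/T and C/G strand-ambiguous pairs
are dropped when requested; all counts logged. Clumping is the standard
greedy rule — smallest p first (ties: smaller SE, then lower position),
removing unassigned same-chromosome variants within ±window whose r² with
the index exceeds `r2_max` (strict >; the pT comparison is inclusive ≤). LD
is computed in-sample on the target cohort, with mean imputation of missing
dosages in the vectorized path (identical to pairwise-complete when nothing
is missing). Scores mean-impute missing dosages per variant. Externally
derived weight files (e.g. shrinkage-posterior effects) are ingested through
the same harmonization and scored without thresholding; re-implementing
those posterior samplers is out of scope by design.

## Risk models and evaluation

Predictors (PRS and ε counts alike) are OLS-residualized on
[1, age, sex, PCs] and z-scored (ddof = 1) before the logistic fit —
adjustment-then-standardization rather than covariates in the logistic
model. Fits are maximum likelihood (statsmodels) with Wald per-coefficient
p-values; perfect separation is reported as a distinct error. AUC is the
Mann-Whitney rank statistic with midranks, computed on the fitted linear
predictor (for single-predictor models this equals the predictor's own AUC);
in-sample, with no optimism correction, matching the benchmarked design. The
optimal pT is chosen by the M5 AUC, ties to the smaller threshold. The
ε3ε3 subgroup refits adjustment within the subgroup. The microglia scope
runs M2–M5 (M1 does not depend on the SNP set), consistent with the
4-model microglia stratum in the 80-test accounting.

## Consistency

Quintiles are assigned by ascending rank (stable ID tie-break); the sample of
0-based rank r joins group `floor(5r/N)+1`, and the nominal group size N/5 is
reported with banker's rounding (giving 114 at N=568 and 153 at N=766). Tail
overlap is `100·|tail_a ∩ tail_b|/|tail_a|` — the first assignment's tail is
the denominator, symmetric whenever sizes match. The composite score for
model-level comparisons is the fitted M5 linear predictor.

## Numerical and design notes

- All randomness flows from one seed through named `SeedSequence` child
  streams (panel, cohort, LD reference, effects, phenotype, GWAS A/B,
  annotation); identical configs are bit-identical end to end, and the
  pipeline derives per-stage seeds below 2³¹ from the global seed by SHA-256.
- Chromosome labels are normalized (no `chr` prefix, `M` → `MT`); all
  internal coordinates are 1-based inclusive, converting only at the BED
  boundary (0-based half-open).
- Defaults `K = 0.05` and `h² = 0.2` are configuration, not estimates: the
  benchmark's source design does not state the values it would imply.
- Default cohort sizes (223 cases / 345 controls) and discovery sizes mirror
  the clinical-cohort scale the benchmark emulates; test and acceptance runs
  use panels of 300–1000 polygenic variants so suites complete in seconds on
  one CPU — panel size changes LD granularity, not the logic under test.
- The `prsbench` CLI (`simulate`, `qc`, `score`, `model`, `consistency`,
  `run`, `validate`) is a thin wrapper; the library functions are the
  primary interface.

## Known limitations

In-sample AUC on small panels is optimistic; clumping on in-sample LD of a
few hundred samples is noisy below r² ≈ 0.05; the e1 APOE haplotype is not
modelled (double heterozygotes are flagged ambiguous, not phased); the
kinship matrix is O(n²·m) pure-Python/numpy and intended for cohort-scale
(thousands), not biobank-scale, inputs.
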