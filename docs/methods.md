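# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the `ssgblup` package.

## Scope and models

The package implements a complete genetic-evaluation workflow for a
multi-trait livestock population: fixed-effect screening, relationship
matrices, REML variance components, and breeding-value estimation with
reliability comparison between pedigree-based BLUP (PBLUP) and single-step
genomic BLUP (ssGBLUP).

### Single-trait animal models

For a trait y the linear mixed models are

    y = Xb + Z1 a + e                    (plain)
    y = Xb + Z1 a + Z2 pe + e            (repeated records)
    y = Xb + Z1 a + Z3 m + e             (newborn growth, maternal)

with a ~ N(0, K σ²a), pe ~ N(0, I σ²pe), m ~ N(0, K σ²m),
e ~ N(0, I σ²e), and K the pedigree relationship matrix A (PBLUP) or the
single-step matrix H (ssGBLUP). The direct–maternal genetic covariance is
fixed at zero: the maternal model used here declares no such term, and
estimating it demands far deeper dam pedigrees than the four-generation
populations this package targets. Heritability is h² = σ²a/σ²p with
σ²p the sum of all estimated components — also for pe/maternal models,
where a "σ²a + σ²e" shortcut would overstate h². Its standard error is the
delta-method expression
h⁴ [Var(σ²a)/σ⁴a + Var(σ²p)/σ⁴p − 2 Cov(σ²a, σ²p)/(σ²a σ²p)], with
Var(σ²p) and Cov(σ²a, σ²p) obtained from the component covariance matrix
by the linear map σ²p = Σθᵢ.

### Relationship matrices

* **A** by the tabular method (a_ii = 1 + a_sd/2, a_ij = (a_js + a_jd)/2),
  vectorized row-by-row; subsets (A11, A12, A22) by index extraction.
* **F** (inbreeding) by the Meuwissen–Luo ancestor-tracing recursion over
  the L-rows of A = LDL′, so A itself is never formed for F.
* **A⁻¹** assembled sparsely from Mendelian-sampling variances
  d_i = 0.5 − 0.25(F_s + F_d) (0.75 − 0.25F with one known parent, 1 with
  none) and Henderson's {animal, sire, dam} contribution rules. Unknown
  parents are base-population animals; no unknown-parent groups.
* **G** = WW′ / (2 Σ p_k(1 − p_k)) with W the 0/1/2 codes centered by 2p_j.
  Centering uses the counted allele's frequency; with observed-frequency
  centering the ones vector lies in G's null space, which is one of the
  reasons G is blended before inversion. Frequency policy is a parameter
  (observed in the genotyped set | supplied | 0.5); observed is the
  default since base-population frequencies are unobservable.
* **G\*** = wG + (1 − w)A22 with default w = 0.95 and optional two-parameter
  rescaling of G to match A22's mean diagonal and off-diagonal first. The
  blend is the minimal standard repair for G's rank deficiency; G\* must
  be positive definite or construction fails loudly.
* **H** in block form (non-genotyped block A11 + A12A22⁻¹(G\* − A22)A22⁻¹A21,
  off-diagonal A12A22⁻¹G\*, genotyped block G\*) and
  **H⁻¹ = A⁻¹ + [0 0; 0 G\*⁻¹ − A22⁻¹]** scattered onto the genotyped
  rows/columns of the sparse A⁻¹. The two constructions are verified
  against each other (H·H⁻¹ = I) in the tests.

### Genotype quality control

Four filters in a fixed order, each applied to the survivors of the
previous step: individual call rate ≥ 0.90, SNP call rate ≥ 0.90,
Hardy–Weinberg equilibrium p ≥ 1e-6 (1-df Pearson chi-square on the three
genotype counts; monomorphic SNPs carry no HWE evidence), minor allele
frequency ≥ 0.05. Missing codes surviving QC are imputed to the SNP mean
2p_j so the G formula applies to a complete matrix.

### REML

Two estimation paths, dispatched automatically:

* **Spectral path** (additive + residual only): ZKZ′ is eigendecomposed
  once and the restricted likelihood is profiled to the single ratio
  λ = σ²a/σ²e, maximized by bounded scalar search on log λ ∈ [−14, 10].
  Component covariances come from the exact expected (Fisher) information,
  evaluated in the eigenbasis at O(np²) cost. The eigendecomposition can
  be precomputed (`additive_structure`) and reused across replicated fits
  on one pedigree.
* **Average-information path** (pe and/or maternal terms): dense V-matrix
  AI-REML. Newton steps on the AI matrix; whenever a proposal leaves the
  parameter space (or AI is singular) the iteration falls back to an
  EM-REML step σ²ᵢ ← σ²ᵢ + σ⁴ᵢ(y′PVᵢPy − tr(PVᵢ))/qᵢ, which cannot leave
  the space; step-halving guards against likelihood decreases. Components
  are pinned (and flagged) at a floor of 1e-8·Var(y). Convergence: max
  relative component change < 1e-8 or score norm < 1e-6, 200 iterations.
  Starting values: half of Var(y) to the residual, the rest split equally.
* **Two-trait model** (additive + residual per trait, shared relationship
  structure): direct maximization of the restricted likelihood over
  log-Cholesky-parametrized G₀ and R₀ (Nelder–Mead polish + BFGS). When
  both traits are single-record on a common animal set the likelihood is
  evaluated spectrally in O(n) per evaluation; otherwise a dense stacked
  likelihood is used, with residual covariance only between records of the
  same animal. Repeated records are reduced to the first record — the
  two-trait model carries no permanent-environmental term. Asymptotic
  covariances of (g11, g12, g22, r11, r12, r22) come from the numerically
  differentiated observed information; rA and rP are the usual ratios with
  phenotypic covariance = genetic + residual covariance.

Fixed effects enter as full-rank treatment-coded designs (first observed
level as reference) in the MME; screening F-tests use sum-to-zero
constraints with marginal (drop-one, Type-III-style) tests, because the
data are unbalanced and one F per factor is wanted. Aliased factors are
reported as such, never silently dropped. The lactation-stage factor is
binned half-open: [0, 100], [101, 200], [201, ∞) days.

### Evaluation and reliability

Henderson's MME are held in variance-ratio form
(C = W′W + blockdiag(0, λ_a K⁻¹, λ_pe I, λ_m K⁻¹), right side W′y) and
solved sparsely; every animal in K⁻¹ receives an equation, so recordless
animals get pedigree/genomic predictions. PEV is the additive-block
diagonal of C⁻¹σ²e: via a dense Cholesky inverse below a configurable cap
(default 8,000 equations) and per-column sparse solves above it.
Model reliability is R² = 1 − PEV/σ²a, clamped to [0, 1); an optional
(1 + F_i)σ²a denominator is available but off by default, matching the
common field convention. Validation reliability is Cor²(EBV, true a)
(truth mode) or Cor²(EBV, y adjusted by the training fit's fixed effects)
divided by h² (phenotype mode). With repeated records the phenotype-mode
normalizer refers to a single record, so values computed on record means
overstate reliability; truth mode is preferred on simulated data.
Forward validation masks the youngest generation's records, mirroring the
early-selection use case. Comparison tables report, per population subset
(whole / genotyped / genotyped plus relatives), mean reliabilities, Δrel
in percentage points (means, not medians), and the Pearson correlation of
EBV vs GEBV, plus reliability deciles. "Relatives" are animals with a
nonzero additive relationship to a genotyped animal, found via
founder-ancestor set intersection (two animals are related exactly when
they share a common founder ancestor).

## Synthetic herd generator

The generator emulates the study system — a two-herd dual-purpose cattle
population with repeated lactation/reproduction records, newborn growth
records with maternal effects, and a genotyped subset — at a scale where
every stage runs in seconds.

* **Pedigree**: hierarchical random mating without selection. Each
  generation uses as many sires as the dam pool allows (default 2–4 dams
  per sire, 2 offspring per dam), guaranteeing the paternal half-sib
  structure REML identification relies on; offspring sexes alternate
  within litter. Founder cohorts default to a few hundred animals over
  four generations.
* **Genotypes**: unlinked biallelic SNPs by gene dropping. Founder allele
  frequencies are uniform on (0.05, 0.5]; each offspring allele is a fair
  draw from the parent's two alleles; no mutation, no genotyping error.
  The genotyped subset is a seeded uniform sample of
  round(genotyping_fraction × n) animals.
* **Breeding values**: QTL-plus-polygenic by default — 50 panel SNPs (a
  configurable number and variance fraction, default one half) receive
  normal effects scaled to the founder-population variance, the remainder
  follows the pedigree through the Mendelian-sampling recursion
  a_i = (a_s + a_d)/2 + N(0, d_i σ²), so genomic relationships carry real
  signal for ssGBLUP while the A-model stays well-posed. A pure-polygenic
  mode (no genotypes, or zero QTL) makes the fitted A-model exactly the
  generative model and is used for the REML recovery experiments.
  Correlated trait pairs draw QTL effects and Mendelian deviates jointly
  at the declared rA.
* **Phenotypes**: trait means plus declared constant factor effects (the
  level sets mirror the herd/parity/year/season/lactation,
  service-related, and birth-year/month/sex factor structures of the
  three study trait groups), one permanent-environmental draw per animal
  shared across records, the dam's maternal genetic effect where
  declared, and i.i.d. residuals. σ²e = residual_sd²; σ²p follows from
  1 − repeatability − maternal h², so h², repeatability and maternal h²
  are exact population parameters. Maternal traits are recorded only for
  animals with a known dam (a phantom-dam effect would sit outside the
  fitted model). True breeding values are stored with every record.

What the generator does **not** emulate: linkage and LD structure,
selection and non-random mating, genotyping error and imputation,
heterogeneous residual variances, and herd-year contemporary-group
confounding with genetics. Passing tests therefore demonstrate correctness
of the estimators under their own assumptions and the qualitative behavior
of ssGBLUP vs PBLUP, not performance on any real cattle population —
evaluation datasets of this kind are proprietary to the farms that collect
them, which is exactly why the generator exists.

## Study-scale experiments

The replicated experiments (`ssgblup.experiments`) fix one hierarchical
population per experiment and redraw genetics and records per replicate
seed:

* **Heritability recovery**: n = 3,000 animals (600 founders, four
  generations), true h² = 0.30, single records, pure polygenic, 20
  replicates. The additive eigenstructure is computed once and shared.
  Reported: per-replicate ĥ² and SE; the 2-SE coverage of the truth.
  The zero-heritability boundary uses n = 2,000 pure-noise records.
* **Genetic-correlation recovery**: same population scale, trait pair
  with h² 0.35/0.40 and rA 0.5 (and an rA = 0 null), 10 replicates.
* **Method comparison**: 10 fresh populations of n = 2,000 (three
  generations), 30% genotyped on a 600-SNP panel, QTL-driven trait
  (100 QTL, 80% of additive variance) with h² = 0.30; youngest
  generation's records masked; both systems solved at the generative
  variance ratios. Population size was chosen so that the genotyped
  validation set (~150 animals) gives per-replicate truth-mode r²
  estimates precise enough to resolve the expected ssGBLUP advantage;
  at a few hundred animals the advantage is still positive in the mean
  but single replicates are sampling-noise dominated.

## Numerical choices and degenerate inputs

* Ratio-form MME with a floor: components estimated at the zero boundary
  enter downstream systems at 1e-6·σ²p so ratios stay finite; the
  estimate itself is reported (and flagged) as pinned.
* The bivariate log-Cholesky parameters are clamped at ±15 so perfectly
  correlated traits saturate near |r| = 1 instead of overflowing.
* Cyclic pedigrees, duplicate ids, records for unknown animals, factors
  with one observed level, monomorphic panels, and singular blended G\*
  all raise typed errors with diagnostics.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration and seed reproduce
  byte-identical simulation output and pipeline tables.

## Known limitations

* Dense A, G, H and the dense REML paths target populations up to a few
  thousand animals — the package's study scale; industrial-scale
  (100K+ animal) evaluations would need APY-type approximations, which
  are deliberately out of scope, as are metafounders, weighted
  single-step, random-regression/test-day models, Gibbs-sampling
  estimation, and joint models beyond two traits.
* The bivariate model ignores permanent-environmental covariance between
  repeated records (first record used), so genetic correlations for
  repeated-record traits are estimated with less information than a full
  multi-trait repeatability model would use.
* Phenotype-mode validation reliability depends on an h² supplied by the
  caller and on the single-record interpretation of the normalizer (the
  conventional reading of an otherwise underdetermined formula); both
  modes are exposed and truth mode is the default on simulated data.
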