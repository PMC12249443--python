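# ssgblup

Pedigree and single-step genomic evaluation for livestock populations:
relationship matrices (A, A⁻¹, G, G*, H, H⁻¹), REML variance components
and heritabilities for animal models with permanent-environmental and
maternal effects, genetic/phenotypic correlations from two-trait models,
and EBV/GEBV reliability comparison between pedigree BLUP (PBLUP) and
single-step genomic BLUP (ssGBLUP). A synthetic herd generator — a
two-herd cattle population with repeated lactation and reproduction
records, newborn growth records with maternal effects, and a genotyped
subset — stands in for proprietary farm data, so the whole analysis is
reproducible from a seed.

The package is aimed at quantitative geneticists and breeding-program
analysts who want a transparent, tested reference implementation of the
standard evaluation stack rather than an industrial-scale engine.

## The models

Single-trait animal models per trait group:

    milk:        y = Xb + Z1 a + Z2 pe + e
    reproduction: y = Xb + Z1 a (+ Z2 pe) + e
    growth:      y = Xb + Z1 a (+ Z3 m) + e

with a ~ N(0, Kσ²a) for K = A (pedigree) or K = H (single-step),
pe ~ N(0, Iσ²pe), m ~ N(0, Kσ²m). The genomic relationship matrix is
G = WW′/2Σp_k(1−p_k) with W the 0/1/2 SNP codes centered by 2p_j, blended
as G* = 0.95·G + 0.05·A22 for invertibility, and combined with the
pedigree through

    H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹].

Variance components are estimated by REML (profiled spectral likelihood
for plain models, average-information iteration with EM fallback for
pe/maternal models); h² = σ²a/σ²p with a delta-method SE. Per-animal
reliability is R² = 1 − PEV/σ²a from the inverse of Henderson's
mixed-model equations, and Δrel is the difference in mean reliability
between ssGBLUP and PBLUP in percentage points. See `docs/methods.md`
for the full account.

## Worked example

```python
from ssgblup import RunConfig, SimulationConfig, run_pipeline
from ssgblup.simulate import default_traits

cfg = RunConfig(
    outdir="run",
    seed=20250101,
    simulation=SimulationConfig(n_founders=150, n_generations=3,
                                dams_per_sire=3, offspring_per_dam=2,
                                n_snps=1000, genotyping_fraction=0.3,
                                seed=20250101),
    traits=default_traits(),
)
run_pipeline(cfg)
```

This simulates 600 animals over four cohorts (180 genotyped on a
1,000-SNP panel; 19 SNPs fall to the MAF < 0.05 filter), screens the
candidate fixed factors per trait, estimates variance components under
both A and H, and writes every table into `run/`. The same analysis is
available as numbered drivers (`analysis/01_simulate_herd.py` …
`analysis/08_recovery_experiments.py`). Heritabilities from
`variance_components.tsv` at this scale (generative values 0.25, 0.08,
0.30, 0.35, 0.40):

```
           trait  method    h2  h2_se
      milk_yield   PBLUP 0.194  0.044
calving_interval   PBLUP 0.024  0.030
    birth_weight   PBLUP 0.316  0.093
      weight_6mo   PBLUP 0.335  0.074
      height_6mo   PBLUP 0.328  0.074
```

and the reliability comparison for the maternal growth trait
(`comparison_birth_weight.tsv`):

```
                 subset   n  mean_rel_pblup  mean_rel_ssgblup  delta_rel_pct  corr_ebv_gebv
                  whole 600          0.2712            0.2987         2.7529         0.9903
              genotyped 180          0.2760            0.3172         4.1194         0.9770
genotyped_and_relatives 561          0.2894            0.3188         2.9407         0.9903
```

The gain from genomic information concentrates on the genotyped subset
(+4.1 percentage points of reliability here), while EBV and GEBV stay
highly correlated — the qualitative pattern genomic evaluations are
expected to show.

## Layout

    src/ssgblup/        library: simulate, genotypes, pedigree,
                        relationship, screening, mme, reml, evaluate,
                        experiments, pipeline, cli
    analysis/           numbered narrative drivers over the library
    tests/              pytest suite (unit, property, and study-scale)
    scripts/acceptance.py
    docs/methods.md     models, generator, numerics, limitations

A thin command-line interface mirrors the pipeline stages
(`ssgblup simulate|qc|relmat|screen|run-all …`).
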