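"""Replicated simulation experiments over the synthetic herd.

These functions define the package's standard study conditions: a fixed
hierarchical population structure with phenotypes (and QTL effects)
redrawn across replicate seeds, REML parameter recovery for heritability
and genetic correlation, and the PBLUP-vs-ssGBLUP reliability comparison
with forward validation. They back both the analysis drivers and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import solve_blup, validation_reliability
from .genotypes import qc_filter_genotypes
from .mme import assemble_mme
from .relationship import blend_and_tune_G, build_genomic_matrix, build_H_inverse
from .reml import (additive_structure, bivariate_reml, correlations,
                   heritability, reml_estimate)
from .screening import TraitModelSpec
from .simulate import (SimulationConfig, SyntheticTraitDefinition,
                       genotyped_subset, simulate_genotypes,
                       simulate_pedigree, simulate_phenotypes)


def population_config(n_animals: int, seed: int, *, dams_per_sire: int = 2,
                      offspring_per_dam: int = 2, n_snps: int = 500,
                      genotyping_fraction: float = 0.3, **kw) -> SimulationConfig:
    """Hierarchical-design config sized to ~n_animals total.

    With a balanced design each generation reproduces the founder cohort
    size, so founders = n_animals / (1 + n_generations).
    """
    gens = kw.pop("n_generations", 4)
    founders = int(round(n_animals / (1 + gens)))
    founders += founders % 2
    return SimulationConfig(
        n_founders=founders, n_generations=gens, dams_per_sire=dams_per_sire,
        offspring_per_dam=offspring_per_dam, n_snps=n_snps,
        genotyping_fraction=genotyping_fraction, seed=seed, **kw)


def h2_recovery_experiment(
    n_seeds: int = 20,
    seed: int = 1,
    n_animals: int = 3000,
    h2_true: float = 0.30,
) -> pd.DataFrame:
    """REML heritability recovery across phenotype replicates.

    One pedigree defines the population structure; polygenic breeding
    values and records are redrawn for each replicate seed, so the fitted
    A-model is exactly the generative model. Returns one row per
    replicate: ĥ², its SE, and the estimated components.
    """
    cfg = population_config(n_animals, seed)
    ped = simulate_pedigree(cfg)
    A = ped.relationship_matrix()
    structure = additive_structure(A, list(ped.ids))
    trait = SyntheticTraitDefinition("t", mean=0.0, h2_true=h2_true, residual_sd=1.0)
    spec = TraitModelSpec("t")
    rows = []
    for k in range(n_seeds):
        # pure polygenic draws: the fitted A-model is the generative model
        ph = simulate_phenotypes(ped, None, [trait], seed=seed + 1000 * (k + 1),
                                 config=cfg)
        vc = reml_estimate(spec, ph, A, structure=structure)
        h2, se = heritability(vc)
        rows.append((k, h2, se, vc.sigma2_a, vc.sigma2_e, vc.converged))
    return pd.DataFrame(rows, columns=["replicate", "h2", "se", "sigma2_a",
                                       "sigma2_e", "converged"])


def bivariate_recovery_experiment(
    n_seeds: int = 10,
    seed: int = 1,
    n_animals: int = 3000,
    ra_true: float = 0.5,
) -> pd.DataFrame:
    """Genetic-correlation recovery across phenotype replicates."""
    cfg = population_config(n_animals, seed)
    ped = simulate_pedigree(cfg)
    A = ped.relationship_matrix()
    structure = additive_structure(A, list(ped.ids))
    t1 = SyntheticTraitDefinition("x", 0.0, 0.35, 1.0,
                                  genetic_correlation_partner=("z", ra_true))
    t2 = SyntheticTraitDefinition("z", 0.0, 0.40, 1.0)
    rows = []
    for k in range(n_seeds):
        ph = simulate_phenotypes(ped, None, [t1, t2], seed=seed + 1000 * (k + 1),
                                 config=cfg)
        bc = bivariate_reml(TraitModelSpec("x"), TraitModelSpec("z"), ph, A,
                            structure=structure)
        ra, rp = correlations(bc)
        rows.append((k, ra, rp, bc.converged))
    return pd.DataFrame(rows, columns=["replicate", "r_genetic", "r_phenotypic",
                                       "converged"])


def method_comparison_experiment(
    n_reps: int = 10,
    seed: int = 1,
    n_animals: int = 2000,
    h2_true: float = 0.30,
    genotyping_fraction: float = 0.3,
    n_snps: int = 600,
) -> pd.DataFrame:
    """PBLUP vs ssGBLUP reliability on the genotyped subset.

    Per replicate: a fresh population with QTL-driven breeding values and
    ~30% genotyped animals; the youngest generation's records are masked
    (forward validation); both systems are solved at the generative
    variance ratios. Reported per replicate: mean model reliability over
    the genotyped subset and truth-mode validation reliability over the
    genotyped validation animals.
    """
    rows = []
    trait = SyntheticTraitDefinition("t", mean=0.0, h2_true=h2_true, residual_sd=1.0)
    spec = TraitModelSpec("t")
    for rep in range(n_reps):
        cfg = population_config(
            n_animals, seed + 7919 * rep, n_generations=3, dams_per_sire=3,
            n_snps=n_snps, genotyping_fraction=genotyping_fraction,
            n_qtl=100, qtl_variance_fraction=0.8)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        ph = simulate_phenotypes(ped, geno, [trait], config=cfg)
        gids = genotyped_subset(ped, cfg)
        gpos = {a: i for i, a in enumerate(geno.ids)}
        gsub, _ = qc_filter_genotypes(geno.subset(animal_idx=[gpos[g] for g in gids]))
        gids = list(gsub.ids)
        A22 = ped.relationship_matrix(subset=gids)
        A22.kind = "A22"
        Gs = blend_and_tune_G(build_genomic_matrix(gsub), A22, 0.95)
        ainv = ped.a_inverse()
        hinv = build_H_inverse(ainv, Gs, A22, gids)
        young = ped.generation == ped.generation.max()
        vids = {ped.ids[i] for i in np.flatnonzero(young)}
        train = ph[~ph["animal"].isin(vids)]
        truth = ph.drop_duplicates("animal")[["animal", "tbv"]]
        lam = {"additive": trait.sigma2_e / trait.sigma2_a}
        out = {}
        for method, kinv in (("PBLUP", ainv), ("ssGBLUP", hinv)):
            res = solve_blup(assemble_mme(spec, train, kinv, lam),
                             trait.sigma2_a, trait.sigma2_e, method=method)
            out[method] = res
        gv = sorted(vids & set(gids))
        rows.append((
            rep,
            float(np.mean(out["PBLUP"].reliability_of(gids))),
            float(np.mean(out["ssGBLUP"].reliability_of(gids))),
            validation_reliability(out["PBLUP"], truth, mode="truth", ids=gv),
            validation_reliability(out["ssGBLUP"], truth, mode="truth", ids=gv),
            float(np.corrcoef(out["PBLUP"].ebv_of(gids),
                              out["ssGBLUP"].ebv_of(gids))[0, 1]),
        ))
    return pd.DataFrame(rows, columns=[
        "replicate", "mean_rel_pblup", "mean_rel_ssgblup",
        "r2_truth_pblup", "r2_truth_ssgblup", "corr_ebv_gebv"])
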