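"""Synthetic herd generator: pedigree, gene-dropped SNP genotypes, and
multi-trait phenotypes.

The generator emulates a two-herd dual-purpose cattle population with a
hierarchical (sires × dams) mating design, biallelic SNPs transmitted by
gene dropping, and phenotypes built from declared fixed-factor effects plus
additive-genetic, permanent-environmental, maternal-genetic, and residual
draws. Breeding values are QTL-plus-polygenic by default: a subset of panel
SNPs receives sampled effects (so genomic relationships are genuinely
informative) and the remainder of the additive variance follows the
pedigree through Mendelian-sampling recursion.

All randomness is controlled by ``SimulationConfig.seed``; identical
configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Population and panel design for the synthetic herd.

    The default scale is a reduced image of a commercial two-farm
    population: a few thousand pedigree animals over four generations with
    a genotyped subset, and an SNP panel small enough to be simulated in
    seconds while leaving the genomic machinery fully exercised.
    """

    n_founders: int = 200
    n_generations: int = 4
    dams_per_sire: int = 4
    offspring_per_dam: int = 2
    n_snps: int = 1000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_fraction: float = 0.3
    seed: int = 20250101
    n_qtl: int = 50
    qtl_variance_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "dams_per_sire", "offspring_per_dam", "n_snps"):
            if getattr(self, name) < (0 if name == "n_generations" else 1):
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("founder_maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.genotyping_fraction <= 1:
            raise ConfigurationError("genotyping_fraction must lie in [0, 1]")
        if not 0 <= self.qtl_variance_fraction <= 1:
            raise ConfigurationError("qtl_variance_fraction must lie in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-scoped generator; stages are decoupled so adding SNPs does
        not perturb the pedigree, etc."""
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class SyntheticTraitDefinition:
    """Generative definition of one trait.

    σ²e = residual_sd²; the implied phenotypic variance is
    σ²p = σ²e / (1 − repeatability − maternal_h²) with repeatability
    defaulting to h² when absent, so that h², repeatability and maternal h²
    are exact population parameters of the generative model.
    """

    trait_name: str
    mean: float
    h2_true: float
    residual_sd: float
    repeatability: Optional[float] = None
    maternal_h2: Optional[float] = None
    fixed_factors: dict[str, dict[str, float]] = field(default_factory=dict)
    records_per_animal: int = 1
    genetic_correlation_partner: Optional[tuple[str, float]] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.h2_true <= 1:
            raise ConfigurationError("h2_true must lie in [0, 1]")
        if self.repeatability is not None and self.repeatability < self.h2_true:
            raise ConfigurationError("repeatability must be >= h2_true")
        if self.maternal_h2 is not None and not 0 <= self.maternal_h2 < 1:
            raise ConfigurationError("maternal_h2 must lie in [0, 1)")
        if self.genetic_correlation_partner is not None:
            _, ra = self.genetic_correlation_partner
            if not -1 <= ra <= 1:
                raise ConfigurationError("|rA| must be <= 1")
        if self.records_per_animal < 1:
            raise ConfigurationError("records_per_animal must be >= 1")
        tot = self.h2_true if self.repeatability is None else self.repeatability
        tot += self.maternal_h2 or 0.0
        if tot >= 1:
            raise ConfigurationError("h2 + pe + maternal fractions must sum to < 1")

    # -- derived generative variances ----------------------------------
    @property
    def sigma2_e(self) -> float:
        return self.residual_sd**2

    @property
    def sigma2_p(self) -> float:
        rep = self.h2_true if self.repeatability is None else self.repeatability
        return self.sigma2_e / (1.0 - rep - (self.maternal_h2 or 0.0))

    @property
    def sigma2_a(self) -> float:
        return self.h2_true * self.sigma2_p

    @property
    def sigma2_pe(self) -> float:
        if self.repeatability is None:
            return 0.0
        return (self.repeatability - self.h2_true) * self.sigma2_p

    @property
    def sigma2_m(self) -> float:
        return (self.maternal_h2 or 0.0) * self.sigma2_p


# ----------------------------------------------------------------------
def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Hierarchical random-mating pedigree (no selection).

    Founders are half male, half female. Each generation draws as many
    sires as the available dams allow (dams_per_sire dams each, every dam
    producing offspring_per_dam offspring), so half/full-sib family
    structure is guaranteed. Offspring sexes alternate within litter.
    """
    if config.n_founders < 1:
        raise ConfigurationError("need at least one founder")
    rng = config.rng(stage=0)
    ids = [f"A{k+1:06d}" for k in range(config.n_founders)]
    sire = [-1] * config.n_founders
    dam = [-1] * config.n_founders
    gen = [0] * config.n_founders
    sex = ["M" if k % 2 == 0 else "F" for k in range(config.n_founders)]
    prev = list(range(config.n_founders))
    counter = config.n_founders
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        n_sires = min(len(males), len(females) // config.dams_per_sire)
        if n_sires == 0:
            break
        sires = list(rng.choice(males, size=n_sires, replace=False))
        dams = list(rng.choice(females, size=n_sires * config.dams_per_sire, replace=False))
        cur = []
        for si, s in enumerate(sires):
            for d in dams[si * config.dams_per_sire : (si + 1) * config.dams_per_sire]:
                for off in range(config.offspring_per_dam):
                    ids.append(f"A{counter+1:06d}")
                    sire.append(s)
                    dam.append(d)
                    gen.append(g)
                    sex.append("M" if off % 2 == 0 else "F")
                    cur.append(counter)
                    counter += 1
        prev = cur
    ped = Pedigree(ids, np.array(sire), np.array(dam), np.array(gen))
    ped.sex = np.array(sex)
    return ped


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Gene-dropped SNP genotypes for every pedigree animal.

    Founder allele frequencies are uniform on ``founder_maf_range``;
    founder haplotypes are Bernoulli draws and each offspring allele is a
    fair draw from the parent's two alleles (unlinked SNPs, no mutation).
    """
    if config.n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    rng = config.rng(stage=1)
    n, m = len(pedigree), config.n_snps
    p = rng.uniform(*config.founder_maf_range, size=m)
    hap = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        for h, par in enumerate((s, d)):
            if par < 0:
                hap[i, h] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, h] = hap[par, pick, np.arange(m)]
    codes = hap.sum(axis=1).astype(np.int8)
    snps = [f"snp{j+1:05d}" for j in range(m)]
    return GenotypeMatrix(list(pedigree.ids), snps, codes)


def genotyped_subset(pedigree: Pedigree, config: SimulationConfig) -> list[str]:
    """Reproducible genotyped subset of size round(fraction × n animals)."""
    n = len(pedigree)
    k = int(round(config.genotyping_fraction * n))
    if k == 0:
        return []
    rng = config.rng(stage=2)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return [pedigree.ids[i] for i in idx]


# ----------------------------------------------------------------------
def _polygenic_values(
    pedigree: Pedigree, cov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Breeding values a ~ N(0, A ⊗ cov) by gene-flow recursion.

    cov is the k×k base-population (co)variance of the k (possibly
    correlated) traits. Mendelian deviates are scaled by the per-animal
    within-family variance d_i (accounting for parental inbreeding).
    """
    k = cov.shape[0]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(k)) if np.any(cov) else np.zeros((k, k))
    d = pedigree.mendelian_variance()
    z = rng.standard_normal((len(pedigree), k))
    a = np.zeros((len(pedigree), k))
    for i in range(len(pedigree)):
        mid = np.zeros(k)
        if pedigree.sire[i] >= 0:
            mid += 0.5 * a[pedigree.sire[i]]
        if pedigree.dam[i] >= 0:
            mid += 0.5 * a[pedigree.dam[i]]
        a[i] = mid + np.sqrt(d[i]) * (L @ z[i])
    return a


def _qtl_values(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    cov: np.ndarray,
    n_qtl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """QTL component of breeding values with base (founder) variance ≈ cov.

    Effects for the k traits are drawn jointly with correlation structure
    from cov, then scaled so the founder-population variance of each
    trait's QTL sum matches the requested variance.
    """
    k = cov.shape[0]
    n_qtl = min(n_qtl, genotypes.n_snps)
    if n_qtl == 0 or not np.any(cov):
        return np.zeros((len(pedigree), k))
    qtl = np.sort(rng.choice(genotypes.n_snps, size=n_qtl, replace=False))
    founders = np.flatnonzero(pedigree.is_founder)
    codes = np.asarray(genotypes.codes, dtype=float)[:, qtl]
    pf = codes[founders].mean(axis=0) / 2.0
    W = codes - 2.0 * pf
    het = 2.0 * np.sum(pf * (1 - pf))
    if het <= 0:
        return np.zeros((len(pedigree), k))
    corr = np.zeros((k, k))
    sd = np.sqrt(np.diag(cov))
    nz = sd > 0
    corr[np.ix_(nz, nz)] = cov[np.ix_(nz, nz)] / np.outer(sd[nz], sd[nz])
    np.fill_diagonal(corr, np.where(nz, 1.0, 0.0))
    Lc = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    beta = rng.standard_normal((n_qtl, k)) @ Lc.T  # unit-variance, rA-correlated
    beta *= sd / np.sqrt(het)  # founder var of W @ beta ≈ cov diagonal
    return W @ beta


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix | None,
    traits: list[SyntheticTraitDefinition],
    seed: int | None = None,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Long-format phenotype table with stored truth.

    Columns: animal, trait, record, value, tbv (true breeding value),
    tbv_maternal (maternal traits), plus one column per fixed factor.
    Repeated records share one permanent-environmental draw per animal;
    maternal traits add the dam's maternal genetic effect (and are recorded
    only for animals with a known dam). QTL-plus-polygenic architecture is
    taken from ``config`` (pure polygenic when genotypes is None or
    n_qtl = 0).
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng([int(seed if seed is not None else cfg.seed) % (2**31), 3])
    if genotypes is not None and list(genotypes.ids) != list(pedigree.ids):
        raise ValueError("genotype matrix must cover the pedigree animals in pedigree order")

    # group correlated pairs so their breeding values are drawn jointly
    by_name = {t.trait_name: t for t in traits}
    groups: list[list[SyntheticTraitDefinition]] = []
    used: set[str] = set()
    for t in traits:
        if t.trait_name in used:
            continue
        if t.genetic_correlation_partner is not None:
            pname, _ = t.genetic_correlation_partner
            if pname not in by_name:
                raise ConfigurationError(f"correlation partner {pname!r} not among traits")
            groups.append([t, by_name[pname]])
            used |= {t.trait_name, pname}
        else:
            groups.append([t])
            used.add(t.trait_name)

    n = len(pedigree)
    frames = []
    for grp in groups:
        k = len(grp)
        sa = np.array([t.sigma2_a for t in grp])
        cov = np.diag(sa)
        if k == 2:
            ra = grp[0].genetic_correlation_partner[1]
            cov[0, 1] = cov[1, 0] = ra * np.sqrt(sa[0] * sa[1])
        qfrac = cfg.qtl_variance_fraction if genotypes is not None and cfg.n_qtl > 0 else 0.0
        a = _qtl_values(pedigree, genotypes, qfrac * cov, cfg.n_qtl, rng) if qfrac > 0 else np.zeros((n, k))
        a += _polygenic_values(pedigree, (1.0 - qfrac) * cov, rng)
        for col, t in enumerate(grp):
            tbv = a[:, col]
            pe = rng.normal(0.0, np.sqrt(t.sigma2_pe), size=n) if t.sigma2_pe > 0 else np.zeros(n)
            has_m = t.sigma2_m > 0
            if has_m:
                mat = _polygenic_values(pedigree, np.array([[t.sigma2_m]]), rng)[:, 0]
            keep = np.arange(n) if not has_m else np.flatnonzero(pedigree.dam >= 0)
            rows = []
            for rec in range(t.records_per_animal):
                e = rng.normal(0.0, t.residual_sd, size=len(keep))
                y = t.mean + tbv[keep] + pe[keep] + e
                df = pd.DataFrame(
                    {
                        "animal": [pedigree.ids[i] for i in keep],
                        "trait": t.trait_name,
                        "record": rec + 1,
                        "value": y,
                        "tbv": tbv[keep],
                    }
                )
                if has_m:
                    dam_m = mat[pedigree.dam[keep]]
                    df["value"] += dam_m
                    df["tbv_maternal"] = mat[keep]
                for fac, levels in t.fixed_factors.items():
                    names = list(levels)
                    if fac == "sex" and pedigree.sex is not None:
                        lev = [pedigree.sex[i] for i in keep]
                        lev = [x if x in levels else names[0] for x in lev]
                    else:
                        lev = [names[j] for j in rng.integers(0, len(names), size=len(keep))]
                    df[fac] = pd.Categorical(lev, categories=names)
                    df["value"] += np.array([levels[x] for x in lev])
                rows.append(df)
            frames.append(pd.concat(rows, ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    return out


# ----------------------------------------------------------------------
def default_traits() -> list[SyntheticTraitDefinition]:
    """Trait set mirroring the three study groups.

    A repeated-lactation milk trait (additive + permanent environment), a
    repeated reproduction trait, a newborn growth trait with a maternal
    genetic component, and a genetically correlated pair of 6-month growth
    traits for bivariate analyses. Factor effects are declared constants.
    """
    seasons = {"spring": 0.0, "summer": -0.4, "autumn": 0.2, "winter": 0.1}

    def scaled(d: dict[str, dict[str, float]], s: float) -> dict[str, dict[str, float]]:
        return {f: {k: v * s for k, v in levels.items()} for f, levels in d.items()}

    milk_factors = {
        "herd": {"h1": 0.0, "h2": 0.3},
        "parity": {"p1": 0.0, "p2": 0.25, "p3": 0.35, "p4": 0.3, "p5plus": 0.2},
        "calving_year": {"y2019": 0.0, "y2020": 0.1, "y2021": 0.25, "y2022": 0.35, "y2023": 0.5},
        "calving_season": dict(seasons),
        "lactation_stage": {"d0_100": 0.0, "d101_200": -0.15, "d201_plus": -0.35},
    }
    repro_factors = {
        "herd": {"h1": 0.0, "h2": 0.2},
        "parity": {"p1": 0.0, "p2": -0.15, "p3": -0.2, "p4": -0.1, "p5plus": 0.1},
        "breeder_first": {f"t{i}": e for i, e in enumerate((0.0, 0.15, -0.1, 0.25, 0.05))},
        "service_year_first": {"y2020": 0.0, "y2021": 0.1, "y2022": -0.1, "y2023": 0.15},
        "service_season_first": dict(seasons),
    }
    growth_factors = {
        "birth_year": {f"y{2017+i}": e for i, e in enumerate((0.0, 0.1, 0.2, 0.15, 0.3, 0.25, 0.4))},
        "birth_month": {f"m{i+1:02d}": 0.1 * np.sin(i / 12 * 2 * np.pi) for i in range(12)},
        "sex": {"M": 0.0, "F": -0.6},
    }
    return [
        SyntheticTraitDefinition(
            "milk_yield", mean=6000.0, h2_true=0.25, repeatability=0.40, residual_sd=700.0,
            records_per_animal=3, fixed_factors=scaled(milk_factors, 500.0), group="milk",
        ),
        SyntheticTraitDefinition(
            "calving_interval", mean=400.0, h2_true=0.08, repeatability=0.15, residual_sd=35.0,
            records_per_animal=2, fixed_factors=scaled(repro_factors, 20.0), group="reproduction",
        ),
        SyntheticTraitDefinition(
            "birth_weight", mean=40.0, h2_true=0.30, maternal_h2=0.10, residual_sd=3.1,
            records_per_animal=1, fixed_factors=scaled(growth_factors, 3.0), group="growth",
        ),
        SyntheticTraitDefinition(
            "weight_6mo", mean=180.0, h2_true=0.35, residual_sd=16.0, records_per_animal=1,
            fixed_factors=scaled(growth_factors, 15.0), group="growth",
            genetic_correlation_partner=("height_6mo", 0.5),
        ),
        SyntheticTraitDefinition(
            "height_6mo", mean=105.0, h2_true=0.40, residual_sd=3.9, records_per_animal=1,
            fixed_factors=scaled(growth_factors, 3.5), group="growth",
        ),
    ]


def simulate_herd(
    config: SimulationConfig | None = None,
    traits: list[SyntheticTraitDefinition] | None = None,
) -> dict:
    """One-call herd simulation: pedigree, genotypes, phenotypes, truth."""
    cfg = config or SimulationConfig()
    trts = traits if traits is not None else default_traits()
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    pheno = simulate_phenotypes(ped, geno, trts, config=cfg)
    gids = genotyped_subset(ped, cfg)
    truth = (
        pheno.drop_duplicates(["animal", "trait"])[
            ["animal", "trait", "tbv"] + (["tbv_maternal"] if "tbv_maternal" in pheno else [])
        ].reset_index(drop=True)
    )
    return {
        "config": cfg,
        "traits": trts,
        "pedigree": ped,
        "genotypes": geno,
        "phenotypes": pheno,
        "genotyped_ids": gids,
        "truth": truth,
    }
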