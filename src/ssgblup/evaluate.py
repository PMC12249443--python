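"""Breeding-value estimation and reliability comparison.

Solves the mixed-model equations for EBV (PBLUP, A-based) or GEBV
(ssGBLUP, H-based), computes per-animal model reliabilities
R² = 1 − PEV/σ²a from the inverse of the coefficient matrix, validation
reliabilities against the truth or against adjusted phenotypes, and the
PBLUP-vs-ssGBLUP comparison tables over the whole population, the
genotyped subset, and genotyped animals plus their pedigree relatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mme import MMESystem, solve_mme
from .pedigree import Pedigree


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationResult:
    """Per-animal solutions of one evaluation."""

    method: str  # PBLUP | ssGBLUP
    trait: str
    ids: list[str]
    ebv: np.ndarray
    pev: np.ndarray
    reliability: np.ndarray
    fixed_effects: dict[str, float]
    sigma2_a: float
    sigma2_e: float
    solutions: dict[str, np.ndarray] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.ids, "ebv": self.ebv, "pev": self.pev,
             "reliability": self.reliability}
        )

    def ebv_of(self, ids) -> np.ndarray:
        idx = {a: i for i, a in enumerate(self.ids)}
        return np.array([self.ebv[idx[str(a)]] for a in ids])

    def reliability_of(self, ids) -> np.ndarray:
        idx = {a: i for i, a in enumerate(self.ids)}
        return np.array([self.reliability[idx[str(a)]] for a in ids])


def solve_blup(
    system: MMESystem,
    sigma2_a: float,
    sigma2_e: float,
    method: str = "PBLUP",
    dense_cap: int = 8000,
) -> EvaluationResult:
    """Solve the MME and attach PEV-based reliabilities.

    EBVs are produced for every animal carried by the relationship inverse,
    including recordless ones (predicted through the pedigree/genomic
    covariance).
    """
    sol, slices, pev_fn = solve_mme(system, dense_cap=dense_cap)
    a = slices["additive"]
    ebv = sol[a]
    pev = pev_fn(sigma2_e)
    rel = reliability_from_pev(pev, sigma2_a)
    fixed = dict(zip(system.fixed_names, sol[slices["fixed"]]))
    sols = {t: sol[s] for t, s in slices.items() if t != "fixed"}
    return EvaluationResult(
        method=method, trait=system.spec.trait, ids=list(system.kinv.ids),
        ebv=ebv, pev=pev, reliability=rel, fixed_effects=fixed,
        sigma2_a=sigma2_a, sigma2_e=sigma2_e, solutions=sols,
    )


def reliability_from_pev(
    pev: np.ndarray, sigma2_a: float, inbreeding: np.ndarray | None = None
) -> np.ndarray:
    """R² = 1 − PEV/σ²a per animal, clamped to [0, 1).

    With ``inbreeding`` supplied the denominator becomes (1 + F_i)σ²a.
    """
    if sigma2_a <= 0:
        raise EvaluationError("sigma2_a must be positive")
    denom = sigma2_a * (1.0 + inbreeding) if inbreeding is not None else sigma2_a
    r = 1.0 - np.asarray(pev, dtype=float) / denom
    return np.clip(r, 0.0, np.nextafter(1.0, 0.0))


def validation_reliability(
    result: EvaluationResult,
    truth_or_phenotypes,
    h2: float | None = None,
    mode: str = "truth",
    ids=None,
) -> float:
    """Scalar validation reliability over a set of validation animals.

    mode="truth": Cor²(GEBV, true breeding value). mode="phenotype":
    Cor²(GEBV, adjusted phenotype)/h², where the adjusted phenotype is the
    record minus the fitted fixed effects; values above 1 are flagged with
    a warning attribute rather than clamped.
    """
    if mode not in ("truth", "phenotype"):
        raise EvaluationError("mode must be 'truth' or 'phenotype'")
    if mode == "truth":
        t = truth_or_phenotypes
        if isinstance(t, pd.DataFrame):
            t = t.set_index("animal")["tbv"]
        ids = list(ids) if ids is not None else [a for a in result.ids if str(a) in t.index]
        target = np.array([t[str(a)] for a in ids], dtype=float)
    else:
        if h2 is None or h2 <= 0:
            raise EvaluationError("phenotype mode requires h2 > 0")
        d = truth_or_phenotypes
        d = d.loc[d["trait"] == result.trait] if "trait" in d.columns else d
        d = d.groupby("animal", as_index=True)["adjusted"].mean()
        ids = list(ids) if ids is not None else [a for a in result.ids if str(a) in d.index]
        target = np.array([d[str(a)] for a in ids], dtype=float)
    if len(ids) < 10:
        raise EvaluationError("fewer than 10 validation animals")
    pred = result.ebv_of(ids)
    c = float(np.corrcoef(pred, target)[0, 1])
    rel = c * c if mode == "truth" else c * c / h2
    return rel


def adjusted_phenotypes(data: pd.DataFrame, result: EvaluationResult, spec) -> pd.DataFrame:
    """Records minus fitted fixed effects from a (training) evaluation."""
    from .mme import fixed_design

    d = data.loc[data["trait"] == result.trait] if "trait" in data.columns else data
    d = d.reset_index(drop=True).copy()
    X, names = fixed_design(d, spec.fixed_factors)
    b = np.array([result.fixed_effects.get(nm, 0.0) for nm in names])
    d["adjusted"] = d["value"].to_numpy(dtype=float) - X @ b
    return d


# ----------------------------------------------------------------------
@dataclass
class PopulationSubsets:
    whole: list[str]
    genotyped: list[str]
    genotyped_and_relatives: list[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {"whole": self.whole, "genotyped": self.genotyped,
                "genotyped_and_relatives": self.genotyped_and_relatives}


def define_subsets(pedigree: Pedigree, genotyped_ids) -> PopulationSubsets:
    """Whole / genotyped / genotyped-plus-relatives id sets.

    Relatives are animals with a nonzero additive relationship to at least
    one genotyped animal; two animals are related exactly when they share a
    common ancestor, i.e. when their founder-ancestor sets intersect.
    """
    genotyped_ids = [str(g) for g in genotyped_ids]
    gset = set(genotyped_ids)
    unknown = gset - set(pedigree.ids)
    if unknown:
        raise EvaluationError(f"genotyped ids outside the pedigree: {sorted(unknown)[:5]}")
    if not gset:
        return PopulationSubsets(list(pedigree.ids), [], [])
    n = len(pedigree)
    founders: list[frozenset[int]] = []
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        fs: set[int] = set()
        if s >= 0:
            fs |= founders[s]
        if d >= 0:
            fs |= founders[d]
        if s < 0 and d < 0:
            fs.add(i)
        founders.append(frozenset(fs))
    marked = set().union(*(founders[i] for i in pedigree.index_of(genotyped_ids)))
    rel = [pedigree.ids[i] for i in range(n) if founders[i] & marked]
    return PopulationSubsets(list(pedigree.ids), genotyped_ids, rel)


@dataclass
class ComparisonTable:
    """Per-subset PBLUP-vs-ssGBLUP reliability comparison for one trait."""

    trait: str
    table: pd.DataFrame       # subset, n, mean_rel_pblup, mean_rel_ssgblup, delta_rel_pct, corr
    density: pd.DataFrame     # subset × method reliability deciles


def compare_methods(
    pblup: EvaluationResult, ssgblup: EvaluationResult, subsets: PopulationSubsets
) -> ComparisonTable:
    """Mean reliabilities, Δrel (percentage points) and EBV–GEBV correlation
    per population subset, with reliability decile summaries."""
    if set(pblup.ids) != set(ssgblup.ids):
        raise EvaluationError("evaluations cover different animal sets")
    rows, dens = [], []
    qs = np.linspace(0.1, 0.9, 9)
    for name, ids in subsets.as_dict().items():
        if not ids:
            rows.append((name, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        rp = pblup.reliability_of(ids)
        rs = ssgblup.reliability_of(ids)
        ep = pblup.ebv_of(ids)
        es = ssgblup.ebv_of(ids)
        corr = float(np.corrcoef(ep, es)[0, 1]) if len(ids) >= 2 and np.std(ep) > 0 and np.std(es) > 0 else np.nan
        delta = 100.0 * (float(np.mean(rs)) - float(np.mean(rp)))
        rows.append((name, len(ids), float(np.mean(rp)), float(np.mean(rs)), delta, corr))
        for meth, r in (("PBLUP", rp), ("ssGBLUP", rs)):
            dens.append([name, meth] + list(np.quantile(r, qs)))
    table = pd.DataFrame(
        rows, columns=["subset", "n", "mean_rel_pblup", "mean_rel_ssgblup",
                       "delta_rel_pct", "corr_ebv_gebv"]
    )
    density = pd.DataFrame(dens, columns=["subset", "method"] + [f"q{int(q*100)}" for q in qs])
    return ComparisonTable(pblup.trait, table, density)
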