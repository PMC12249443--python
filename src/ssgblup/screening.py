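"""Fixed-effect screening: per-factor GLM F-tests and model selection.

Each candidate factor is tested by a marginal (drop-one, Type-III-style)
F-test from an ordinary-least-squares fit of the full fixed model with
sum-to-zero level constraints; factors significant at the chosen level are
carried into the trait's mixed-model specification, whose random terms
follow the trait group (repeated milk/reproduction records → permanent
environment; newborn growth → maternal genetic effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


class ScreeningError(ValueError):
    pass


@dataclass
class TraitModelSpec:
    """Mixed-model specification for one trait."""

    trait: str
    fixed_factors: dict[str, list[str]] = field(default_factory=dict)
    random_terms: tuple[str, ...] = ("additive",)
    relationship: str = "A"  # A (PBLUP) or H (ssGBLUP)
    aliased_factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "additive" not in self.random_terms:
            raise ScreeningError("the additive genetic term is always present")
        extra = set(self.random_terms) - {"additive", "permanent_env", "maternal"}
        if extra:
            raise ScreeningError(f"unknown random terms: {sorted(extra)}")
        if self.relationship not in ("A", "H"):
            raise ScreeningError("relationship source must be 'A' or 'H'")

    def with_relationship(self, rel: str) -> "TraitModelSpec":
        return TraitModelSpec(self.trait, dict(self.fixed_factors), self.random_terms, rel,
                              self.aliased_factors)


def _tier(p: float) -> str:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def fit_glm_anova(
    data: pd.DataFrame, trait: str, candidate_factors: list[str]
) -> pd.DataFrame:
    """Marginal F-tests of candidate fixed factors for one trait.

    Fits value ~ Σ C(factor, Sum) by OLS on the trait's records and reports
    a drop-one (Type III) F per factor, with significance tiers at 0.05 and
    0.01. Aliased (rank-deficient) factors are reported with NaN statistics
    rather than silently dropped.

    Returns a FTestReport frame: trait, factor, F, df_num, df_den, p_value,
    tier, aliased.
    """
    d = data.loc[data["trait"] == trait] if "trait" in data.columns else data
    if d.empty:
        raise ScreeningError(f"no records for trait {trait!r}")
    d = d.copy()
    for f in candidate_factors:
        if f not in d.columns:
            raise ScreeningError(f"factor {f!r} missing from the phenotype table")
        levels = pd.unique(d[f].dropna())
        if len(levels) < 2:
            raise ScreeningError(f"factor {f!r} has fewer than 2 observed levels")
        d[f] = d[f].astype(str)
    d = d.rename(columns={"value": "_y"}) if "value" in d.columns else d
    if "_y" not in d.columns:
        raise ScreeningError("phenotype table must have a 'value' column")
    formula = "_y ~ " + " + ".join(f"C({f}, Sum)" for f in candidate_factors)
    fit = smf.ols(formula, data=d).fit()
    n_params_full = sum(d[f].nunique() - 1 for f in candidate_factors) + 1
    rank = np.linalg.matrix_rank(fit.model.exog)
    aliased: list[str] = []
    if rank < n_params_full:
        # identify factors whose removal does not reduce design rank
        for f in candidate_factors:
            others = [g for g in candidate_factors if g != f]
            if not others:
                continue
            sub = smf.ols("_y ~ " + " + ".join(f"C({g}, Sum)" for g in others), data=d)
            if np.linalg.matrix_rank(sub.exog) == rank:
                aliased.append(f)
    rows = []
    if not aliased:
        an = anova_lm(fit, typ=3)
        for f in candidate_factors:
            r = an.loc[f"C({f}, Sum)"]
            F, p = float(r["F"]), float(r["PR(>F)"])
            if float(r["sum_sq"]) <= 1e-12 * max(1.0, float(np.sum(d["_y"] ** 2))):
                F, p = 0.0, 1.0  # no between-level variance (degenerate 0/0 case)
            rows.append((trait, f, F, int(r["df"]), int(fit.df_resid),
                         p, _tier(p), False))
    else:
        for f in candidate_factors:
            if f in aliased:
                rows.append((trait, f, np.nan, d[f].nunique() - 1, int(fit.df_resid),
                             np.nan, "aliased", True))
            else:
                others = [g for g in candidate_factors if g != f]
                red = smf.ols("_y ~ " + " + ".join(f"C({g}, Sum)" for g in others)
                              if others else "_y ~ 1", data=d).fit()
                cmp = sm.stats.anova_lm(red, fit)
                F = float(cmp["F"].iloc[-1]); p = float(cmp["Pr(>F)"].iloc[-1])
                rows.append((trait, f, F, int(cmp["df_diff"].iloc[-1]), int(fit.df_resid),
                             p, _tier(p), False))
    return pd.DataFrame(
        rows, columns=["trait", "factor", "F", "df_num", "df_den", "p_value", "tier", "aliased"]
    )


GROUP_RANDOM_TERMS = {
    "milk": ("additive", "permanent_env"),
    "reproduction": ("additive", "permanent_env"),
    "reproduction_heifer": ("additive",),
    "growth": ("additive", "maternal"),
    "growth_6mo": ("additive",),
}


def select_fixed_effects(
    report: pd.DataFrame,
    alpha: float = 0.05,
    data: pd.DataFrame | None = None,
    trait_group: str | None = None,
    repeated_records: bool | None = None,
    has_maternal: bool | None = None,
) -> TraitModelSpec:
    """Build a TraitModelSpec from an F-test report.

    Factors with p < alpha are retained as fixed effects. Random terms
    follow the trait group when given (milk/cow-reproduction → permanent
    environment; newborn growth → maternal), refined by whether the data
    actually carry repeated records / recorded dams.
    """
    if report.empty:
        raise ScreeningError("empty F-test report")
    trait = str(report["trait"].iloc[0])
    keep = report.loc[report["p_value"] < alpha, "factor"].tolist()
    levels: dict[str, list[str]] = {}
    if data is not None:
        d = data.loc[data["trait"] == trait] if "trait" in data.columns else data
        for f in keep:
            levels[f] = sorted(map(str, pd.unique(d[f].dropna())))
    else:
        levels = {f: [] for f in keep}
    terms = list(GROUP_RANDOM_TERMS.get(trait_group or "", ("additive",)))
    if repeated_records is False and "permanent_env" in terms:
        terms.remove("permanent_env")
    if repeated_records and "permanent_env" not in terms and trait_group in (None, ""):
        terms.append("permanent_env")
    if has_maternal is False and "maternal" in terms:
        terms.remove("maternal")
    aliased = tuple(report.loc[report.get("aliased", False) == True, "factor"])  # noqa: E712
    return TraitModelSpec(trait, levels, tuple(terms), "A", aliased)


def write_report(report: pd.DataFrame, path) -> None:
    """TSV report with the conventional star annotation."""
    out = report.copy()
    out["stars"] = np.where(out["p_value"] < 0.01, "**",
                            np.where(out["p_value"] < 0.05, "*", ""))
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
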