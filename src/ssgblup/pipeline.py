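"""End-to-end genetic-evaluation pipeline over an on-disk run directory.

Stages: simulate (or load user files) → genotype QC → relationship
matrices → fixed-effect screening → REML variance components and
heritabilities (PBLUP and ssGBLUP) → bivariate correlations → breeding
value estimation with reliabilities → method comparison. Each stage reads
its inputs from, and writes its outputs to, a run directory with fixed
file names, so any stage can be re-run in isolation; a JSON manifest
records seed, configuration hash, package version, and per-stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (adjusted_phenotypes, compare_methods, define_subsets,
                       solve_blup, validation_reliability)
from .genotypes import GenotypeMatrix, QCThresholds, qc_filter_genotypes
from .mme import assemble_mme
from .pedigree import Pedigree
from .relationship import blend_and_tune_G, build_genomic_matrix, build_H_inverse
from .reml import bivariate_reml, correlations, heritability, reml_estimate
from .screening import TraitModelSpec, fit_glm_anova, select_fixed_effects, write_report
from .simulate import (SimulationConfig, SyntheticTraitDefinition, default_traits,
                       genotyped_subset, simulate_genotypes, simulate_pedigree,
                       simulate_phenotypes)

FLOAT_FMT = "%.8g"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulation- or file-driven)."""

    outdir: str = "run"
    seed: int = 20250101
    simulation: SimulationConfig | None = None
    traits: list[SyntheticTraitDefinition] | None = None
    pedigree_path: str | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    alpha: float = 0.05
    blend_weight: float = 0.95
    tune_G: bool = False
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    validation_split: bool = True
    dense_cap: int = 8000

    def __post_init__(self) -> None:
        sim = self.simulation is not None
        files = self.pedigree_path is not None
        if sim == files:
            raise PipelineError("exactly one of simulation config / input paths must be set")
        if sim and self.simulation.seed != self.seed:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # a run's identity is independent of where it lives
        blob = json.dumps(d, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ----------------------------------------------------------------------
def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    traits = cfg.traits if cfg.traits is not None else default_traits()
    if cfg.simulation is not None:
        ped = simulate_pedigree(cfg.simulation)
        geno_all = simulate_genotypes(ped, cfg.simulation)
        pheno = simulate_phenotypes(ped, geno_all, traits, config=cfg.simulation)
        gids = genotyped_subset(ped, cfg.simulation)
        if gids:
            gpos = {a: i for i, a in enumerate(geno_all.ids)}
            geno = geno_all.subset(animal_idx=[gpos[g] for g in gids])
        else:
            geno = None
        truth_cols = ["animal", "trait", "tbv"] + (
            ["tbv_maternal"] if "tbv_maternal" in pheno.columns else [])
        truth = pheno.drop_duplicates(["animal", "trait"])[truth_cols]
        truth.to_csv(out / "truth.csv", index=False, float_format=FLOAT_FMT)
    else:
        ped = Pedigree.from_csv(cfg.pedigree_path)
        pheno = pd.read_csv(cfg.phenotype_path)
        geno = GenotypeMatrix.from_raw(cfg.genotype_path) if cfg.genotype_path else None
        gids = list(geno.ids) if geno is not None else []
    ped.to_csv(out / "pedigree.csv")
    pheno.to_csv(out / "phenotypes.csv", index=False, float_format=FLOAT_FMT)
    if geno is not None:
        geno.to_raw(out / "genotypes_raw.txt")
    (out / "genotyped_ids.txt").write_text("\n".join(gids) + ("\n" if gids else ""))
    return {"pedigree": ped, "phenotypes": pheno, "genotypes": geno,
            "genotyped_ids": gids, "traits": traits}


def stage_qc(cfg: RunConfig, out: Path, geno: GenotypeMatrix | None) -> GenotypeMatrix | None:
    if geno is None:
        return None
    filtered, report = qc_filter_genotypes(geno, cfg.qc)
    _write(report.to_frame(), out / "qc_report.tsv")
    filtered.to_raw(out / "genotypes_qc.txt")
    return filtered


def stage_matrices(cfg: RunConfig, out: Path, ped: Pedigree, geno: GenotypeMatrix | None):
    ainv = ped.a_inverse()
    hinv = None
    gids: list[str] = []
    if geno is not None and geno.n_animals > 0:
        gids = [a for a in geno.ids if a in set(ped.ids)]
        A22 = ped.relationship_matrix(subset=gids)
        A22.kind = "A22"
        G = build_genomic_matrix(geno)
        Gs = blend_and_tune_G(G, A22, cfg.blend_weight, cfg.tune_G)
        hinv = build_H_inverse(ainv, Gs, A22, gids)
        Gs.to_triplets(out / "Gstar.tsv")
        A22.to_triplets(out / "A22.tsv")
    ainv.to_triplets(out / "Ainv.tsv", tol=1e-12)
    if hinv is not None:
        hinv.to_triplets(out / "Hinv.tsv", tol=1e-12)
    return ainv, hinv, gids


def stage_screen(cfg: RunConfig, out: Path, pheno: pd.DataFrame,
                 traits: list[SyntheticTraitDefinition]) -> dict[str, TraitModelSpec]:
    from .screening import GROUP_RANDOM_TERMS

    reports = []
    specs: dict[str, TraitModelSpec] = {}
    for t in traits:
        factors = [f for f in t.fixed_factors if f in pheno.columns]
        if factors:
            rep = fit_glm_anova(pheno, t.trait_name, factors)
            reports.append(rep)
            specs[t.trait_name] = select_fixed_effects(
                rep, cfg.alpha, data=pheno, trait_group=t.group,
                repeated_records=t.records_per_animal > 1,
                has_maternal=t.maternal_h2 is not None,
            )
        else:  # mean-only fixed model; random terms still follow the group
            terms = list(GROUP_RANDOM_TERMS.get(t.group or "", ("additive",)))
            if t.records_per_animal == 1 and "permanent_env" in terms:
                terms.remove("permanent_env")
            if t.maternal_h2 is None and "maternal" in terms:
                terms.remove("maternal")
            specs[t.trait_name] = TraitModelSpec(t.trait_name, {}, tuple(terms))
    if reports:
        write_report(pd.concat(reports, ignore_index=True), out / "screening.tsv")
    else:
        (out / "screening.tsv").write_text(
            "trait\tfactor\tF\tdf_num\tdf_den\tp_value\ttier\taliased\tstars\n")
    with open(out / "model_specs.yaml", "w") as fh:
        yaml.safe_dump(
            {k: {"fixed_factors": v.fixed_factors, "random_terms": list(v.random_terms)}
             for k, v in specs.items()}, fh, sort_keys=True)
    return specs


def stage_reml(cfg: RunConfig, out: Path, specs, pheno, ainv, hinv, ped):
    rows = []
    results: dict[tuple[str, str], object] = {}
    for trait, spec in specs.items():
        for method, kinv in (("PBLUP", ainv), ("ssGBLUP", hinv)):
            if kinv is None:
                continue
            vc = reml_estimate(spec, pheno, kinv, tol=cfg.reml_tol,
                               max_iter=cfg.reml_max_iter, pedigree=ped)
            h2, se = heritability(vc)
            results[(trait, method)] = vc
            for comp, est in vc.components.items():
                rows.append((trait, method, comp, est,
                             float(np.sqrt(max(vc.cov[vc.names.index(comp),
                                                      vc.names.index(comp)], 0.0))),
                             h2, se, vc.converged, vc.iterations))
    _write(pd.DataFrame(rows, columns=["trait", "method", "component", "estimate", "se",
                                       "h2", "h2_se", "converged", "iterations"]),
           out / "variance_components.tsv")
    return results


def stage_bivariate(cfg: RunConfig, out: Path, specs, pheno, ainv,
                    traits: list[SyntheticTraitDefinition]):
    rows = []
    for t in traits:
        if t.genetic_correlation_partner is None:
            continue
        partner, _ = t.genetic_correlation_partner
        bc = bivariate_reml(specs[t.trait_name], specs[partner], pheno, ainv)
        ra, rp = correlations(bc)
        rows.append((t.trait_name, partner, bc.G0[0, 1], bc.R0[0, 1], ra, rp, bc.converged))
    df = pd.DataFrame(rows, columns=["trait_i", "trait_j", "cov_a", "cov_e",
                                     "r_genetic", "r_phenotypic", "converged"])
    _write(df, out / "correlations.tsv")
    return df


def stage_evaluate(cfg: RunConfig, out: Path, specs, pheno, ainv, hinv, ped,
                   vcs, truth: pd.DataFrame | None):
    """BLUP/ssGBLUP solutions, reliabilities, and forward validation."""
    evals: dict[tuple[str, str], object] = {}
    val_rows = []
    youngest = ped.generation.max()
    mask = np.array([ped.generation[ped.index_of([a])[0]] == youngest
                     for a in pheno["animal"]])
    train = pheno.loc[~mask] if cfg.validation_split else pheno
    for (trait, method), vc in vcs.items():
        spec = specs[trait]
        kinv = ainv if method == "PBLUP" else hinv
        ratios = {t: vc.ratio(t) for t in spec.random_terms}
        sys_ = assemble_mme(spec, train, kinv, ratios, pedigree=ped)
        # boundary estimates enter at the same floor the ratios use
        s2a = max(vc.sigma2_a, 1e-6 * vc.sigma2_p)
        res = solve_blup(sys_, s2a, vc.sigma2_e, method=method,
                         dense_cap=cfg.dense_cap)
        evals[(trait, method)] = res
        _write(res.frame(), out / f"evaluation_{trait}_{method}.tsv")
        if cfg.validation_split:
            vids = [ped.ids[i] for i in np.flatnonzero(ped.generation == youngest)]
            h2, _ = heritability(vc)
            if truth is not None:
                tt = truth.loc[truth["trait"] == trait]
                try:
                    r2t = validation_reliability(res, tt, mode="truth",
                                                 ids=[a for a in vids if a in set(tt["animal"])])
                except Exception:
                    r2t = np.nan
            else:
                r2t = np.nan
            try:
                adj = adjusted_phenotypes(pheno.loc[mask], res, spec)
                r2p = validation_reliability(res, adj, h2=h2, mode="phenotype",
                                             ids=sorted(set(map(str, adj["animal"]))))
            except Exception:
                r2p = np.nan
            val_rows.append((trait, method, r2t, r2p, len(vids)))
    if val_rows:
        _write(pd.DataFrame(val_rows, columns=["trait", "method", "r2_truth",
                                               "r2_phenotype", "n_validation"]),
               out / "validation.tsv")
    return evals


def stage_compare(cfg: RunConfig, out: Path, evals, ped, gids):
    subsets = define_subsets(ped, gids)
    tables = {}
    for trait in {t for t, _ in evals}:
        if (trait, "ssGBLUP") not in evals:
            continue
        ct = compare_methods(evals[(trait, "PBLUP")], evals[(trait, "ssGBLUP")], subsets)
        _write(ct.table, out / f"comparison_{trait}.tsv")
        _write(ct.density, out / f"density_{trait}.tsv")
        tables[trait] = ct
    return tables


# ----------------------------------------------------------------------
def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage; returns the run directory. Any stage failure aborts
    with the stage name, leaving a partial-results manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__, "seed": cfg.seed, "config_hash": cfg.digest(),
        "stages": {}, "mode": "simulation" if cfg.simulation else "files",
    }

    def record(stage: str, ok: bool, note: str = "") -> None:
        manifest["stages"][stage] = {"ok": ok, **({"note": note} if note else {})}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    stage = "simulate"
    try:
        art = stage_simulate(cfg, out)
        record(stage, True)
        ped, pheno, traits = art["pedigree"], art["phenotypes"], art["traits"]
        truth = None
        if (out / "truth.csv").exists():
            truth = pd.read_csv(out / "truth.csv", dtype={"animal": str})
        stage = "qc"
        geno = stage_qc(cfg, out, art["genotypes"])
        record(stage, True, "" if geno is not None else "no genotypes: PBLUP-only run")
        stage = "matrices"
        ainv, hinv, gids = stage_matrices(cfg, out, ped, geno)
        record(stage, True)
        stage = "screen"
        specs = stage_screen(cfg, out, pheno, traits)
        record(stage, True)
        stage = "reml"
        vcs = stage_reml(cfg, out, specs, pheno, ainv, hinv, ped)
        record(stage, True)
        stage = "bivariate"
        stage_bivariate(cfg, out, specs, pheno, ainv, traits)
        record(stage, True)
        stage = "evaluate"
        evals = stage_evaluate(cfg, out, specs, pheno, ainv, hinv, ped, vcs, truth)
        record(stage, True)
        stage = "compare"
        stage_compare(cfg, out, evals, ped, gids)
        record(stage, True, "" if hinv is not None else "ssGBLUP outputs absent")
    except Exception as e:
        record(stage, False, f"{type(e).__name__}: {e}")
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    return out
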