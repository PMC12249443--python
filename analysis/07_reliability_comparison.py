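"""Breeding-value estimation and the PBLUP-vs-ssGBLUP reliability
comparison over the whole population, the genotyped subset, and genotyped
animals plus relatives, with forward validation on the youngest
generation."""

import pandas as pd

from common import RUN_DIR, study_config
from ssgblup.genotypes import GenotypeMatrix
from ssgblup.pedigree import Pedigree
from ssgblup.pipeline import (stage_compare, stage_evaluate, stage_matrices,
                              stage_reml, stage_screen)


def main() -> None:
    cfg = study_config()
    ped = Pedigree.from_csv(RUN_DIR / "pedigree.csv")
    pheno = pd.read_csv(RUN_DIR / "phenotypes.csv")
    truth = pd.read_csv(RUN_DIR / "truth.csv", dtype={"animal": str})
    geno = GenotypeMatrix.from_raw(RUN_DIR / "genotypes_qc.txt")
    ainv, hinv, gids = stage_matrices(cfg, RUN_DIR, ped, geno)
    specs = stage_screen(cfg, RUN_DIR, pheno, cfg.traits)
    vcs = stage_reml(cfg, RUN_DIR, specs, pheno, ainv, hinv, ped)
    evals = stage_evaluate(cfg, RUN_DIR, specs, pheno, ainv, hinv, ped, vcs, truth)
    tables = stage_compare(cfg, RUN_DIR, evals, ped, gids)
    for trait, ct in tables.items():
        print(f"\n=== {trait} ===")
        print(ct.table.round(4).to_string(index=False))
    print("\nforward validation (truth- and phenotype-mode reliabilities):")
    print(pd.read_csv(RUN_DIR / "validation.tsv", sep="\t").round(4).to_string(index=False))


if __name__ == "__main__":
    main()
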