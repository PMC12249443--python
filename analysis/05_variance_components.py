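"""REML variance components and heritabilities, PBLUP vs ssGBLUP.

Estimates each trait's components under the pedigree (A) and single-step
(H) variance structures and prints h² ± SE per trait and method.
"""

import numpy as np
import pandas as pd

from common import RUN_DIR, study_config
from ssgblup.genotypes import GenotypeMatrix
from ssgblup.pedigree import Pedigree
from ssgblup.pipeline import stage_matrices, stage_reml, stage_screen


def main() -> None:
    cfg = study_config()
    ped = Pedigree.from_csv(RUN_DIR / "pedigree.csv")
    pheno = pd.read_csv(RUN_DIR / "phenotypes.csv")
    geno = GenotypeMatrix.from_raw(RUN_DIR / "genotypes_qc.txt")
    ainv, hinv, _ = stage_matrices(cfg, RUN_DIR, ped, geno)
    specs = stage_screen(cfg, RUN_DIR, pheno, cfg.traits)
    stage_reml(cfg, RUN_DIR, specs, pheno, ainv, hinv, ped)
    vc = pd.read_csv(RUN_DIR / "variance_components.tsv", sep="\t")
    h2 = vc.drop_duplicates(["trait", "method"])[["trait", "method", "h2", "h2_se"]]
    print(h2.assign(h2=h2.h2.round(3), h2_se=h2.h2_se.round(3)).to_string(index=False))


if __name__ == "__main__":
    main()
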