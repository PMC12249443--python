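"""Two-trait REML: genetic and phenotypic correlations for the declared
trait pair (6-month weight and height, simulated with rA = 0.5)."""

import pandas as pd

from common import RUN_DIR, study_config
from ssgblup.genotypes import GenotypeMatrix
from ssgblup.pedigree import Pedigree
from ssgblup.pipeline import stage_bivariate, stage_matrices, stage_screen


def main() -> None:
    cfg = study_config()
    ped = Pedigree.from_csv(RUN_DIR / "pedigree.csv")
    pheno = pd.read_csv(RUN_DIR / "phenotypes.csv")
    geno = GenotypeMatrix.from_raw(RUN_DIR / "genotypes_qc.txt")
    ainv, _, _ = stage_matrices(cfg, RUN_DIR, ped, geno)
    specs = stage_screen(cfg, RUN_DIR, pheno, cfg.traits)
    df = stage_bivariate(cfg, RUN_DIR, specs, pheno, ainv, cfg.traits)
    print(df.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
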