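"""Relationship matrices: sparse A⁻¹, A22, blended G*, and H⁻¹.

Writes the matrices as triplet text files and prints structural
diagnostics (sparsity of A⁻¹, agreement of G's diagonal with A22's).
"""

import numpy as np

from common import RUN_DIR, study_config
from ssgblup.genotypes import GenotypeMatrix
from ssgblup.pedigree import Pedigree
from ssgblup.pipeline import stage_matrices


def main() -> None:
    ped = Pedigree.from_csv(RUN_DIR / "pedigree.csv")
    geno = GenotypeMatrix.from_raw(RUN_DIR / "genotypes_qc.txt")
    ainv, hinv, gids = stage_matrices(study_config(), RUN_DIR, ped, geno)
    n = len(ped)
    print(f"A⁻¹: {n}×{n}, {ainv.values.nnz} nonzeros "
          f"({ainv.values.nnz / n**2:.2%} dense)")
    print(f"H⁻¹ correction block: {len(gids)} genotyped animals")
    F = ped.inbreeding()
    print(f"mean inbreeding F = {F.mean():.4f} (max {F.max():.4f})")
    print(f"outputs: Ainv.tsv, A22.tsv, Gstar.tsv, Hinv.tsv in {RUN_DIR}")


if __name__ == "__main__":
    main()
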