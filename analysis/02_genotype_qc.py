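"""Panel quality control on the genotyped subset.

Applies the four filters in order (individual call rate ≥ 0.90, SNP call
rate ≥ 0.90, HWE p ≥ 1e-6, MAF ≥ 0.05), writes qc_report.tsv and the
filtered matrix, and prints the removal counts.
"""

import pandas as pd

from common import RUN_DIR, study_config
from ssgblup.genotypes import GenotypeMatrix
from ssgblup.pipeline import stage_qc


def main() -> None:
    geno = GenotypeMatrix.from_raw(RUN_DIR / "genotypes_raw.txt")
    stage_qc(study_config(), RUN_DIR, geno)
    print(pd.read_csv(RUN_DIR / "qc_report.tsv", sep="\t").to_string(index=False))


if __name__ == "__main__":
    main()
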