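"""Simulate the study herd: pedigree, SNP panel, and multi-trait records.

Writes pedigree.csv, genotypes_raw.txt, phenotypes.csv, truth.csv and the
genotyped-id list to results/run/ and prints the population summary.
"""

from common import RUN_DIR, study_config
from ssgblup.pipeline import stage_simulate


def main() -> None:
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    art = stage_simulate(study_config(), RUN_DIR)
    ped, ph = art["pedigree"], art["phenotypes"]
    print(f"pedigree animals : {len(ped)} over {ped.generation.max() + 1} generations")
    print(f"genotyped subset : {len(art['genotyped_ids'])} animals "
          f"× {art['genotypes'].n_snps} SNPs")
    print(f"phenotype records: {len(ph)} across traits "
          f"{sorted(ph['trait'].unique())}")
    print(f"outputs in {RUN_DIR}")


if __name__ == "__main__":
    main()
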