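"""Shared configuration for the numbered analysis drivers.

One deterministic study herd (~600 animals over three generations, five
traits spanning the milk / reproduction / growth groups, 30% genotyped on
a 1,000-SNP panel) feeds every driver; each driver re-runs the pipeline
stages it needs from this configuration and writes its tables under
results/run/.
"""

from pathlib import Path

from ssgblup import RunConfig, SimulationConfig
from ssgblup.simulate import default_traits

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"
SEED = 20250101


def study_config() -> RunConfig:
    sim = SimulationConfig(
        n_founders=150, n_generations=3, dams_per_sire=3, offspring_per_dam=2,
        n_snps=1000, genotyping_fraction=0.3, seed=SEED,
    )
    return RunConfig(outdir=str(RUN_DIR), seed=SEED, simulation=sim,
                     traits=default_traits())
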