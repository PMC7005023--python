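"""Shared study design for the analysis drivers.

One master seed fixes everything: the synthetic reference database
(14 lineages, 2 cryptic pairs), the 13 stream + 7 lake community profiles
along the pollution gradient, and all per-site sequencing noise
(substitutions at 1e-3/base, 1% chimeras, ~50 read pairs per specimen).
"""

from pathlib import Path

from oligocoi.pipeline import PipelineConfig, derive_seed
from oligocoi.refdb import ReferenceDatabase
from oligocoi.synthetic_data import (
    SimulationConfig,
    gradient_profiles,
    simulate_reference_lineages,
)

MASTER_SEED = 20
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_database() -> ReferenceDatabase:
    return simulate_reference_lineages(
        14, min_sep=0.15, cryptic_pairs=2, seed=derive_seed(MASTER_SEED, "refdb")
    )


def study_profiles(db: ReferenceDatabase):
    return gradient_profiles(
        db, n_stream=13, n_lake=7, seed=derive_seed(MASTER_SEED, "profiles")
    )


def study_config(specimens_per_site: int) -> PipelineConfig:
    return PipelineConfig(
        sim=SimulationConfig(
            specimens_per_site=specimens_per_site,
            reads_per_specimen=50.0,
            per_base_error=0.001,
            chimera_rate=0.01,
        ),
        unresolved_rate=0.10,
        master_seed=MASTER_SEED,
    )
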