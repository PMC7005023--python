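import numpy as np
import pytest

from oligocoi.refdb import ReferenceDatabase, ReferenceRecord, ThresholdPolicy
from oligocoi.synthetic_data import simulate_reference_lineages


@pytest.fixture(scope="session")
def small_db() -> ReferenceDatabase:
    """Eight well-separated synthetic reference lineages."""
    return simulate_reference_lineages(8, min_sep=0.15, seed=7)


@pytest.fixture(scope="session")
def cryptic_db() -> ReferenceDatabase:
    """Twelve lineages, the first two of which have cryptic partners."""
    return simulate_reference_lineages(12, min_sep=0.15, cryptic_pairs=2, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_record(lineage_id="L1", genus="Tubifex", seq="ACGT" * 80, **kw) -> ReferenceRecord:
    defaults = dict(
        taxon_name=f"{genus} sp1" if genus else "Tubificinae g. sp.",
        rank="species" if genus else "subfamily",
        genus=genus,
        group="tubificinae_hair",
        sensitive=False,
        sequence=seq[:313].ljust(313, "A")[:313] if len(seq) != 313 else seq,
    )
    defaults.update(kw)
    return ReferenceRecord(lineage_id=lineage_id, **defaults)


@pytest.fixture()
def policy() -> ThresholdPolicy:
    return ThresholdPolicy()
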