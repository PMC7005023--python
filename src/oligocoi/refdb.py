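"""COI reference database: barcodes, taxonomy, traits and assignment thresholds.

A reference database holds one 313-bp (nominal) COI barcode per known
oligochaete lineage together with the traits needed downstream:

* ``group`` — the coarse taxonomic/ecological group; for Tubificinae the
  split into worms with vs without hair setae is what the stream index
  (IOBS) keys on;
* ``sensitive`` — membership of the lake pollution-sensitivity list (the
  list is an input column, not hard-coded, so species such as
  *Spirosperma ferox* can be flagged sensitive);
* a divergence threshold policy: barcodes closer than 10% K2P to a
  reference are treated as conspecific, except in genera with a stricter
  override (by default *Nais* and *Uncinais* at 8%, applied genus-wide).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RANKS = frozenset({"species", "genus", "subfamily", "family"})
VALID_GROUPS = frozenset(
    {
        "tubificinae_hair",
        "tubificinae_nohair",
        "naidinae",
        "pristininae",
        "lumbriculidae",
        "enchytraeidae",
        "other",
    }
)
#: Family/subfamily display name for each trait group (used for tree placement
#: and for family-level percentage metrics).
GROUP_CLADE = {
    "tubificinae_hair": "Tubificinae",
    "tubificinae_nohair": "Tubificinae",
    "naidinae": "Naidinae",
    "pristininae": "Pristininae",
    "lumbriculidae": "Lumbriculidae",
    "enchytraeidae": "Enchytraeidae",
    "other": "other",
}

NOMINAL_BARCODE_LENGTH = 313

TRAITS_COLUMNS = ["lineage_id", "taxon_name", "rank", "genus", "group", "sensitive"]

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference COI lineage with its taxonomy and index-relevant traits."""

    lineage_id: str
    taxon_name: str
    rank: str
    genus: str | None
    group: str
    sensitive: bool
    sequence: str

    def __post_init__(self) -> None:
        if self.rank not in VALID_RANKS:
            raise ValueError(f"invalid rank {self.rank!r}")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"invalid group {self.group!r}")
        if self.rank == "species" and not self.genus:
            raise ValueError(f"{self.lineage_id}: rank=species requires a genus")
        if set(self.sequence) - _DNA:
            raise ValueError(f"ambiguous reference sequence: {self.lineage_id}")

    @property
    def family(self) -> str:
        return GROUP_CLADE[self.group]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Same-species divergence thresholds: a default plus per-genus overrides."""

    default_threshold: float = 0.10
    genus_overrides: Mapping[str, float] = field(
        default_factory=lambda: {"Nais": 0.08, "Uncinais": 0.08}
    )

    def __post_init__(self) -> None:
        for value in (self.default_threshold, *self.genus_overrides.values()):
            if not 0.0 < value < 0.5:
                raise ValueError(f"threshold {value} outside (0, 0.5)")
        if any(not g for g in self.genus_overrides):
            raise ValueError("empty genus key in overrides")


@dataclass
class ReferenceDatabase:
    records: list[ReferenceRecord]
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.lineage_id in seen:
                raise ValueError(f"duplicate reference: {rec.lineage_id}")
            seen.add(rec.lineage_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, lineage_id: str) -> ReferenceRecord:
        for rec in self.records:
            if rec.lineage_id == lineage_id:
                return rec
        raise KeyError(lineage_id)

    @property
    def sensitive_list(self) -> set[str]:
        return {r.taxon_name for r in self.records if r.sensitive}

    def traits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lineage_id": r.lineage_id,
                    "taxon_name": r.taxon_name,
                    "rank": r.rank,
                    "genus": r.genus or "",
                    "group": r.group,
                    "sensitive": r.sensitive,
                }
                for r in self.records
            ],
            columns=TRAITS_COLUMNS,
        )


def threshold_for(db: ReferenceDatabase, record: ReferenceRecord) -> float:
    """Divergence threshold applicable when assigning against ``record``.

    Genus overrides win over the default; records without a genus (family- or
    subfamily-level references) always use the default.
    """
    if record.genus and record.genus in db.policy.genus_overrides:
        return db.policy.genus_overrides[record.genus]
    return db.policy.default_threshold


def load_reference_db(
    fasta: str | Path,
    traits_table: str | Path,
    policy: ThresholdPolicy | None = None,
) -> ReferenceDatabase:
    """Load reference barcodes (FASTA) and their traits (TSV) into one database.

    Every FASTA entry must have a matching ``lineage_id`` row in the traits
    table; sequences are uppercased and must be unambiguous A/C/G/T. Barcodes
    that are not the nominal 313 bp are accepted with a warning (real
    references vary; distances handle unequal lengths by end-trimmed
    comparison).
    """
    policy = policy or ThresholdPolicy()
    traits = pd.read_csv(traits_table, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(TRAITS_COLUMNS) - set(traits.columns)
    if missing_cols:
        raise ValueError(f"traits table missing columns: {sorted(missing_cols)}")
    by_id = {row.lineage_id: row for row in traits.itertuples(index=False)}
    if len(by_id) != len(traits):
        raise ValueError("duplicate reference: traits table has repeated lineage_id")

    records: list[ReferenceRecord] = []
    for entry in SeqIO.parse(str(fasta), "fasta"):
        row = by_id.get(entry.id)
        if row is None:
            raise ValueError(f"unannotated reference: {entry.id}")
        seq = str(entry.seq).upper()
        if len(seq) != NOMINAL_BARCODE_LENGTH:
            warnings.warn(
                f"reference {entry.id} is {len(seq)} bp "
                f"(nominal {NOMINAL_BARCODE_LENGTH})",
                stacklevel=2,
            )
        records.append(
            ReferenceRecord(
                lineage_id=entry.id,
                taxon_name=row.taxon_name,
                rank=row.rank,
                genus=row.genus or None,
                group=row.group,
                sensitive=_parse_bool(row.sensitive),
                sequence=seq,
            )
        )
    return ReferenceDatabase(records=records, policy=policy)


def write_reference_db(
    db: ReferenceDatabase, fasta: str | Path, traits_table: str | Path
) -> None:
    """Write a database back to FASTA + traits TSV (inverse of ``load_reference_db``)."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.lineage_id, description="") for r in db),
        str(fasta),
        "fasta",
    )
    db.traits_frame().to_csv(traits_table, sep="\t", index=False)


def _parse_bool(text: str | bool) -> bool:
    if isinstance(text, bool):
        return text
    lowered = str(text).strip().lower()
    if lowered in {"true", "1", "yes"}:
        return True
    if lowered in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"cannot parse boolean {text!r}")


def resolve_traits(
    db: ReferenceDatabase, labels: Iterable[str]
) -> dict[str, tuple[str | None, bool]]:
    """Map labels to (group, sensitive); labels unknown to the database get
    ``(None, False)`` — e.g. new lineages whose hair-setae group cannot be
    determined from a barcode alone."""
    known = {r.lineage_id: (r.group, r.sensitive) for r in db}
    by_name = {r.taxon_name: (r.group, r.sensitive) for r in db}
    out: dict[str, tuple[str | None, bool]] = {}
    for label in labels:
        out[label] = known.get(label) or by_name.get(label) or (None, False)
    return out
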