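"""Sediment-quality indices from oligochaete community count tables.

Streams are scored with the Oligochaete Index of Sediment Bioindication,

    IOBS = 10 * S / T,

where S is the number of taxa identified among the specimens examined and T
is the percentage (of all identified specimens) of the dominant group of
tubificids — with hair setae or without hair setae, whichever is larger.
Lakes are scored with the percentage of specimens belonging to
pollution-sensitive taxa. Both metrics map onto five quality classes; the
printed class bands leave literal gaps (e.g. between 5.9 and 6), which are
closed here with half-open intervals. The computation is blind to whether
the counts came from morphological or genetic identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum


class QualityClass(IntEnum):
    """Ordered sediment-quality classes (bad < ... < very_good)."""

    bad = 0
    poor = 1
    medium = 2
    good = 3
    very_good = 4


TUBIFICID_GROUPS = ("tubificinae_hair", "tubificinae_nohair")


@dataclass
class SiteCommunity:
    site_id: str
    habitat: str  # stream | lake
    source: str  # morphological | genetic
    counts: dict[str, int]
    #: label -> (group or None, sensitive flag)
    traits: dict[str, tuple[str | None, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habitat not in ("stream", "lake"):
            raise ValueError(f"invalid habitat {self.habitat!r}")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("counts must be >= 1 per present label")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class IobsResult:
    S: int
    T: float  # percentage 0-100
    iobs: float | None
    quality_class: QualityClass | None


@dataclass(frozen=True)
class LakeResult:
    pct_sensitive: float
    quality_class: QualityClass


def compute_iobs(community: SiteCommunity) -> IobsResult:
    """IOBS = 10*S/T for a stream community; undefined when T = 0.

    S counts every distinct label (new lineages included). T is the larger
    of the two tubificid-group percentages, computed over ALL identified
    specimens; labels without a hair-setae group (e.g. new tubificid
    lineages) contribute to S and the denominator but never to T.
    """
    if community.habitat != "stream":
        raise ValueError("IOBS applies to stream communities")
    total = community.total
    if total == 0:
        raise ValueError("no specimens")
    s = sum(1 for c in community.counts.values() if c >= 1)
    group_counts = {g: 0 for g in TUBIFICID_GROUPS}
    for label, count in community.counts.items():
        group, _ = community.traits.get(label, (None, False))
        if group in group_counts:
            group_counts[group] += count
    t = 100.0 * max(group_counts.values()) / total
    if t == 0.0:
        return IobsResult(S=s, T=0.0, iobs=None, quality_class=None)
    iobs = 10.0 * s / t
    return IobsResult(S=s, T=t, iobs=iobs, quality_class=classify_iobs(iobs))


def classify_iobs(iobs: float | None) -> QualityClass | None:
    """Stream quality class from an IOBS value.

    Bands: >=6 very good, [3,6) good, [2,3) medium, [1,2) poor, [0,1) bad;
    an undefined IOBS passes through as None.
    """
    if iobs is None:
        return None
    if iobs < 0:
        raise ValueError("invalid index")
    if iobs >= 6:
        return QualityClass.very_good
    if iobs >= 3:
        return QualityClass.good
    if iobs >= 2:
        return QualityClass.medium
    if iobs >= 1:
        return QualityClass.poor
    return QualityClass.bad


def percent_sensitive(community: SiteCommunity) -> LakeResult:
    """Percentage of pollution-sensitive specimens in a lake community.

    Labels with no sensitivity flag resolved are counted non-sensitive (with
    a warning). Bands: >50 very good, (20,50] good, (10,20] medium,
    (5,10] poor, [0,5] bad.
    """
    if community.habitat != "lake":
        raise ValueError("percent sensitive applies to lake communities")
    total = community.total
    if total == 0:
        raise ValueError("no specimens")
    sensitive = 0
    for label, count in community.counts.items():
        if label not in community.traits:
            warnings.warn(
                f"{community.site_id}: no sensitivity flag for {label!r}; "
                "counted non-sensitive",
                stacklevel=2,
            )
            continue
        if community.traits[label][1]:
            sensitive += count
    pct = 100.0 * sensitive / total
    return LakeResult(pct_sensitive=pct, quality_class=classify_percent_sensitive(pct))


def classify_percent_sensitive(pct: float) -> QualityClass:
    if not 0.0 <= pct <= 100.0:
        raise ValueError("invalid index")
    if pct > 50:
        return QualityClass.very_good
    if pct > 20:
        return QualityClass.good
    if pct > 10:
        return QualityClass.medium
    if pct > 5:
        return QualityClass.poor
    return QualityClass.bad


def score_site(community: SiteCommunity) -> IobsResult | LakeResult:
    """Habitat-appropriate index for one site."""
    if community.habitat == "stream":
        return compute_iobs(community)
    return percent_sensitive(community)


def pct_by_group(community: SiteCommunity) -> dict[str, float]:
    """Family/subfamily-group percentages of a community (for concordance)."""
    total = community.total
    out: dict[str, int] = {}
    for label, count in community.counts.items():
        group, _ = community.traits.get(label, (None, False))
        key = group or "ungrouped"
        out[key] = out.get(key, 0) + count
    return {g: 100.0 * c / total for g, c in out.items()}
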