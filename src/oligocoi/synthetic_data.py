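"""Ground-truth simulator for the single-specimen barcoding study.

Generates everything the pipeline consumes — a COI reference database whose
pairwise divergences straddle the assignment thresholds, site communities
along a pollution gradient (tolerant tubificids at degraded sites, sensitive
naidids/lumbriculids/enchytraeids at clean ones), per-specimen tagged
paired-end read bundles with substitution errors and PCR chimeras, and a
morphological "observer" that merges cryptic species and demotes part of the
specimens to family level — with full per-read and per-specimen truth, so
every downstream stage can be tested against known answers.

The observation model per specimen: read depth ~ Poisson(mean) with a floor
of one pair; substitutions i.i.d. per base with Phred qualities drawn from a
two-tier (high/low) mixture whose expected error equals the configured rate;
a configured fraction of pairs are two-parent chimeras spliced at a uniform
breakpoint. Indels are not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assigner import k2p_distance
from .indices import SiteCommunity
from .readproc import ReadPair, TagScheme, reverse_complement, write_fastq
from .refdb import GROUP_CLADE, ReferenceDatabase, ReferenceRecord, ThresholdPolicy

BASES = np.array(list("ACGT"))
#: transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: genus used for each trait group, and whether the group is on the lake
#: sensitivity list (tubificids tolerant; the other families sensitive).
GROUP_SCHEME = [
    ("tubificinae_nohair", "Limnodrilus", False),
    ("tubificinae_hair", "Tubifex", False),
    ("naidinae", "Nais", True),
    ("enchytraeidae", "Cognettia", True),
    ("lumbriculidae", "Stylodrilus", True),
    ("pristininae", "Pristina", True),
]


@dataclass(frozen=True)
class SimulationConfig:
    n_sites: int = 20
    specimens_per_site: int = 33
    reads_per_specimen: float = 50.0
    per_base_error: float = 0.001
    chimera_rate: float = 0.01
    indel_rate: float = 0.0  # reserved; substitution-only model by default
    dropout_rate: float = 0.0
    tag_length: int = 8
    amplicon_length: int = 313
    read_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.per_base_error, self.chimera_rate, self.indel_rate, self.dropout_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class CommunityProfile:
    profile_name: str
    lineage_weights: dict[str, float]
    habitat: str  # stream | lake

    def __post_init__(self) -> None:
        if not self.lineage_weights or sum(self.lineage_weights.values()) <= 0:
            raise ValueError("empty community")
        if any(w < 0 for w in self.lineage_weights.values()):
            raise ValueError("negative weight")


@dataclass
class SimulatedTruth:
    site_id: str
    habitat: str
    specimens: list[tuple[str, str]]  # (specimen_id, lineage_id)
    amplicons: dict[str, str]  # specimen_id -> true amplicon sequence

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, lineage in self.specimens:
            out[lineage] = out.get(lineage, 0) + 1
        return out

    def true_community(self, db: ReferenceDatabase, source: str = "genetic") -> SiteCommunity:
        from .refdb import resolve_traits

        counts = self.counts
        return SiteCommunity(
            site_id=self.site_id,
            habitat=self.habitat,
            source=source,
            counts=counts,
            traits=resolve_traits(db, counts),
        )


# --- reference lineages -------------------------------------------------------


def _mutate(seq: str, n_subs: int, rng: np.random.Generator, transitions_only: bool = False) -> str:
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for pos in positions:
        if transitions_only:
            out[pos] = _TRANSITION[out[pos]]
        else:
            choices = [b for b in "ACGT" if b != out[pos]]
            out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_reference_lineages(
    n_lineages: int,
    min_sep: float = 0.15,
    cryptic_pairs: int = 0,
    cryptic_distance: float = 0.12,
    seed: int = 0,
    amplicon_length: int = 313,
    policy: ThresholdPolicy | None = None,
) -> ReferenceDatabase:
    """Reference database of ``n_lineages`` barcodes with controlled divergences.

    All pairwise K2P distances exceed ``min_sep``, except that each of the
    first ``cryptic_pairs`` lineages gets a *cryptic partner* at roughly
    ``cryptic_distance`` (transitions only) sharing its morphological taxon
    name — a barcode-distinguishable species pair a morphologist lumps.
    Traits follow a fixed scheme: groups cycle through the six
    family/subfamily groups, tubificids are non-sensitive, the rest
    sensitive.
    """
    policy = policy or ThresholdPolicy()
    max_threshold = max(policy.default_threshold, *policy.genus_overrides.values())
    if not max_threshold < min_sep < 0.5:
        raise ValueError("min_sep must lie between the largest threshold and 0.5")
    if n_lineages < 2:
        raise ValueError("need at least 2 lineages")
    if cryptic_pairs > n_lineages:
        raise ValueError("more cryptic pairs than lineages")
    if cryptic_pairs > 0 and cryptic_distance <= max_threshold:
        # partners must be distinct species, i.e. above the assignment threshold
        raise ValueError("cryptic_distance must exceed the assignment threshold")

    rng = np.random.default_rng(seed)
    length = amplicon_length
    root = "".join(rng.choice(BASES, size=length))
    # per-lineage mutation count targeting pairwise p-distance comfortably
    # above what min_sep requires (rejection loop enforces the guarantee)
    pd_needed = 0.75 * (1.0 - math.exp(-min_sep / 0.75))
    per_lineage = int(math.ceil(length * min(0.45, 1.5 * pd_needed)))

    templates: list[str] = []
    for _ in range(n_lineages):
        for _attempt in range(300):
            cand = _mutate(root, per_lineage, rng)
            if all(k2p_distance(cand, t).k2p > min_sep for t in templates):
                templates.append(cand)
                break
        else:
            raise ValueError("cannot satisfy min_sep")

    records: list[ReferenceRecord] = []
    for idx, template in enumerate(templates):
        group, genus, sensitive = GROUP_SCHEME[idx % len(GROUP_SCHEME)]
        records.append(
            ReferenceRecord(
                lineage_id=f"L{idx + 1:03d}",
                taxon_name=f"{genus} sp{idx + 1}",
                rank="species",
                genus=genus,
                group=group,
                sensitive=sensitive,
                sequence=template,
            )
        )

    # cryptic partners: transitions-only mutants of the first lineages
    p_target = 0.5 * (1.0 - math.exp(-2.0 * cryptic_distance))
    n_subs = max(1, round(p_target * length))
    for k in range(cryptic_pairs):
        origin = records[k]
        partner_seq = _mutate(origin.sequence, n_subs, rng, transitions_only=True)
        records.append(
            ReferenceRecord(
                lineage_id=f"L{len(records) + 1:03d}",
                taxon_name=origin.taxon_name,  # shared morphological name
                rank=origin.rank,
                genus=origin.genus,
                group=origin.group,
                sensitive=origin.sensitive,
                sequence=partner_seq,
            )
        )
    return ReferenceDatabase(records=records, policy=policy)


# --- communities --------------------------------------------------------------


def gradient_profiles(
    db: ReferenceDatabase,
    n_stream: int = 13,
    n_lake: int = 7,
    seed: int = 0,
) -> list[CommunityProfile]:
    """Site community profiles along a pollution gradient.

    Each site gets a degradation level g in [0, 1]; tolerant (tubificid)
    lineages receive weight proportional to g, sensitive taxa to 1 - g, with
    lognormal heterogeneity so communities differ between sites.
    """
    rng = np.random.default_rng(seed)
    profiles: list[CommunityProfile] = []
    specs = [("stream", i, n_stream) for i in range(n_stream)] + [
        ("lake", i, n_lake) for i in range(n_lake)
    ]
    for habitat, i, n_total in specs:
        g = (i + 0.5) / n_total
        weights: dict[str, float] = {}
        for rec in db:
            base = g if not rec.sensitive else 1.0 - g
            weights[rec.lineage_id] = max(base, 0.02) * float(rng.lognormal(0.0, 0.6))
        profiles.append(
            CommunityProfile(
                profile_name=f"{habitat[:2].upper()}{i + 1:02d}",
                lineage_weights=weights,
                habitat=habitat,
            )
        )
    return profiles


def simulate_site_community(
    profile: CommunityProfile, n_specimens: int, seed: int, db: ReferenceDatabase | None = None
) -> SimulatedTruth:
    """Draw specimen lineages i.i.d. from the profile's normalized weights.

    Specimens are drawn sequentially, so a 66-specimen draw at a given seed
    contains the 33-specimen draw at the same seed as its first half
    (nested subsampling).
    """
    if n_specimens < 1:
        raise ValueError("need at least one specimen")
    rng = np.random.default_rng(seed)
    lineages = sorted(profile.lineage_weights)
    weights = np.array([profile.lineage_weights[l] for l in lineages], dtype=float)
    probs = weights / weights.sum()
    specimens: list[tuple[str, str]] = []
    amplicons: dict[str, str] = {}
    seq_of = {r.lineage_id: r.sequence for r in db} if db is not None else {}
    for i in range(n_specimens):
        lineage = lineages[int(rng.choice(len(lineages), p=probs))]
        sid = f"{profile.profile_name}_SP{i + 1:03d}"
        specimens.append((sid, lineage))
        if seq_of:
            amplicons[sid] = seq_of[lineage]
    return SimulatedTruth(
        site_id=profile.profile_name,
        habitat=profile.habitat,
        specimens=specimens,
        amplicons=amplicons,
    )


# --- tag schemes --------------------------------------------------------------


def _random_tags(n: int, rng: np.random.Generator, length: int = 8, min_dist: int = 3) -> list[str]:
    tags: list[str] = []
    for _ in range(10000):
        cand = "".join(rng.choice(BASES, size=length))
        if all(sum(a != b for a, b in zip(cand, t)) >= min_dist for t in tags):
            tags.append(cand)
            if len(tags) == n:
                return tags
    raise ValueError("cannot generate enough well-separated tags")


def make_tag_scheme(site_id: str, specimen_ids: Sequence[str], seed: int) -> TagScheme:
    """Latin-square style tagging: each 8-mer is reused across specimens but
    every (forward, reverse) combination is unique; tags are pairwise
    >= 3 mismatches apart so a single tag error cannot hit another tag."""
    rng = np.random.default_rng(seed)
    k = int(math.ceil(math.sqrt(len(specimen_ids))))
    tags = _random_tags(2 * k, rng)
    fwd_tags, rev_tags = tags[:k], tags[k:]
    entries = {
        sid: (fwd_tags[i % k], rev_tags[i // k]) for i, sid in enumerate(specimen_ids)
    }
    return TagScheme(site_id=site_id, entries=entries)


# --- reads --------------------------------------------------------------------


def _quality_tiers(per_base_error: float) -> tuple[float, int, float, int, float]:
    """(w_low, q_low, e_low, q_high, e_high) such that the expected per-base
    error of the mixture equals per_base_error."""
    e_high = 1e-4
    if per_base_error <= e_high:
        q = 40 if per_base_error == 0 else min(40, round(-10 * math.log10(per_base_error)))
        return 0.0, q, per_base_error, q, per_base_error
    e_low = 0.01 if per_base_error <= 0.01 else per_base_error
    w_low = (per_base_error - e_high) / (e_low - e_high)
    q_low = round(-10 * math.log10(e_low))
    return w_low, q_low, e_low, 40, e_high


def generate_reads(
    truth: SimulatedTruth,
    scheme: TagScheme,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Tagged paired-end reads for one site, plus read-level truth.

    Forward read: fwd_tag + fwd_primer + amplicon prefix; reverse read:
    rev_tag + rev_primer + reverse-complemented amplicon prefix; both
    truncated to the read length. Chimeric pairs splice the focal amplicon
    with a second specimen's amplicon at a uniform breakpoint but keep the
    focal specimen's tags (chimeras form during PCR, inside one reaction).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    missing = [sid for sid, _ in truth.specimens if sid not in scheme.entries]
    if missing:
        raise ValueError(f"untagged specimen: {missing[0]}")
    w_low, q_low, e_low, q_high, e_high = _quality_tiers(config.per_base_error)
    pairs: list[ReadPair] = []
    truth_rows: list[dict] = []
    counter = 0
    sids = [sid for sid, _ in truth.specimens]
    for sid, lineage in truth.specimens:
        if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
            continue
        depth = max(1, int(rng.poisson(config.reads_per_specimen)))
        fwd_tag, rev_tag = scheme.entries[sid]
        for _ in range(depth):
            counter += 1
            rid = f"{truth.site_id}_R{counter:06d}"
            amplicon = truth.amplicons[sid]
            is_chimera = False
            parent = ""
            if config.chimera_rate > 0 and rng.random() < config.chimera_rate and len(sids) > 1:
                others = [s for s in sids if truth.amplicons[s] != amplicon]
                if others:
                    parent = others[int(rng.integers(0, len(others)))]
                    bp = int(rng.integers(1, len(amplicon)))
                    amplicon = amplicon[:bp] + truth.amplicons[parent][bp:]
                    is_chimera = True
            fwd = (fwd_tag + scheme.fwd_primer + amplicon)[: config.read_length]
            rev = (rev_tag + scheme.rev_primer + reverse_complement(amplicon))[
                : config.read_length
            ]
            fseq, fq = _apply_errors(fwd, rng, w_low, q_low, e_low, q_high, e_high)
            rseq, rq = _apply_errors(rev, rng, w_low, q_low, e_low, q_high, e_high)
            pairs.append(
                ReadPair(
                    read_id=rid,
                    forward_seq=fseq,
                    forward_qual=fq,
                    reverse_seq=rseq,
                    reverse_qual=rq,
                )
            )
            truth_rows.append(
                {
                    "read_id": rid,
                    "specimen_id": sid,
                    "lineage_id": lineage,
                    "is_chimera": is_chimera,
                    "chimera_parent": parent,
                }
            )
    return pairs, pd.DataFrame(
        truth_rows,
        columns=["read_id", "specimen_id", "lineage_id", "is_chimera", "chimera_parent"],
    )


def _apply_errors(
    seq: str,
    rng: np.random.Generator,
    w_low: float,
    q_low: int,
    e_low: float,
    q_high: int,
    e_high: float,
) -> tuple[str, list[int]]:
    n = len(seq)
    low = rng.random(n) < w_low if w_low > 0 else np.zeros(n, dtype=bool)
    quals = np.where(low, q_low, q_high)
    err_p = np.where(low, e_low, e_high)
    if e_high == 0.0 and e_low == 0.0:
        return seq, [int(q) for q in quals]
    errors = rng.random(n) < err_p
    if not errors.any():
        return seq, [int(q) for q in quals]
    out = list(seq)
    for pos in np.flatnonzero(errors):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out), [int(q) for q in quals]


def write_site_fastq(
    pairs: Sequence[ReadPair], out_dir: str | Path, site_id: str
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r1 = out_dir / f"{site_id}_R1.fastq"
    r2 = out_dir / f"{site_id}_R2.fastq"
    write_fastq(r1, ((p.read_id, p.forward_seq, p.forward_qual) for p in pairs))
    write_fastq(r2, ((p.read_id, p.reverse_seq, p.reverse_qual) for p in pairs))
    return r1, r2


# --- morphological observer ---------------------------------------------------


def coarsen_to_morphology(
    truth: SimulatedTruth,
    db: ReferenceDatabase,
    unresolved_rate: float = 0.0,
    seed: int = 0,
) -> SiteCommunity:
    """What a morphologist reports for the same specimens.

    Cryptic-pair members collapse onto their shared taxon name; a fraction
    ``unresolved_rate`` of specimens is demoted to a family/subfamily-level
    label ("<Family> g. sp.") that keeps the hair-setae group (visible on
    immatures) but loses species-level sensitivity information. Specimen
    counts are conserved.
    """
    if not 0.0 <= unresolved_rate <= 1.0:
        raise ValueError("unresolved_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_id = {r.lineage_id: r for r in db}
    counts: dict[str, int] = {}
    traits: dict[str, tuple[str | None, bool]] = {}
    for sid, lineage in truth.specimens:
        rec = by_id[lineage]
        if unresolved_rate > 0 and rng.random() < unresolved_rate:
            if rec.group.startswith("tubificinae"):
                suffix = "with hair setae" if rec.group == "tubificinae_hair" else "without hair setae"
                label = f"Tubificinae {suffix} g. sp."
            else:
                label = f"{GROUP_CLADE[rec.group]} g. sp."
            traits[label] = (rec.group, False)
        else:
            label = rec.taxon_name
            traits.setdefault(label, (rec.group, rec.sensitive))
        counts[label] = counts.get(label, 0) + 1
    return SiteCommunity(
        site_id=truth.site_id,
        habitat=truth.habitat,
        source="morphological",
        counts=counts,
        traits=traits,
    )
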