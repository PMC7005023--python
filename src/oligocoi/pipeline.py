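"""End-to-end orchestration: simulate -> demux -> assign -> indices -> compare.

A study run is fully reproducible from one master seed: per-site, per-stage
seeds are derived by hashing ``master_seed:site:stage``, so sites are
independent and any execution order yields identical results. Every output
table carries the configuration hash and master seed in a comment line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import readproc
from .assigner import (
    SpecimenAssignment,
    assign_lineage,
    cluster_new_lineages,
    cluster_otus,
    dereplicate,
    dominant_otu,
    place_new_lineage,
    remove_chimeras,
)
from .concordance import (
    AgreementResult,
    PairedMetric,
    RegressionResult,
    class_agreement,
    linear_regression,
    log_linearize,
)
from .indices import IobsResult, LakeResult, SiteCommunity, score_site
from .refdb import ReferenceDatabase, resolve_traits
from .synthetic_data import (
    CommunityProfile,
    SimulationConfig,
    coarsen_to_morphology,
    generate_reads,
    gradient_profiles,
    make_tag_scheme,
    simulate_site_community,
)


def derive_seed(master_seed: int, *parts: str) -> int:
    """Stable per-site/per-stage seed below 2^31 from the master seed."""
    digest = hashlib.sha256(":".join([str(master_seed), *parts]).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_mean_q: float = 30.0
    min_overlap: int = 20
    max_overlap_mismatch_frac: float = 0.1
    min_reads: int = 10
    otu_identity: float = 0.97
    bootstrap_replicates: int = 1000
    place_new_lineages: bool = False
    unresolved_rate: float = 0.10
    master_seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SiteReport:
    site_id: str
    habitat: str
    n_pairs: int
    n_quality_filtered: int
    n_demux_assigned: int
    n_demux_rejected: int
    n_specimens: int
    n_failed: int
    assignments: list[SpecimenAssignment]
    genetic_community: SiteCommunity
    genetic_index: IobsResult | LakeResult
    morph_community: SiteCommunity
    morph_index: IobsResult | LakeResult
    true_community: SiteCommunity
    true_index: IobsResult | LakeResult
    placements: dict[str, str] = field(default_factory=dict)

    @property
    def success_rate(self) -> float:
        if self.n_specimens == 0:
            return 0.0
        return (self.n_specimens - self.n_failed) / self.n_specimens


def barcode_from_reads(
    reads: Sequence[readproc.ReadPair], specimen_id: str, config: PipelineConfig
) -> str | None:
    """Distill one specimen's trimmed read pairs into a barcode (or None)."""
    merged, _dropped = readproc.merge_pairs(
        reads,
        specimen_id=specimen_id,
        min_overlap=config.min_overlap,
        max_overlap_mismatch_frac=config.max_overlap_mismatch_frac,
    )
    uniques = dereplicate(m.sequence for m in merged)
    retained = remove_chimeras(uniques)
    otus = cluster_otus(retained, identity=config.otu_identity, specimen_id=specimen_id)
    return dominant_otu(otus, min_reads=config.min_reads)


def run_site(
    db: ReferenceDatabase,
    profile: CommunityProfile,
    config: PipelineConfig,
    secondary: ReferenceDatabase | None = None,
    n_specimens: int | None = None,
) -> SiteReport:
    """Run the full pipeline for one site from its community profile."""
    site = profile.profile_name
    n_spec = n_specimens or config.sim.specimens_per_site
    truth = simulate_site_community(
        profile, n_spec, seed=derive_seed(config.master_seed, site, "community"), db=db
    )
    scheme = make_tag_scheme(
        site, [sid for sid, _ in truth.specimens], seed=derive_seed(config.master_seed, site, "tags")
    )
    pairs, _read_truth = generate_reads(
        truth, scheme, config.sim, seed=derive_seed(config.master_seed, site, "reads")
    )
    kept = [p for p in pairs if readproc.quality_filter(p, config.min_mean_q)]
    demux = readproc.demultiplex(kept, scheme)

    assignments: list[SpecimenAssignment] = []
    n_failed = 0
    for sid in sorted(scheme.entries):
        barcode = barcode_from_reads(demux.assigned.get(sid, []), sid, config)
        if barcode is None:
            n_failed += 1
            continue
        assignments.append(assign_lineage(barcode, db, secondary=secondary, specimen_id=sid))

    unassigned = [a for a in assignments if a.route == "unassigned"]
    placements: dict[str, str] = {}
    if unassigned:
        relabelled = {a.specimen_id: a for a in cluster_new_lineages(unassigned, db, label_prefix=f"{site}_NEW")}
        assignments = [relabelled.get(a.specimen_id, a) for a in assignments]
        if config.place_new_lineages:
            for label in sorted({a.lineage_id for a in relabelled.values() if a.lineage_id}):
                rep = min(a.barcode for a in relabelled.values() if a.lineage_id == label)
                placements[label] = place_new_lineage(
                    rep,
                    db,
                    n_replicates=config.bootstrap_replicates,
                    seed=derive_seed(config.master_seed, site, "placement", label),
                )

    counts: dict[str, int] = {}
    for a in assignments:
        label = a.lineage_id or "unassigned"
        counts[label] = counts.get(label, 0) + 1
    genetic = SiteCommunity(
        site_id=site,
        habitat=profile.habitat,
        source="genetic",
        counts=counts,
        traits=resolve_traits(db, counts),
    )
    morph = coarsen_to_morphology(
        truth, db, unresolved_rate=config.unresolved_rate,
        seed=derive_seed(config.master_seed, site, "morph"),
    )
    true_comm = truth.true_community(db)
    return SiteReport(
        site_id=site,
        habitat=profile.habitat,
        n_pairs=len(pairs),
        n_quality_filtered=len(pairs) - len(kept),
        n_demux_assigned=demux.n_assigned,
        n_demux_rejected=demux.rejected,
        n_specimens=len(truth.specimens),
        n_failed=n_failed,
        assignments=assignments,
        genetic_community=genetic,
        genetic_index=score_site(genetic),
        morph_community=morph,
        morph_index=score_site(morph),
        true_community=true_comm,
        true_index=score_site(true_comm),
        placements=placements,
    )


@dataclass
class StudyResult:
    reports: list[SiteReport]
    summary: pd.DataFrame
    regressions: pd.DataFrame
    agreement: AgreementResult


def _index_value(result: IobsResult | LakeResult) -> float | None:
    if isinstance(result, IobsResult):
        return result.iobs
    return result.pct_sensitive


def concordance_tables(reports: Sequence[SiteReport]) -> tuple[pd.DataFrame, AgreementResult]:
    """Regressions (genetic y vs morphological x) and class agreement."""
    rows = []
    stream_pairs = [
        PairedMetric(r.site_id, _index_value(r.morph_index), _index_value(r.genetic_index), "iobs")
        for r in reports
        if r.habitat == "stream" and _index_value(r.morph_index) is not None
        and _index_value(r.genetic_index) is not None
    ]
    lake_pairs = [
        PairedMetric(r.site_id, _index_value(r.morph_index), _index_value(r.genetic_index), "pct_sensitive")
        for r in reports
        if r.habitat == "lake"
    ]
    for name, pairs, transform in (
        ("iobs_log", stream_pairs, True),
        ("pct_sensitive", lake_pairs, False),
    ):
        if transform:
            pairs = log_linearize(pairs)
        if len(pairs) >= 3:
            rows.append({"metric": name, **_reg_row(linear_regression(pairs))})
    from .indices import pct_by_group

    groups = sorted({g for r in reports for g in pct_by_group(r.morph_community)} - {"ungrouped"})
    for group in groups:
        pairs = [
            PairedMetric(
                r.site_id,
                pct_by_group(r.morph_community).get(group, 0.0),
                pct_by_group(r.genetic_community).get(group, 0.0),
                f"pct_group:{group}",
            )
            for r in reports
        ]
        xs = {p.x for p in pairs}
        if len(pairs) >= 3 and len(xs) > 1:
            rows.append({"metric": f"pct_group:{group}", **_reg_row(linear_regression(pairs))})
    regressions = pd.DataFrame(rows, columns=["metric", "n", "slope", "intercept", "r_squared", "pearson_p"])
    agreement = class_agreement(
        {r.site_id: r.morph_index.quality_class for r in reports},
        {r.site_id: r.genetic_index.quality_class for r in reports},
    )
    return regressions, agreement


def _reg_row(reg: RegressionResult) -> dict:
    return {
        "n": reg.n,
        "slope": reg.slope,
        "intercept": reg.intercept,
        "r_squared": reg.r_squared,
        "pearson_p": reg.pearson_p,
    }


def run_study(
    db: ReferenceDatabase,
    config: PipelineConfig,
    profiles: Sequence[CommunityProfile] | None = None,
    secondary: ReferenceDatabase | None = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Run every site, then the morphology-vs-genetics concordance layer.

    With no explicit profiles, a 13-stream + 7-lake gradient design is
    simulated (seeded from the master seed).
    """
    if profiles is None:
        profiles = gradient_profiles(db, seed=derive_seed(config.master_seed, "profiles"))
    reports = [run_site(db, profile, config, secondary=secondary) for profile in profiles]
    summary = pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "habitat": r.habitat,
                "n_specimens": r.n_specimens,
                "n_failed": r.n_failed,
                "success_rate": r.success_rate,
                "S_genetic": len(r.genetic_community.counts),
                "S_morph": len(r.morph_community.counts),
                "index_genetic": _index_value(r.genetic_index),
                "index_morph": _index_value(r.morph_index),
                "index_true": _index_value(r.true_index),
                "class_genetic": _class_name(r.genetic_index),
                "class_morph": _class_name(r.morph_index),
                "class_true": _class_name(r.true_index),
            }
            for r in reports
        ]
    )
    regressions, agreement = concordance_tables(reports)
    result = StudyResult(reports=reports, summary=summary, regressions=regressions, agreement=agreement)
    if out_dir is not None:
        write_study(result, db, config, out_dir)
    return result


def _class_name(result: IobsResult | LakeResult) -> str:
    cls = result.quality_class
    return cls.name if cls is not None else "undefined"


def write_study(
    result: StudyResult, db: ReferenceDatabase, config: PipelineConfig, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# config={config.config_hash()} master_seed={config.master_seed}\n"

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    _write(result.summary, "summary.tsv")
    _write(result.regressions, "regressions.tsv")
    _write(result.agreement.per_site, "class_agreement.tsv")
    assignment_rows = [
        {
            "site_id": r.site_id,
            "specimen_id": a.specimen_id,
            "lineage_id": a.lineage_id or "",
            "distance": "" if a.distance is None else f"{a.distance:.6f}",
            "route": a.route,
        }
        for r in result.reports
        for a in r.assignments
    ]
    _write(pd.DataFrame(assignment_rows), "assignments.tsv")
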