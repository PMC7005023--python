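"""Front half of the pipeline: quality filtering, exact-tag demultiplexing,
paired-end merging.

Each specimen was amplified with primers carrying a unique combination of
8-nt tags at the 5' ends, so a read pair identifies its specimen through the
(forward tag, reverse tag) combination. The filters mirror the study design:

* a pair is kept only if both mates have mean Phred quality >= 30 (inclusive)
  and contain no ambiguous base;
* a pair is demultiplexed only on an exact, zero-mismatch match of
  tag+primer on both mates — any mismatch in the tagged primer rejects the
  pair (no tag-error correction);
* kept pairs are merged into one amplicon sequence by a quality-weighted
  ungapped overlap consensus.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Concrete disambiguations of the degenerate metazoan COI primer pair
#: (mlCOIintF / jgHCO2198) used as simulator + demultiplexer defaults.
DEFAULT_FWD_PRIMER = "GGAACAGGATGAACAGTATATCCTCC"
DEFAULT_REV_PRIMER = "TAAACCTCAGGGTGACCGAAGAACCA"

TAG_LENGTH = 8

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPair:
    read_id: str
    forward_seq: str
    forward_qual: Sequence[int]
    reverse_seq: str
    reverse_qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.forward_seq) != len(self.forward_qual) or len(
            self.reverse_seq
        ) != len(self.reverse_qual):
            raise ValueError(f"malformed read: {self.read_id}")


@dataclass
class TagScheme:
    """Bijection specimen <-> (forward tag, reverse tag) within one site library."""

    site_id: str
    entries: dict[str, tuple[str, str]]
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER

    def __post_init__(self) -> None:
        combos: set[tuple[str, str]] = set()
        for specimen, (fwd, rev) in self.entries.items():
            if len(fwd) != TAG_LENGTH or len(rev) != TAG_LENGTH:
                raise ValueError(f"ambiguous scheme: tag of {specimen} is not 8 nt")
            if (fwd, rev) in combos:
                raise ValueError(f"ambiguous scheme: duplicate combination {fwd}/{rev}")
            combos.add((fwd, rev))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"specimen_id": s, "fwd_tag": f, "rev_tag": r}
                for s, (f, r) in self.entries.items()
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        site_id: str,
        fwd_primer: str = DEFAULT_FWD_PRIMER,
        rev_primer: str = DEFAULT_REV_PRIMER,
    ) -> "TagScheme":
        table = pd.read_csv(path, sep="\t", dtype=str)
        entries = {
            row.specimen_id: (row.fwd_tag, row.rev_tag)
            for row in table.itertuples(index=False)
        }
        return cls(site_id=site_id, entries=entries, fwd_primer=fwd_primer, rev_primer=rev_primer)


@dataclass
class MergedRead:
    specimen_id: str
    sequence: str
    quality: list[int]
    overlap_length: int
    overlap_mismatches: int


@dataclass
class DemuxResult:
    assigned: dict[str, list[ReadPair]]
    rejected: int

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    def report_frame(self, site_id: str) -> pd.DataFrame:
        rows = [
            {"site_id": site_id, "specimen_id": s, "n_pairs": len(v)}
            for s, v in sorted(self.assigned.items())
        ]
        rows.append(
            {"site_id": site_id, "specimen_id": "<rejected>", "n_pairs": self.rejected}
        )
        return pd.DataFrame(rows)


def quality_filter(pair: ReadPair, min_mean_q: float = 30.0) -> bool:
    """Keep a pair iff both mates have mean quality >= ``min_mean_q`` and no N.

    The threshold is inclusive: a mate at mean quality exactly 30.0 passes.
    """
    if "N" in pair.forward_seq or "N" in pair.reverse_seq:
        return False
    if float(np.mean(pair.forward_qual)) < min_mean_q:
        return False
    if float(np.mean(pair.reverse_qual)) < min_mean_q:
        return False
    return True


def demultiplex(pairs: Iterable[ReadPair], scheme: TagScheme) -> DemuxResult:
    """Assign read pairs to specimens by exact tag+primer prefixes.

    A pair goes to specimen *s* iff the forward read starts with
    ``fwd_tag(s) + fwd_primer`` AND the reverse read starts with
    ``rev_tag(s) + rev_primer``, with zero mismatches. Tag and primer bases
    are trimmed from assigned reads; everything else is rejected (counted).
    """
    lookup: dict[tuple[str, str], str] = {}
    for specimen, (fwd, rev) in scheme.entries.items():
        key = (fwd + scheme.fwd_primer, rev + scheme.rev_primer)
        if key in lookup:
            raise ValueError("ambiguous scheme: duplicate tag+primer combination")
        lookup[key] = specimen

    fwd_len = TAG_LENGTH + len(scheme.fwd_primer)
    rev_len = TAG_LENGTH + len(scheme.rev_primer)
    assigned: dict[str, list[ReadPair]] = {s: [] for s in scheme.entries}
    rejected = 0
    for pair in pairs:
        key = (pair.forward_seq[:fwd_len], pair.reverse_seq[:rev_len])
        specimen = lookup.get(key)
        if specimen is None:
            rejected += 1
            continue
        assigned[specimen].append(
            ReadPair(
                read_id=pair.read_id,
                forward_seq=pair.forward_seq[fwd_len:],
                forward_qual=list(pair.forward_qual[fwd_len:]),
                reverse_seq=pair.reverse_seq[rev_len:],
                reverse_qual=list(pair.reverse_qual[rev_len:]),
            )
        )
    return DemuxResult(assigned=assigned, rejected=rejected)


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Merge one trimmed pair into a single amplicon sequence, or None.

    The reverse mate is reverse-complemented; candidate ungapped overlaps of
    length >= ``min_overlap`` are scored by a quality-weighted sum
    (+min(q_f, q_r) per agreeing position, -min per disagreeing); the best
    acceptable overlap (mismatch fraction <= ``max_overlap_mismatch_frac``)
    wins, longest overlap breaking score ties. Disagreements are resolved in
    favour of the higher-quality base; merged quality is the max of the two.
    """
    fwd = np.frombuffer(pair.forward_seq.encode(), dtype=np.uint8)
    fq = np.asarray(pair.forward_qual, dtype=np.int32)
    rseq = reverse_complement(pair.reverse_seq)
    rev = np.frombuffer(rseq.encode(), dtype=np.uint8)
    rq = np.asarray(pair.reverse_qual, dtype=np.int32)[::-1]

    best = None  # (score, overlap, mismatches)
    max_olap = min(len(fwd), len(rev))
    for olap in range(max_olap, min_overlap - 1, -1):
        f_seg = fwd[-olap:]
        r_seg = rev[:olap]
        match = f_seg == r_seg
        mism = int(olap - match.sum())
        if mism > max_overlap_mismatch_frac * olap:
            continue
        weights = np.minimum(fq[-olap:], rq[:olap])
        score = int(weights[match].sum()) - int(weights[~match].sum())
        if best is None or score > best[0]:
            best = (score, olap, mism)
    if best is None:
        return None

    _, olap, mism = best
    f_seg = fwd[-olap:]
    r_seg = rev[:olap]
    take_rev = rq[:olap] > fq[-olap:]
    consensus = np.where(take_rev, r_seg, f_seg)
    cons_q = np.maximum(fq[-olap:], rq[:olap])
    merged_seq = (
        pair.forward_seq[: len(fwd) - olap]
        + consensus.tobytes().decode()
        + rseq[olap:]
    )
    merged_q = list(fq[: len(fwd) - olap]) + list(cons_q) + list(rq[olap:])
    return MergedRead(
        specimen_id="",
        sequence=merged_seq,
        quality=[int(q) for q in merged_q],
        overlap_length=olap,
        overlap_mismatches=mism,
    )


def merge_pairs(
    reads: Sequence[ReadPair],
    specimen_id: str = "",
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.1,
) -> tuple[list[MergedRead], int]:
    """Merge a specimen's read pairs; returns (merged reads, dropped count)."""
    merged: list[MergedRead] = []
    dropped = 0
    for pair in reads:
        result = merge_pair(pair, min_overlap, max_overlap_mismatch_frac)
        if result is None:
            dropped += 1
            continue
        result.specimen_id = specimen_id
        merged.append(result)
    return merged, dropped


# --- FASTQ IO (Phred+33 only) -------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files (Phred+33)."""
    with _open_text(r1) as fh1, _open_text(r2) as fh2:
        while True:
            block1 = [fh1.readline() for _ in range(4)]
            block2 = [fh2.readline() for _ in range(4)]
            if not block1[0] and not block2[0]:
                return
            if not block1[0] or not block2[0]:
                raise ValueError("FASTQ pair files of unequal length")
            rid = block1[0].strip().lstrip("@").split()[0]
            yield ReadPair(
                read_id=rid,
                forward_seq=block1[1].strip(),
                forward_qual=_decode_quals(block1[3].strip()),
                reverse_seq=block2[1].strip(),
                reverse_qual=_decode_quals(block2[3].strip()),
            )


def _decode_quals(qual: str) -> list[int]:
    scores = [ord(c) - 33 for c in qual]
    if any(q < 0 or q > 60 for q in scores):
        raise ValueError("quality string outside Phred+33 range")
    return scores


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, Sequence[int]]]) -> None:
    """Write (read_id, sequence, qualities) records as Phred+33 FASTQ."""
    with _open_text(path, "wt") as fh:
        for rid, seq, quals in records:
            fh.write(f"@{rid}\n{seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals) + "\n")
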