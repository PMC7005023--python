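"""Per-specimen barcode determination and lineage assignment.

From a specimen's merged reads one barcode sequence is distilled
(dereplication -> de-novo chimera removal -> greedy 97% OTU clustering ->
dominant OTU) and assigned to a reference lineage when its Kimura
2-parameter (K2P) distance to the nearest reference falls below that
reference's threshold (default 10%, 8% in *Nais*/*Uncinais*). Barcodes that
match neither the local nor an optional secondary database are clustered
into new lineages under the same conspecificity rule, and can be placed to
the family/subfamily level on a bootstrapped neighbour-joining tree.

K2P distance between two aligned sequences with transition proportion P and
transversion proportion Q:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Distances where the argument of a logarithm is non-positive are *saturated*
and treated as larger than any threshold.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .refdb import ReferenceDatabase, ReferenceRecord, threshold_for

MIN_COMPARED_SITES = 100

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PURINE = (0, 2)  # A, G


def encode_seq(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)


# --- barcode distillation -----------------------------------------------------


@dataclass(frozen=True)
class Otu:
    representative: str
    member_count: int
    specimen_id: str = ""


def dereplicate(sequences: Iterable[str]) -> list[tuple[str, int]]:
    """Collapse exact duplicates; sort by descending count, then sequence."""
    counts = Counter(sequences)
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def remove_chimeras(uniques: Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    """De-novo two-parent chimera test on an abundance-sorted unique list.

    A query is chimeric if some split point divides it into a left segment
    within 1 mismatch of the prefix of a >=2x-more-abundant sequence A and a
    right segment within 1 mismatch of the suffix of a different
    >=2x-more-abundant sequence B, while the full query differs from both
    putative parents by >=3 mismatches. Flagged sequences are dropped;
    retained counts are unchanged.
    """
    if not uniques:
        return []
    seqs = [s for s, _ in uniques]
    counts = [c for _, c in uniques]
    arrays = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    keep: list[tuple[str, int]] = []
    for qi, (qseq, qcount) in enumerate(uniques):
        query = arrays[qi]
        length = len(query)
        # candidate parents: same length, >= 2x abundance, >= 3 mismatches away
        cands: list[tuple[int, np.ndarray]] = []
        for pi in range(len(uniques)):
            if pi == qi or counts[pi] < 2 * qcount or len(arrays[pi]) != length:
                continue
            mism = np.cumsum(arrays[pi] != query)
            if mism[-1] < 3:
                continue
            cands.append((pi, mism))
        chimeric = False
        if len(cands) >= 2:
            # prefix of A usable up to max split where mismatches <= 1;
            # suffix of B usable from min split where remaining mismatches <= 1
            max_prefix = {pi: int(np.searchsorted(m, 2)) for pi, m in cands}
            min_suffix = {
                pi: int(np.searchsorted(m, m[-1] - 1)) + 1 for pi, m in cands
            }
            for pi_b, _ in cands:
                lo = min_suffix[pi_b]
                if lo <= 0:
                    lo = 1
                # need a different parent A with max_prefix >= lo and split in [1, L-1]
                for pi_a, _ in cands:
                    if pi_a == pi_b:
                        continue
                    hi = min(max_prefix[pi_a], length - 1)
                    if lo <= hi:
                        chimeric = True
                        break
                if chimeric:
                    break
        if not chimeric:
            keep.append((qseq, qcount))
    return keep


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return float((a[:n] == b[:n]).sum()) / n


def cluster_otus(
    seqs: Sequence[tuple[str, int]],
    identity: float = 0.97,
    specimen_id: str = "",
) -> list[Otu]:
    """Greedy abundance-ordered centroid clustering at the given identity.

    Each sequence (in descending-abundance order) joins the first centroid
    with pairwise identity >= the threshold (matches / compared sites over
    the end-trimmed common length), otherwise it founds a new centroid.
    """
    centroids: list[np.ndarray] = []
    otu_counts: list[int] = []
    reps: list[str] = []
    for seq, count in seqs:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        placed = False
        for k, cent in enumerate(centroids):
            if _identity(arr, cent) >= identity:
                otu_counts[k] += count
                placed = True
                break
        if not placed:
            centroids.append(arr)
            otu_counts.append(count)
            reps.append(seq)
    return [
        Otu(representative=rep, member_count=cnt, specimen_id=specimen_id)
        for rep, cnt in zip(reps, otu_counts)
    ]


def dominant_otu(otus: Sequence[Otu], min_reads: int = 10) -> str | None:
    """Barcode of the highest-count OTU passing ``min_reads``; None = failed.

    Ties on count break to the lexicographically smallest representative.
    """
    passing = [o for o in otus if o.member_count >= min_reads]
    if not passing:
        return None
    best = min(passing, key=lambda o: (-o.member_count, o.representative))
    return best.representative


# --- K2P distance -------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseDistance:
    p_transitions: float
    q_transversions: float
    k2p: float
    compared_sites: int

    @property
    def saturated(self) -> bool:
        return math.isinf(self.k2p)


class InsufficientOverlap(ValueError):
    pass


def _best_offset(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """End-free trim of unequal-length sequences: slide the shorter along the
    longer and keep the offset with the most matches."""
    if len(a) == len(b):
        return a, b
    short, long_, swapped = (a, b, False) if len(a) < len(b) else (b, a, True)
    n = len(short)
    best_off, best_matches = 0, -1
    for off in range(len(long_) - n + 1):
        matches = int((short == long_[off : off + n]).sum())
        if matches > best_matches:
            best_off, best_matches = off, matches
    window = long_[best_off : best_off + n]
    return (short, window) if not swapped else (window, short)


def k2p_distance(
    a: str | np.ndarray,
    b: str | np.ndarray,
    min_sites: int = MIN_COMPARED_SITES,
) -> PairwiseDistance:
    """Kimura 2-parameter distance between two barcodes.

    Unequal lengths are end-trimmed to the best ungapped offset; positions
    where either sequence has N are excluded. Saturated pairs (log argument
    <= 0) return ``k2p = inf``.
    """
    arr_a = encode_seq(a) if isinstance(a, str) else a
    arr_b = encode_seq(b) if isinstance(b, str) else b
    arr_a, arr_b = _best_offset(arr_a, arr_b)
    valid = (arr_a != _CODE["N"]) & (arr_b != _CODE["N"])
    n = int(valid.sum())
    if n < min_sites:
        raise InsufficientOverlap(f"insufficient overlap: {n} < {min_sites} sites")
    x, y = arr_a[valid], arr_b[valid]
    diff = x != y
    transitions = diff & (np.isin(x, _PURINE) == np.isin(y, _PURINE))
    p = float(transitions.sum()) / n
    q = float(diff.sum() - transitions.sum()) / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0.0 or arg2 <= 0.0:
        d = math.inf  # distance saturated
    else:
        d = -0.5 * math.log(arg1 * math.sqrt(arg2)) + 0.0  # avoid -0.0
    return PairwiseDistance(p_transitions=p, q_transversions=q, k2p=d, compared_sites=n)


def k2p_matrix(
    seqs: Sequence[str], min_sites: int = MIN_COMPARED_SITES, saturated_value: float = 5.0
) -> np.ndarray:
    """Symmetric K2P matrix; saturated pairs get ``saturated_value``."""
    n = len(seqs)
    arrays = [encode_seq(s) for s in seqs]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(arrays[i], arrays[j], min_sites=min_sites).k2p
            out[i, j] = out[j, i] = d if math.isfinite(d) else saturated_value
    return out


# --- lineage assignment -------------------------------------------------------


@dataclass
class SpecimenAssignment:
    specimen_id: str
    barcode: str
    lineage_id: str | None
    distance: float | None
    route: str  # local_db | secondary_db | tree_placement | morphology | unassigned
    placement_support: float | None = None


def _nearest_record(
    barcode: str, db: ReferenceDatabase
) -> tuple[ReferenceRecord | None, float]:
    arr = encode_seq(barcode)
    best: list[tuple[float, ReferenceRecord]] = []
    for rec in db:
        try:
            d = k2p_distance(arr, encode_seq(rec.sequence)).k2p
        except InsufficientOverlap:
            continue
        best.append((d, rec))
    if not best:
        return None, math.inf
    dmin = min(d for d, _ in best)
    ties = [rec for d, rec in best if d == dmin]
    # prefer a record whose threshold admits the match, then smallest id
    admitting = [rec for rec in ties if dmin < threshold_for(db, rec)]
    pool = admitting or ties
    return min(pool, key=lambda r: r.lineage_id), dmin


def assign_lineage(
    barcode: str,
    db: ReferenceDatabase,
    secondary: ReferenceDatabase | None = None,
    specimen_id: str = "",
) -> SpecimenAssignment:
    """Assign a barcode to its nearest reference if within threshold.

    The local database is consulted first; unassigned barcodes fall through
    to the secondary database (the stand-in for a public-repository search)
    when one is provided; otherwise the specimen is returned unassigned.
    """
    for route, database in (("local_db", db), ("secondary_db", secondary)):
        if database is None or len(database) == 0:
            continue
        rec, dist = _nearest_record(barcode, database)
        if rec is not None and dist < threshold_for(database, rec):
            return SpecimenAssignment(
                specimen_id=specimen_id,
                barcode=barcode,
                lineage_id=rec.lineage_id,
                distance=dist,
                route=route,
            )
    return SpecimenAssignment(
        specimen_id=specimen_id,
        barcode=barcode,
        lineage_id=None,
        distance=None,
        route="unassigned",
    )


def cluster_new_lineages(
    unassigned: Sequence[SpecimenAssignment],
    db: ReferenceDatabase,
    label_prefix: str = "NEW",
) -> list[SpecimenAssignment]:
    """Single-linkage cluster unassigned barcodes into labelled new lineages.

    Two barcodes are conspecific when their K2P distance is below the
    database's default threshold. Clusters are numbered in order of their
    first member after sorting specimens by id, so labels are stable.
    """
    if any(a.route != "unassigned" for a in unassigned):
        raise ValueError("cluster_new_lineages expects only unassigned specimens")
    items = sorted(unassigned, key=lambda a: a.specimen_id)
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    threshold = db.policy.default_threshold
    arrays = [encode_seq(a.barcode) for a in items]
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = k2p_distance(arrays[i], arrays[j]).k2p
            except InsufficientOverlap:
                continue
            if d < threshold:
                parent[find(i)] = find(j)

    label_of_root: dict[int, str] = {}
    out: list[SpecimenAssignment] = []
    for i, item in enumerate(items):
        root = find(i)
        if root not in label_of_root:
            label_of_root[root] = f"{label_prefix}_{len(label_of_root) + 1:02d}"
        out.append(
            SpecimenAssignment(
                specimen_id=item.specimen_id,
                barcode=item.barcode,
                lineage_id=label_of_root[root],
                distance=item.distance,
                route="unassigned",
            )
        )
    return out


def apply_morphology_overrides(
    assignments: Sequence[SpecimenAssignment], overrides: Mapping[str, str]
) -> list[SpecimenAssignment]:
    """Merge manual morphological identifications (specimen -> taxon) made on
    the specimens' preserved anterior parts; overridden specimens get
    route="morphology"."""
    out: list[SpecimenAssignment] = []
    for a in assignments:
        if a.specimen_id in overrides:
            out.append(
                SpecimenAssignment(
                    specimen_id=a.specimen_id,
                    barcode=a.barcode,
                    lineage_id=overrides[a.specimen_id],
                    distance=None,
                    route="morphology",
                )
            )
        else:
            out.append(a)
    return out


# --- neighbour joining --------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an unrooted NJ tree (the root is the final trifurcation)."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(
            f"{child._newick(with_support)}:{length:.6f}"
            for child, length in self.children
        )
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.3f}"
        return f"({inner}){label}"

    def bipartitions(self) -> dict[frozenset[str], "TreeNode"]:
        """Internal-edge bipartitions, keyed by the leafset below the edge."""
        all_leaves = frozenset(self.leaves())
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name or ""])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node is not self and 1 < len(below) < len(all_leaves) - 1:
                out[below] = node
            return below

        walk(self)
        return out


def nj_tree(dist_matrix: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Neighbour joining (Q-criterion, Studier-Keppler branch lengths).

    Returns the unrooted tree as a trifurcating root node. Ties in the
    Q-criterion break deterministically on the smallest leaf label carried
    by each active node.
    """
    d = np.asarray(dist_matrix, dtype=float)
    n = len(labels)
    if d.shape != (n, n) or n < 3:
        raise ValueError("invalid distance matrix")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("invalid distance matrix")

    nodes = [TreeNode(name=str(lbl)) for lbl in labels]
    reps = [str(lbl) for lbl in labels]  # smallest leaf label per active node
    d = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        pairs = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        ai, aj = min(
            ((int(i), int(j)) for i, j in pairs if i < j),
            key=lambda ij: tuple(sorted((reps[active[ij[0]]], reps[active[ij[1]]]))),
        )
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        # distances from the new node to the remaining actives
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # three-point closed form for the central node
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])


def _pair_classes(arrays: Sequence[np.ndarray]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per column, classify each sequence pair: 0 same, 1 transition,
    2 transversion, 3 excluded (N)."""
    n = len(arrays)
    length = len(arrays[0])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    cls = np.zeros((len(pairs), length), dtype=np.uint8)
    for idx, (i, j) in enumerate(pairs):
        a, b = arrays[i], arrays[j]
        diff = a != b
        same_class = np.isin(a, _PURINE) == np.isin(b, _PURINE)
        cls[idx] = np.where(diff & same_class, 1, np.where(diff, 2, 0))
        cls[idx][(a == _CODE["N"]) | (b == _CODE["N"])] = 3
    return cls, pairs


def _matrix_from_classes(
    cls: np.ndarray, pairs: list[tuple[int, int]], n: int, saturated_value: float
) -> np.ndarray:
    valid = (cls != 3).sum(axis=1).astype(float)
    p = (cls == 1).sum(axis=1) / valid
    q = (cls == 2).sum(axis=1) / valid
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(
            (arg1 > 0) & (arg2 > 0),
            -0.5 * np.log(np.clip(arg1, 1e-300, None) * np.sqrt(np.clip(arg2, 1e-300, None))),
            saturated_value,
        )
    out = np.zeros((n, n))
    for (i, j), val in zip(pairs, d):
        out[i, j] = out[j, i] = val
    return out


def nj_with_bootstrap(
    seqs: Mapping[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    saturated_value: float = 5.0,
) -> TreeNode:
    """NJ tree from aligned sequences with column-bootstrap edge supports.

    Alignment columns are resampled with replacement ``n_replicates`` times
    (default 1,000); each internal edge of the tree built from the full
    alignment is annotated with the fraction of replicate trees containing
    its bipartition.
    """
    labels = sorted(seqs)
    arrays = [encode_seq(seqs[lbl]) for lbl in labels]
    length = len(arrays[0])
    if any(len(a) != length for a in arrays):
        raise ValueError("sequences must be aligned to equal length")
    cls, pairs = _pair_classes(arrays)
    base = nj_tree(_matrix_from_classes(cls, pairs, len(labels), saturated_value), labels)
    biparts = base.bipartitions()
    if not biparts:
        return base
    counts = {key: 0 for key in biparts}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, length, size=length)
        rep_tree = nj_tree(
            _matrix_from_classes(cls[:, idx], pairs, len(labels), saturated_value),
            labels,
        )
        rep_parts = set(rep_tree.bipartitions())
        for key in counts:
            if key in rep_parts:
                counts[key] += 1
    for key, node in biparts.items():
        node.support = counts[key] / n_replicates
    return base


def place_new_lineage(
    new_barcode: str,
    db: ReferenceDatabase,
    support_min: float = 0.70,
    n_replicates: int = 1000,
    seed: int = 0,
) -> str:
    """Family/subfamily placement of an unassignable barcode via NJ.

    Builds a bootstrapped NJ tree over all references plus the query and
    returns the family/subfamily of the smallest monophyletic reference
    group containing the query whose subtending edge reaches
    ``support_min`` bootstrap support, else ``"incertae sedis"``.
    """
    if len(db) < 3 or len({r.family for r in db}) < 2:
        raise ValueError("reference database too small for tree placement")
    query_label = "\x00QUERY"  # sorts first, cannot collide with lineage ids
    seqs = {r.lineage_id: r.sequence for r in db}
    seqs[query_label] = new_barcode
    tree = nj_with_bootstrap(seqs, n_replicates=n_replicates, seed=seed)
    family_of = {r.lineage_id: r.family for r in db}
    best: tuple[int, str] | None = None
    for leafset, node in tree.bipartitions().items():
        for side in (leafset, frozenset(seqs) - leafset):
            if query_label not in side:
                continue
            refs = side - {query_label}
            if not refs:
                continue
            families = {family_of[r] for r in refs}
            if len(families) != 1 or (node.support or 0.0) < support_min:
                continue
            size = len(refs)
            if best is None or size < best[0]:
                best = (size, next(iter(families)))
    return best[1] if best else "incertae sedis"
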