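"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (pure-python
counting, exhaustive enumeration, normal equations) and never calls the
package code paths it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

PURINES = {"A", "G"}


def k2p_brute_force(a: str, b: str) -> float:
    """Closed-form K2P by direct per-site counting (equal-length sequences)."""
    assert len(a) == len(b)
    n = transitions = transversions = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    p, q = transitions / n, transversions / n
    arg1, arg2 = 1 - 2 * p - q, 1 - 2 * q
    if arg1 <= 0 or arg2 <= 0:
        return math.inf
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


# --- unrooted tree topologies -------------------------------------------------
# A topology is a list of edges over nodes; leaves are strings, internal nodes
# negative ints.


def enumerate_topologies(labels: list[str]) -> list[list[tuple]]:
    """All unrooted binary topologies over the labels (3 -> 1, 4 -> 3,
    5 -> 15, 6 -> 105)."""
    first = [(labels[0], -1), (labels[1], -1), (labels[2], -1)]
    topologies = [first]
    for k in range(3, len(labels)):
        leaf = labels[k]
        grown = []
        for topo in topologies:
            next_internal = min(v for e in topo for v in e if isinstance(v, int)) - 1
            for i, (u, v) in enumerate(topo):
                new = [e for j, e in enumerate(topo) if j != i]
                w = next_internal
                new += [(u, w), (v, w), (leaf, w)]
                grown.append(new)
        topologies = grown
    return topologies


def _paths(topo: list[tuple], labels: list[str]) -> dict[tuple[str, str], list[int]]:
    """Leaf-pair -> list of edge indices on the connecting path."""
    adj: dict = {}
    for idx, (u, v) in enumerate(topo):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path(src, dst):
        stack = [(src, None, [])]
        seen = {src}
        while stack:
            node, _, edges = stack.pop()
            if node == dst:
                return edges
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, edges + [eidx]))
        raise AssertionError("disconnected topology")

    return {
        (a, b): path(a, b) for a, b in itertools.combinations(labels, 2)
    }


def topology_rss(topo: list[tuple], labels: list[str], dist: np.ndarray) -> float:
    """Least-squares residual of fitting branch lengths to the distances."""
    pairs = list(itertools.combinations(range(len(labels)), 2))
    design = np.zeros((len(pairs), len(topo)))
    target = np.zeros(len(pairs))
    paths = _paths(topo, labels)
    for row, (i, j) in enumerate(pairs):
        for eidx in paths[(labels[i], labels[j])]:
            design[row, eidx] = 1.0
        target[row] = dist[i, j]
    fit, *_ = np.linalg.lstsq(design, target, rcond=None)
    return float(((design @ fit - target) ** 2).sum())


def best_topology(labels: list[str], dist: np.ndarray) -> list[tuple]:
    """Exhaustive-search topology with minimal least-squares residual."""
    return min(enumerate_topologies(labels), key=lambda t: topology_rss(t, labels, dist))


def topology_bipartitions(topo: list[tuple], labels: list[str]) -> set[frozenset[str]]:
    """Normalized internal-edge bipartitions (side not holding labels[0])."""
    adj: dict = {}
    for u, v in topo:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = set()
    for u, v in topo:
        if isinstance(u, str) or isinstance(v, str):
            continue
        # leaves reachable from v without crossing u
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.add(node)
                continue
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if labels[0] in side:
            side = set(labels) - side
        if 1 < len(side) < len(labels) - 1:
            out.add(frozenset(side))
    return out


def random_additive_tree(
    labels: list[str], rng: np.random.Generator, low: float = 0.05, high: float = 1.0
) -> tuple[list[tuple], np.ndarray]:
    """Random unrooted binary topology + the additive distance matrix it implies."""
    order = list(labels)
    rng.shuffle(order)
    topos = enumerate_topologies(order)
    topo = topos[int(rng.integers(0, len(topos)))]
    lengths = rng.uniform(low, high, size=len(topo))
    paths = _paths(topo, labels)
    n = len(labels)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = sum(lengths[e] for e in paths[(labels[i], labels[j])])
        dist[i, j] = dist[j, i] = d
    return topo, dist


def nj_bipartitions(tree, labels: list[str]) -> set[frozenset[str]]:
    """Normalized bipartition set of an oligocoi TreeNode."""
    out = set()
    for side in tree.bipartitions():
        part = set(side)
        if labels[0] in part:
            part = set(labels) - part
        out.add(frozenset(part))
    return out


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(slope, intercept, r_squared, two-sided p) via normal equations and the
    t-distribution, independent of scipy.stats.linregress."""
    from scipy.stats import t as t_dist

    n = len(x)
    design = np.column_stack([x, np.ones(n)])
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    r = math.copysign(math.sqrt(r2), slope)
    if r2 >= 1.0:
        return slope, intercept, r2, 0.0
    t_stat = r * math.sqrt((n - 2) / (1 - r2))
    p = 2.0 * float(t_dist.sf(abs(t_stat), n - 2))
    return slope, intercept, r2, p
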