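"""Split networks from distance matrices: NeighborNet, a neighbor-joining
oracle, and Nexus SPLITS output.

NeighborNet generalises neighbor joining: instead of a tree it returns a
circular ordering of the taxa plus a weighted system of splits, every one
of which is contiguous in that ordering. The implementation follows the
standard agglomerative scheme:

1. repeatedly select a pair of clusters with the net-divergence-corrected
   criterion (the NJ Q-criterion lifted to cluster-average distances),
   then a pair of linkable nodes within them;
2. whenever a cluster accumulates three consecutive active nodes, reduce
   them to two with the 2/3–1/3 distance blend, remembering the reduction;
3. when one cluster remains, expand the reductions in reverse to obtain
   the circular ordering;
4. estimate split weights by non-negative least squares of the input
   distances on the full circular split system, dropping weights below a
   small epsilon.

On an exactly additive (tree) metric the recovered splits are the tree's
branches with their lengths; on a circular-decomposable metric the
reconstructed pairwise distances reproduce the input exactly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.optimize

from .diff_stats import DistanceMatrix

logger = logging.getLogger(__name__)

EPSILON_WEIGHT = 1e-8


@dataclass
class SplitNetwork:
    """Weighted circular split system over a fixed taxon list.

    Each split is stored as the frozenset of taxon indices on the side not
    containing ``circular_order[0]``, with its non-negative weight.
    """

    taxa: list[str]
    circular_order: list[int]
    splits: list[tuple[frozenset[int], float]]

    def split_sides(self) -> set[frozenset[str]]:
        """Splits as frozensets of taxon labels (smaller side by labels)."""
        out = set()
        for side, _w in self.splits:
            labels = frozenset(self.taxa[i] for i in side)
            comp = frozenset(set(self.taxa) - labels)
            out.add(min(labels, comp, key=lambda s: (len(s), tuple(sorted(s)))))
        return out

    def weight_of(self, labels: frozenset[str]) -> float:
        comp = frozenset(set(self.taxa) - labels)
        for side, w in self.splits:
            side_labels = frozenset(self.taxa[i] for i in side)
            if side_labels in (labels, comp):
                return w
        return 0.0

    def total_weight(self) -> float:
        return float(sum(w for _s, w in self.splits))

    def distances(self) -> np.ndarray:
        """Pairwise distances induced by the splits (sum of separating weights)."""
        n = len(self.taxa)
        d = np.zeros((n, n))
        for side, w in self.splits:
            mask = np.zeros(n, dtype=bool)
            mask[list(side)] = True
            sep = mask[:, None] != mask[None, :]
            d += w * sep
        return d


@dataclass
class PhyloTree:
    """Unrooted tree as a weighted split system plus a Newick string."""

    taxa: list[str]
    splits: list[tuple[frozenset[int], float]]
    newick: str

    def split_sides(self) -> set[frozenset[str]]:
        out = set()
        full = set(self.taxa)
        for side, _w in self.splits:
            labels = frozenset(self.taxa[i] for i in side)
            comp = frozenset(full - labels)
            out.add(min(labels, comp, key=lambda s: (len(s), tuple(sorted(s)))))
        return out

    def total_length(self) -> float:
        return float(sum(w for _s, w in self.splits))

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.newick + "\n")


def select_panel(gm, locus_ids: list[str]):
    """Restrict a GenotypeMatrix to an explicit SNP panel (e.g. the shared
    most-significant loci feeding the validation network)."""
    if not locus_ids:
        raise ValueError("empty SNP panel")
    sub = gm.subset_loci(locus_ids)
    logger.info("select_panel: %d loci selected", sub.n_loci)
    return sub


# ---------------------------------------------------------------------------
# NeighborNet agglomeration
# ---------------------------------------------------------------------------


class _NNState:
    def __init__(self, d: np.ndarray, labels: list[str]):
        n = d.shape[0]
        self.d: dict[int, dict[int, float]] = {
            i: {j: float(d[i, j]) for j in range(n) if j != i} for i in range(n)
        }
        # lexicographic tie-break key per node: smallest taxon label reachable
        self.key: dict[int, str] = {i: labels[i] for i in range(n)}
        self.clusters: list[list[int]] = [[i] for i in range(n)]
        self.next_id = n
        self.expansions: list[tuple[int, int, int, int, int]] = []  # (u,v,x,y,z)

    def dist(self, a: int, b: int) -> float:
        return self.d[a][b]

    def cluster_dist(self, ca: list[int], cb: list[int]) -> float:
        return float(np.mean([[self.d[a][b] for b in cb] for a in ca]))

    def new_node(self, key: str) -> int:
        i = self.next_id
        self.next_id += 1
        self.d[i] = {}
        self.key[i] = key
        return i

    def reduce3(self, x: int, y: int, z: int) -> tuple[int, int]:
        """Replace consecutive nodes x-y-z by u-v (2/3–1/3 blend)."""
        u = self.new_node(min(self.key[x], self.key[y]))
        v = self.new_node(min(self.key[y], self.key[z]))
        others = [s for s in self.d if s not in (x, y, z, u, v)]
        for s in others:
            du = (2 / 3) * self.d[x][s] + (1 / 3) * self.d[y][s]
            dv = (1 / 3) * self.d[y][s] + (2 / 3) * self.d[z][s]
            self.d[u][s] = du
            self.d[s][u] = du
            self.d[v][s] = dv
            self.d[s][v] = dv
        duv = (self.d[x][y] + self.d[y][z] + self.d[x][z]) / 3.0
        self.d[u][v] = duv
        self.d[v][u] = duv
        for dead in (x, y, z):
            del self.d[dead]
            for s in self.d:
                self.d[s].pop(dead, None)
        self.expansions.append((u, v, x, y, z))
        return u, v


def _circular_order(d: np.ndarray, labels: list[str]) -> list[int]:
    n = d.shape[0]
    if n <= 3:
        return list(range(n))
    st = _NNState(d, labels)

    while len(st.clusters) >= 2:
        m = len(st.clusters)
        # 1. cluster pair by the Q criterion on cluster-average distances
        if m == 2:
            ai, bi = 0, 1
        else:
            cd = np.zeros((m, m))
            for i, j in itertools.combinations(range(m), 2):
                cd[i, j] = cd[j, i] = st.cluster_dist(st.clusters[i], st.clusters[j])
            r = cd.sum(axis=1)
            best = None
            for i, j in itertools.combinations(range(m), 2):
                q = (m - 2) * cd[i, j] - r[i] - r[j]
                key = (
                    q,
                    min(st.key[st.clusters[i][0]], st.key[st.clusters[j][0]]),
                    max(st.key[st.clusters[i][0]], st.key[st.clusters[j][0]]),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
            ai, bi = best[1], best[2]

        ca, cb = st.clusters[ai], st.clusters[bi]

        # 2. linkable node pair: endpoints of the two paths, scored with the
        # Q criterion where the members of the chosen clusters count as
        # singletons and the remaining clusters by their averages
        other_clusters = [c for k, c in enumerate(st.clusters) if k not in (ai, bi)]
        members = ca + cb
        m_hat = len(other_clusters) + len(members)

        def r_node(x: int) -> float:
            tot = sum(st.cluster_dist([x], c) for c in other_clusters)
            tot += sum(st.dist(x, z) for z in members if z != x)
            return tot

        best_pair = None
        for x in ca:
            for y in cb:
                q = (m_hat - 2) * st.dist(x, y) - r_node(x) - r_node(y)
                key = (q, min(st.key[x], st.key[y]), max(st.key[x], st.key[y]))
                if best_pair is None or key < best_pair[0]:
                    best_pair = (key, x, y)
        _, x, y = best_pair

        # 3. splice the two paths together at (x, y) and reduce to <= 2 nodes
        path_a = ca if ca[-1] == x else ca[::-1]
        path_b = cb if cb[0] == y else cb[::-1]
        path = path_a + path_b
        while len(path) > 2:
            u, v = st.reduce3(path[0], path[1], path[2])
            path = [u, v] + path[3:]
        new_clusters = [c for k, c in enumerate(st.clusters) if k not in (ai, bi)]
        new_clusters.append(path)
        st.clusters = new_clusters

    # 4. expand reductions in reverse to recover the circular order
    cycle = list(st.clusters[0])
    for u, v, x, y, z in reversed(st.expansions):
        k = len(cycle)
        for i in range(k):
            a, b = cycle[i], cycle[(i + 1) % k]
            if (a, b) == (u, v):
                repl = [x, y, z]
            elif (a, b) == (v, u):
                repl = [z, y, x]
            else:
                continue
            if i + 1 < k:
                cycle = cycle[:i] + repl + cycle[i + 2 :]
            else:  # pair wraps around the end
                cycle = repl[1:] + cycle[1:i] + [repl[0]]
            break
        else:
            raise AssertionError("expansion nodes not adjacent in cycle")
    assert sorted(cycle) == list(range(n))
    return cycle


def _circular_splits(order: list[int]) -> list[frozenset[int]]:
    """All n(n-1)/2 splits contiguous in the ordering, each listed once as
    the arc not containing ``order[0]``."""
    n = len(order)
    return [
        frozenset(order[i:j])
        for i in range(1, n)
        for j in range(i + 1, n + 1)
    ]


def neighbor_net(dm: DistanceMatrix, epsilon: float = EPSILON_WEIGHT) -> SplitNetwork:
    """NeighborNet split network from a distance matrix.

    For fewer than 4 taxa there is no non-trivial circular structure; the
    network falls back to the exact split decomposition (three-point
    formulas for n=3, half the distance for n=2) with a warning.
    """
    n = len(dm.labels)
    d = dm.d
    if n < 2:
        raise ValueError("neighbor_net needs at least 2 taxa")
    if n < 4:
        logger.warning("neighbor_net: %d taxa < 4; returning trivial split decomposition", n)
        order = list(range(n))
        splits: list[tuple[frozenset[int], float]] = []
        if n == 2:
            w = d[0, 1] / 2.0
            splits = [(frozenset({0}), w), (frozenset({1}), w)]
        else:
            for i, j, k in ((0, 1, 2), (1, 0, 2), (2, 0, 1)):
                w = (d[i, j] + d[i, k] - d[j, k]) / 2.0
                splits.append((frozenset({i}), max(0.0, w)))
        splits = [(s, w) for s, w in splits if w > epsilon]
        return SplitNetwork(taxa=list(dm.labels), circular_order=order, splits=splits)

    order = _circular_order(d, list(dm.labels))
    candidates = _circular_splits(order)

    pairs = list(itertools.combinations(range(n), 2))
    a = np.zeros((len(pairs), len(candidates)))
    for si, side in enumerate(candidates):
        for pi, (p, q) in enumerate(pairs):
            if (p in side) != (q in side):
                a[pi, si] = 1.0
    y = np.array([d[p, q] for p, q in pairs])
    weights, _res = scipy.optimize.nnls(a, y)

    splits = [
        (side, float(w))
        for side, w in zip(candidates, weights)
        if w > epsilon
    ]
    return SplitNetwork(taxa=list(dm.labels), circular_order=order, splits=splits)


# ---------------------------------------------------------------------------
# Neighbor joining (tree oracle)
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining; exact on additive metrics.

    Used as the tree-shaped oracle next to :func:`neighbor_net`: on
    near-additive inputs the network's split set should contain the NJ
    tree's splits. Negative branch lengths arising from noise are clamped
    to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor_joining needs at least 3 taxa")
    d = {i: {j: float(dm.d[i, j]) for j in range(n) if j != i} for i in range(n)}
    leafset: dict[int, frozenset[int]] = {i: frozenset({i}) for i in range(n)}
    news: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    key: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    splits: list[tuple[frozenset[int], float]] = []
    nxt = n
    active = list(range(n))

    def record(side: frozenset[int], length: float) -> None:
        splits.append((side, max(0.0, length)))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[i][j] - r[i] - r[j]
            k2 = (q, min(key[i], key[j]), max(key[i], key[j]))
            if best is None or k2 < best[0]:
                best = (k2, i, j)
        _, i, j = best
        li = d[i][j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i][j] - li
        record(leafset[i], li)
        record(leafset[j], lj)
        u = nxt
        nxt += 1
        d[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = (d[i][k] + d[j][k] - d[i][j]) / 2.0
            d[u][k] = duk
            d[k][u] = duk
        leafset[u] = leafset[i] | leafset[j]
        news[u] = f"({news[i]}:{max(0.0, li):.10g},{news[j]}:{max(0.0, lj):.10g})"
        key[u] = min(key[i], key[j])
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = (d[a][b] + d[a][c] - d[b][c]) / 2.0
    lb = (d[a][b] + d[b][c] - d[a][c]) / 2.0
    lc = (d[a][c] + d[b][c] - d[a][b]) / 2.0
    for node, length in ((a, la), (b, lb), (c, lc)):
        record(leafset[node], length)
    newick = (
        f"({news[a]}:{max(0.0, la):.10g},{news[b]}:{max(0.0, lb):.10g},"
        f"{news[c]}:{max(0.0, lc):.10g});"
    )
    # drop zero-weight duplicate of the same side (degenerate inputs)
    return PhyloTree(taxa=list(dm.labels), splits=splits, newick=newick)


# ---------------------------------------------------------------------------
# Nexus SPLITS I/O
# ---------------------------------------------------------------------------


def write_nexus(net: SplitNetwork, path: str | Path) -> None:
    """Nexus file with TAXA and SPLITS blocks (CYCLE plus weighted splits),
    readable by standard split-network viewers. Output ordering is
    deterministic: splits sorted by (size, sorted indices)."""
    n = len(net.taxa)
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"  DIMENSIONS NTAX={n};", "  TAXLABELS"]
    lines += [f"    '{t}'" for t in net.taxa]
    lines += ["  ;", "END;", "", "BEGIN SPLITS;"]
    lines.append(f"  DIMENSIONS NTAX={n} NSPLITS={len(net.splits)};")
    lines.append("  FORMAT LABELS=NO WEIGHTS=YES;")
    cycle = " ".join(str(i + 1) for i in net.circular_order)
    lines.append(f"  CYCLE {cycle};")
    lines.append("  MATRIX")
    ordered = sorted(net.splits, key=lambda sw: (len(sw[0]), sorted(sw[0])))
    for idx, (side, w) in enumerate(ordered, start=1):
        members = " ".join(str(i + 1) for i in sorted(side))
        lines.append(f"    [{idx}] {w:.17g} {members},")
    lines += ["  ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus_splits(path: str | Path) -> SplitNetwork:
    """Read back a SPLITS Nexus file written by :func:`write_nexus`."""
    text = Path(path).read_text()
    lines = [l.strip() for l in text.splitlines()]
    taxa: list[str] = []
    order: list[int] = []
    splits: list[tuple[frozenset[int], float]] = []
    mode = None
    for line in lines:
        upper = line.upper()
        if upper.startswith("TAXLABELS"):
            mode = "taxa"
            continue
        if upper.startswith("CYCLE"):
            body = line[5:].strip().rstrip(";")
            order = [int(x) - 1 for x in body.split()]
            continue
        if upper.startswith("MATRIX"):
            mode = "matrix"
            continue
        if line == ";" or upper.startswith("END"):
            mode = None
            continue
        if mode == "taxa" and line:
            taxa.append(line.strip("'"))
        elif mode == "matrix" and line:
            body = line.rstrip(",")
            if body.startswith("["):
                body = body[body.index("]") + 1 :].strip()
            parts = body.split()
            w = float(parts[0])
            side = frozenset(int(x) - 1 for x in parts[1:])
            splits.append((side, w))
    return SplitNetwork(taxa=taxa, circular_order=order, splits=splits)
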