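"""Median-joining haplotype networks built from first principles.

The construction follows Bandelt's recipe: start from the epsilon-relaxed
minimum spanning network (MSN) over the observed haplotypes — the union of
all minimum spanning trees, plus any link whose length is within ``epsilon``
of the threshold at which its endpoints' components join — then repeatedly
propose *quasi-medians* of connected node triples (site-wise majority state;
where a site shows three states, every combination) and accept a median
vector whenever it strictly reduces the cost of spanning the current node
set.  Finally, median vectors that no longer participate in any minimum-cost
connection of the observed haplotypes are pruned and the links re-derived.

Distances are raw Hamming mismatch counts on the analysed sites; no
transition/transversion weighting is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from odobenus.diversity import HaplotypeTable
from odobenus.io import DataError


@dataclass
class MJNetwork:
    """Final network: observed haplotypes plus retained median vectors."""

    graph: nx.Graph
    epsilon: int

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "haplotype"]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]


# ---------------------------------------------------------------------------
# distances


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise DataError("sequences of unequal analysed length")
    return sum(1 for x, y in zip(a, b) if x != y)


def hamming_matrix(ht: HaplotypeTable) -> tuple[list[str], np.ndarray]:
    """Pairwise mismatch counts between haplotypes on analysed sites."""
    ids = [hid for hid, _ in ht.haplotypes]
    seqs = [seq for _, seq in ht.haplotypes]
    if len(ids) < 2:
        raise DataError("need >= 2 haplotypes")
    n = len(ids)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming(seqs[i], seqs[j])
    return ids, d


def _mst_cost(seqs: list[str]) -> int:
    """Prim's algorithm over the complete Hamming graph; total tree cost."""
    n = len(seqs)
    if n <= 1:
        return 0
    in_tree = [False] * n
    best = [len(seqs[0]) + 1] * n
    best[0] = 0
    cost = 0
    for _ in range(n):
        u = min((i for i in range(n) if not in_tree[i]), key=lambda i: best[i])
        in_tree[u] = True
        cost += best[u]
        for v in range(n):
            if not in_tree[v]:
                d = hamming(seqs[u], seqs[v])
                if d < best[v]:
                    best[v] = d
    return cost


# ---------------------------------------------------------------------------
# minimum spanning network


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_msn(
    dist: np.ndarray, labels: list[str] | None = None, epsilon: int = 0
) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network from a distance matrix.

    An edge (u, v) is admitted iff d(u, v) <= sigma(u, v) + epsilon, where
    sigma(u, v) is the smallest threshold at which u and v fall in one
    single-linkage component.  epsilon = 0 gives the union of all minimum
    spanning trees (the classic MSN).
    """
    dist = np.asarray(dist)
    if dist.size == 0:
        raise DataError("empty distance matrix")
    n = dist.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if epsilon < 0:
        raise DataError("epsilon must be non-negative")
    g = nx.Graph()
    g.add_nodes_from(labels)
    if n == 1:
        return g
    pairs = sorted(
        ((int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    # single-linkage join thresholds
    uf = _UnionFind(range(n))
    sigma = np.zeros((n, n), dtype=int)
    comp_members = {i: {i} for i in range(n)}
    for d, i, j in pairs:
        ri, rj = uf.find(i), uf.find(j)
        if ri != rj:
            for a in comp_members[ri]:
                for b in comp_members[rj]:
                    sigma[a, b] = sigma[b, a] = d
            uf.union(ri, rj)
            root = uf.find(ri)
            merged = comp_members.pop(ri) | comp_members.pop(rj)
            comp_members[root] = merged
    for d, i, j in pairs:
        if d <= sigma[i, j] + epsilon:
            g.add_edge(labels[i], labels[j], weight=d)
    return g


# ---------------------------------------------------------------------------
# quasi-medians


def quasi_medians(a: str, b: str, c: str, cap: int = 1000) -> list[str]:
    """Site-wise majority consensus of three sequences.

    Sites where all three states differ contribute every choice, so the
    result is a (capped) cartesian product of per-site state sets.
    """
    choices: list[tuple[str, ...]] = []
    total = 1
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            choices.append((x,))
        elif y == z:
            choices.append((y,))
        else:
            choices.append((x, y, z))
            total *= 3
            if total > cap:
                raise DataError(f"quasi-median candidates exceed cap {cap}")
    return ["".join(combo) for combo in itertools.product(*choices)]


def add_median_vectors(
    sequences: dict[str, str],
    epsilon: int = 0,
    max_medians: int = 1000,
) -> dict[str, str]:
    """Iteratively add cost-reducing median vectors until a fixpoint.

    ``sequences`` maps node id -> sequence; new medians get ids ``mv1``,
    ``mv2``, ... in acceptance order.  At each pass the MSN over the current
    node set is rebuilt; triples in which at least two of the three pairs
    are linked are scanned in lexicographic id order, and a quasi-median is
    accepted iff it strictly reduces the minimum spanning cost of the node
    set.  After every acceptance scanning restarts, so the result is a
    deterministic fixpoint.
    """
    nodes = dict(sequences)
    if len(nodes) <= 1:
        return nodes
    next_mv = 1
    while True:
        ids = sorted(nodes)
        seqs = [nodes[i] for i in ids]
        n = len(ids)
        dist = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = hamming(seqs[i], seqs[j])
        g = build_msn(dist, ids, epsilon)
        known = set(nodes.values())
        base_cost = _mst_cost(list(nodes.values()))
        accepted = False
        for u, v, w in itertools.combinations(ids, 3):
            linked = sum((g.has_edge(*p) for p in ((u, v), (u, w), (v, w))))
            if linked < 2:
                continue
            for qm in quasi_medians(nodes[u], nodes[v], nodes[w]):
                if qm in known:
                    continue
                if _mst_cost(list(nodes.values()) + [qm]) < base_cost:
                    if next_mv > max_medians:
                        raise DataError(f"median vectors exceed cap {max_medians}")
                    nodes[f"mv{next_mv}"] = qm
                    next_mv += 1
                    accepted = True
                    break
            if accepted:
                break
        if not accepted:
            return nodes


def prune_medians(
    sequences: dict[str, str], observed: list[str]
) -> dict[str, str]:
    """Drop median vectors not needed for a minimum-cost connection.

    A median is removed (ids rescanned after each removal) whenever the
    minimum spanning cost of the remaining node set does not increase
    without it.  Surviving medians are relabelled ``mv1..mvk`` in id order.
    """
    nodes = dict(sequences)
    while True:
        cost = _mst_cost(list(nodes.values()))
        removed = False
        for mid in sorted(n for n in nodes if n not in observed):
            trial = {k: v for k, v in nodes.items() if k != mid}
            if _mst_cost(list(trial.values())) <= cost:
                nodes = trial
                removed = True
                break
        if not removed:
            break
    relabelled: dict[str, str] = {}
    k = 0
    for nid in list(observed) + sorted(n for n in nodes if n not in observed):
        if nid in nodes:
            if nid in observed:
                relabelled[nid] = nodes[nid]
            else:
                k += 1
                relabelled[f"mv{k}"] = nodes[nid]
    return relabelled


# ---------------------------------------------------------------------------
# full construction


def build_mj_network(
    ht: HaplotypeTable, epsilon: int = 0, max_medians: int = 1000
) -> MJNetwork:
    """Median-joining network of a haplotype table.

    Nodes carry kind ("haplotype"/"median"), total frequency, per-region
    counts and the analysed-site sequence; edges carry the mismatch count
    (weight) and the 1-based analysed-site positions that mutate.
    """
    observed = {hid: seq for hid, seq in ht.haplotypes}
    with_medians = (
        add_median_vectors(observed, epsilon, max_medians)
        if len(observed) >= 3
        else dict(observed)
    )
    final = prune_medians(with_medians, list(observed))
    ids = sorted(final)
    n = len(ids)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = hamming(final[ids[i]], final[ids[j]])
    if n > 1:
        g = build_msn(dist, ids, epsilon)
    else:
        g = nx.Graph()
        g.add_node(ids[0])
    for nid in g.nodes:
        seq = final[nid]
        is_hap = nid in observed
        region_counts = (
            {r: c for (h, r), c in ht.counts.items() if h == nid} if is_hap else {}
        )
        g.nodes[nid].update(
            kind="haplotype" if is_hap else "median",
            frequency=sum(region_counts.values()),
            regions=";".join(f"{r}:{c}" for r, c in sorted(region_counts.items())),
            sequence=seq,
        )
    for u, v, data in g.edges(data=True):
        positions = [
            site
            for site, (x, y) in zip(ht.analysed_sites, zip(final[u], final[v]))
            if x != y
        ]
        data["weight"] = len(positions)
        data["positions"] = ",".join(str(p) for p in positions)
    return MJNetwork(graph=g, epsilon=epsilon)


# ---------------------------------------------------------------------------
# export


def export_network(net: MJNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML or a flat CSV edge list."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge_list_csv":
        rows = [
            {
                "source": u,
                "target": v,
                "weight": d["weight"],
                "positions": d["positions"],
            }
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "positions"]).to_csv(
            path, index=False
        )
    else:
        raise DataError(f"unknown export format {format!r}")
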