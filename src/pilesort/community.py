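"""Modularity and Louvain community detection for co-sort networks.

Modularity of a partition c on a weighted undirected graph is

    Q = (1 / 2m) * sum_ij [ w_ij - gamma * k_i * k_j / 2m ] * delta(c_i, c_j)

with m the total edge weight, k_i the weighted degree and gamma a
resolution parameter (default 1).  The Louvain heuristic greedily maximises
Q in two alternating phases: local moving of single nodes between
communities until no move improves Q beyond a small tolerance, then
aggregation of each community into a super-node, repeated until the
partition stops changing.  Node visit order is a seeded shuffle, so results
are deterministic for a fixed seed.

``exhaustive_max_modularity`` enumerates every set partition of a small
graph (<= 10 nodes) and is used as an independent optimality oracle.
"""

from __future__ import annotations

import random
import warnings
from typing import Hashable, Mapping

import networkx as nx

from .network import CoSortNetwork
from .sortdata import PilesortError

#: quote id -> community label; canonical labels are 1..K ordered by
#: community size (descending), ties broken by smallest member.
GroupingAssignment = dict

_GAIN_TOL = 1e-12


class ZeroEdgeError(PilesortError, ValueError):
    """Modularity is undefined on a network without edges (2m = 0)."""


class AssignmentCoverageError(PilesortError, ValueError):
    """An assignment does not cover every network node."""


def _as_graph(net: CoSortNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, CoSortNetwork) else net


def _adjacency(
    g: nx.Graph, weighted: bool = True
) -> dict[Hashable, dict[Hashable, float]]:
    adj: dict[Hashable, dict[Hashable, float]] = {n: {} for n in g.nodes}
    for i, j, d in g.edges(data=True):
        if i == j:
            continue
        w = float(d.get("weight", 1.0)) if weighted else 1.0
        adj[i][j] = adj[i].get(j, 0.0) + w
        adj[j][i] = adj[j].get(i, 0.0) + w
    return adj


def canonicalize_assignment(assignment: Mapping) -> GroupingAssignment:
    """Relabel communities 1..K by descending size, ties by smallest member."""
    groups: dict = {}
    for node, label in assignment.items():
        groups.setdefault(label, []).append(node)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    out: GroupingAssignment = {}
    for new_label, members in enumerate(ordered, start=1):
        for node in members:
            out[node] = new_label
    return out


def modularity(
    net: CoSortNetwork | nx.Graph,
    assignment: Mapping,
    resolution: float = 1.0,
    weighted: bool = True,
) -> float:
    """Weighted Newman-Girvan modularity of ``assignment`` at ``resolution``.

    Raises :class:`ZeroEdgeError` when the network has no edges and
    :class:`AssignmentCoverageError` when a node is missing a label.
    """
    g = _as_graph(net)
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise AssignmentCoverageError(
            f"assignment misses {len(missing)} node(s), e.g. {missing[0]!r}"
        )
    adj = _adjacency(g, weighted=weighted)
    two_m = sum(sum(nbrs.values()) for nbrs in adj.values())
    if two_m <= 0:
        raise ZeroEdgeError("modularity is undefined for a network with no edges")
    intra = 0.0  # sum over ordered pairs i != j within communities
    deg_by_comm: dict = {}
    for i, nbrs in adj.items():
        ci = assignment[i]
        deg_by_comm[ci] = deg_by_comm.get(ci, 0.0) + sum(nbrs.values())
        for j, w in nbrs.items():
            if assignment[j] == ci:
                intra += w
    q = intra / two_m
    q -= resolution * sum(d * d for d in deg_by_comm.values()) / (two_m * two_m)
    return q


def _one_level(
    adj: dict,
    seed_rng: random.Random,
    resolution: float,
    init: Mapping | None = None,
) -> tuple[dict, bool]:
    """Louvain local-moving phase; returns (node -> community, improved?).

    ``init`` seeds the starting communities (defaults to all singletons);
    it is used for the final refinement sweep over original nodes.
    """
    nodes = list(adj)
    comm = {n: init[n] for n in nodes} if init is not None else {n: n for n in nodes}
    k = {n: sum(adj[n][j] for j in adj[n] if j != n) + 2.0 * adj[n].get(n, 0.0)
         for n in nodes}
    two_m = sum(k.values()) + 0.0
    sigma_tot: dict = {}
    for n in nodes:
        sigma_tot[comm[n]] = sigma_tot.get(comm[n], 0.0) + k[n]
    improved = False
    moved = True
    while moved:
        moved = False
        order = list(nodes)
        seed_rng.shuffle(order)
        for i in order:
            ci = comm[i]
            # weights from i to each neighbouring community (self excluded)
            links: dict = {}
            for j, w in adj[i].items():
                if j != i:
                    links[comm[j]] = links.get(comm[j], 0.0) + w
            sigma_tot[ci] -= k[i]
            base = links.get(ci, 0.0) - resolution * k[i] * sigma_tot[ci] / two_m
            best_comm, best_gain = ci, base
            for cj, l_ij in links.items():
                if cj == ci:
                    continue
                gain = l_ij - resolution * k[i] * sigma_tot[cj] / two_m
                if gain > best_gain + _GAIN_TOL or (
                    abs(gain - best_gain) <= _GAIN_TOL
                    and best_comm != ci
                    and repr(cj) < repr(best_comm)
                ):
                    best_comm, best_gain = cj, gain
            sigma_tot[best_comm] += k[i]
            comm[i] = best_comm
            if best_comm != ci:
                moved = True
                improved = True
    return comm, improved


def _aggregate(adj: dict, comm: Mapping) -> dict:
    """Collapse communities to super-nodes, accumulating self-loops."""
    new_adj: dict = {c: {} for c in set(comm.values())}
    for i, nbrs in adj.items():
        ci = comm[i]
        for j, w in nbrs.items():
            cj = comm[j]
            if i == j:  # existing self-loop carried once
                new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
            elif ci == cj:
                # each intra edge appears twice in the symmetric adj
                new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w / 2.0
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w / 2.0
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w / 2.0
    return new_adj


def louvain(
    net: CoSortNetwork | nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    weighted: bool = True,
) -> GroupingAssignment:
    """Detect quote groupings by greedy modularity maximisation.

    Returns a canonicalised assignment (labels 1..K by descending community
    size).  Isolated nodes become singleton communities.  A network without
    any edge yields the all-singletons assignment with a warning rather
    than an error.
    """
    g = _as_graph(net)
    adj = _adjacency(g, weighted=weighted)
    if sum(len(v) for v in adj.values()) == 0:
        if len(adj) > 0:
            warnings.warn(
                "network has no edges; every quote becomes its own grouping",
                stacklevel=2,
            )
        return canonicalize_assignment({n: n for n in adj})
    rng = random.Random(seed)
    original_adj = adj
    mapping = {n: n for n in adj}  # original node -> current super-node
    while True:
        comm, improved = _one_level(adj, rng, resolution)
        if not improved:
            break
        mapping = {n: comm[mapping[n]] for n in mapping}
        adj = _aggregate(adj, comm)
    # final refinement: move single original nodes between the found
    # communities until no further modularity gain (never worsens Q)
    refined, _ = _one_level(original_adj, rng, resolution, init=mapping)
    return canonicalize_assignment(refined)


def _set_partitions(items: list):
    """Yield all partitions of ``items`` as lists of blocks (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def exhaustive_max_modularity(
    net: CoSortNetwork | nx.Graph,
    resolution: float = 1.0,
    weighted: bool = True,
    max_nodes: int = 10,
) -> GroupingAssignment:
    """Globally optimal partition by brute-force enumeration (test oracle).

    Guarded to ``max_nodes`` nodes because the number of set partitions
    grows as the Bell numbers.  Ties are broken towards fewer communities,
    then towards the lexicographically smallest canonical labelling over
    the sorted node list.
    """
    g = _as_graph(net)
    nodes = sorted(g.nodes)
    if len(nodes) > max_nodes:
        raise PilesortError(
            f"exhaustive search is limited to {max_nodes} nodes, got {len(nodes)}"
        )
    adj = _adjacency(g, weighted=weighted)
    two_m = sum(sum(nbrs.values()) for nbrs in adj.values())
    if two_m <= 0:
        return canonicalize_assignment({n: n for n in nodes})
    best = None
    best_q = float("-inf")
    best_tie: tuple | None = None
    for blocks in _set_partitions(nodes):
        assignment = {n: bi for bi, block in enumerate(blocks) for n in block}
        q = modularity(g, assignment, resolution=resolution, weighted=weighted)
        canon = canonicalize_assignment(assignment)
        tie = (len(blocks), tuple(canon[n] for n in nodes))
        if q > best_q + 1e-12:
            best, best_q, best_tie = canon, q, tie
        elif q > best_q - 1e-12 and tie < best_tie:
            best, best_tie = canon, tie
    return best
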