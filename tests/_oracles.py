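"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force (exhaustive
enumeration, probability trees) without touching the implementation paths
they check.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache


def brute_force_indirect_pairs(
    pol_edges: list[tuple[str, str]], disp_edges: list[tuple[str, str]]
) -> tuple[set[tuple[str, str]], dict[str, int]]:
    """All pollinator-disperser pairs reachable by a two-step walk via a plant.

    Returns the set of connected pairs and n_j per mediating plant, counting
    each distinct pair once per plant.
    """
    pairs: set[tuple[str, str]] = set()
    n_per_plant: dict[str, int] = {}
    plants = {p for p, _ in pol_edges} & {p for p, _ in disp_edges}
    for plant in plants:
        pols = {a for p, a in pol_edges if p == plant}
        disps = {a for p, a in disp_edges if p == plant}
        n_per_plant[plant] = len(pols) * len(disps)
        pairs.update(itertools.product(pols, disps))
    return pairs, n_per_plant


def exact_mean_extinction_pct(
    partners: dict[str, dict[str, float]], R: dict[str, float], primary: str
) -> float:
    """Exact expected E (%) by enumerating the full Bernoulli outcome tree.

    Each cascade round, every survivor adjacent to a newly extinct partner
    goes extinct independently with probability
    1 - prod_x (1 - R_y * d_yx) over its newly lost partners.  The
    recursion enumerates every subset of casualties per round.
    """
    species = sorted(partners)
    n = len(species)

    @lru_cache(maxsize=None)
    def expected(extinct: frozenset, newly: frozenset) -> float:
        if not newly:
            return 100.0 * len(extinct) / n
        probs: dict[str, float] = {}
        for y in species:
            if y in extinct:
                continue
            survive = 1.0
            for x in newly:
                if x in partners[y]:
                    survive *= 1.0 - R[y] * partners[y][x]
            if survive < 1.0:
                probs[y] = 1.0 - survive
        candidates = sorted(probs)
        total = 0.0
        for k in range(len(candidates) + 1):
            for subset in itertools.combinations(candidates, k):
                p = 1.0
                for y in candidates:
                    p *= probs[y] if y in subset else 1.0 - probs[y]
                if p > 0.0:
                    total += p * expected(extinct | frozenset(subset), frozenset(subset))
        return total

    return expected(frozenset({primary}), frozenset({primary}))


def _entropy_terms(probs: list[float], total: float) -> float:
    h = 0.0
    for p in probs:
        if p > 0:
            h -= (p / total) * math.log2(p / total)
    return h


def map_equation_codelength(
    edges: list[tuple[int, int, float]], n_nodes: int, membership: list[int]
) -> float:
    """Two-level map-equation codelength (bits) of a hard partition.

    Undirected flow: node visit rates proportional to strength; module exit
    rates proportional to boundary-crossing edge weight.
    """
    strength = [0.0] * n_nodes
    total_weight = 0.0
    exit_weight: dict[int, float] = {}
    for u, v, w in edges:
        strength[u] += w
        strength[v] += w
        total_weight += w
        if membership[u] != membership[v]:
            exit_weight[membership[u]] = exit_weight.get(membership[u], 0.0) + w
            exit_weight[membership[v]] = exit_weight.get(membership[v], 0.0) + w
    two_w = 2.0 * total_weight
    p = [s / two_w for s in strength]
    modules = sorted(set(membership))
    q = {m: exit_weight.get(m, 0.0) / two_w for m in modules}
    q_total = sum(q.values())
    code = 0.0
    if q_total > 0:
        code += q_total * _entropy_terms([q[m] for m in modules], q_total)
    for m in modules:
        members = [i for i in range(n_nodes) if membership[i] == m]
        p_circ = q[m] + sum(p[i] for i in members)
        if p_circ > 0:
            code += p_circ * _entropy_terms([q[m]] + [p[i] for i in members], p_circ)
    return code


def set_partitions(items: list[int]):
    """All set partitions of ``items`` (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [[first] + block] + partition[i + 1:]
        yield [[first]] + partition


def best_partition_codelength(
    edges: list[tuple[int, int, float]], n_nodes: int
) -> tuple[float, int]:
    """Exhaustive minimum two-level codelength over all partitions.

    Returns (min codelength, number of modules of a minimizer).  Only
    feasible for tiny graphs (Bell numbers).
    """
    best = math.inf
    best_k = n_nodes
    for blocks in set_partitions(list(range(n_nodes))):
        membership = [0] * n_nodes
        for m, block in enumerate(blocks):
            for node in block:
                membership[node] = m
        code = map_equation_codelength(edges, n_nodes, membership)
        if code < best - 1e-12:
            best = code
            best_k = len(blocks)
    return best, best_k
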