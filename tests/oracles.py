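"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: topologies are
enumerated exhaustively and scored by least squares, the K scale factor
is found by brute-force grid search, and additive distance matrices are
built directly from random edge-length vectors.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from typing import Dict, FrozenSet, List, Tuple

import numpy as np

Edge = Tuple[int, int]

_TOPO_CACHE: Dict[int, List[List[Edge]]] = {}
_PINV_CACHE: Dict[int, Tuple[np.ndarray, np.ndarray, List[Tuple[int, int]]]] = {}


def all_unrooted_topologies(n: int) -> List[List[Edge]]:
    """All (2n-5)!! unrooted binary topologies on leaves 0..n-1 by
    sequential leaf insertion.  Internal nodes are numbered from n."""
    if n in _TOPO_CACHE:
        return _TOPO_CACHE[n]
    trees: List[Tuple[List[Edge], int]] = [([(0, n), (1, n), (2, n)], n + 1)]
    for leaf in range(3, n):
        nxt_trees = []
        for edges, nxt in trees:
            for ei in range(len(edges)):
                a, b = edges[ei]
                e2 = [e for k, e in enumerate(edges) if k != ei]
                e2 += [(a, nxt), (b, nxt), (leaf, nxt)]
                nxt_trees.append((e2, nxt + 1))
        trees = nxt_trees
    out = [e for e, _ in trees]
    _TOPO_CACHE[n] = out
    return out


def path_matrix(edges: List[Edge], n: int) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """0/1 matrix mapping edge lengths to leaf-pair path distances."""
    adj = defaultdict(list)
    for ei, (a, b) in enumerate(edges):
        adj[a].append((b, ei))
        adj[b].append((a, ei))
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    for pi, (u, v) in enumerate(pairs):
        prev = {u: None}
        stack = [u]
        while stack:
            x = stack.pop()
            if x == v:
                break
            for y, ei in adj[x]:
                if y not in prev:
                    prev[y] = (x, ei)
                    stack.append(y)
        x = v
        while prev[x] is not None:
            x, ei = prev[x]
            A[pi, ei] = 1.0
    return A, pairs


def _pinv_bank(n: int):
    """Stacked pseudo-inverses of every topology's path matrix."""
    if n not in _PINV_CACHE:
        topos = all_unrooted_topologies(n)
        mats = np.stack([path_matrix(e, n)[0] for e in topos])
        _PINV_CACHE[n] = (mats, np.linalg.pinv(mats), list(itertools.combinations(range(n), 2)))
    return _PINV_CACHE[n]


def ls_best_topology(D: np.ndarray) -> Tuple[List[Edge], np.ndarray, float]:
    """Exhaustive least-squares search: the topology (with fitted edge
    lengths) minimizing the residual to the distance matrix."""
    n = D.shape[0]
    mats, pinvs, pairs = _pinv_bank(n)
    d = np.array([D[i, j] for i, j in pairs])
    x = pinvs @ d  # (T, E)
    resid = mats @ x[..., None]  # (T, P, 1)
    rss = ((resid[..., 0] - d) ** 2).sum(axis=1)
    best = int(np.argmin(rss))
    return all_unrooted_topologies(n)[best], x[best], float(rss[best])


def edges_to_splits(
    edges: List[Edge], lengths: np.ndarray, labels: List[str]
) -> Dict[FrozenSet[str], float]:
    """Canonical split -> length map for an edge-list tree, keyed like
    PhyloTree.bipartitions (side not containing the first label)."""
    n = len(labels)
    adj = defaultdict(list)
    for ei, (a, b) in enumerate(edges):
        adj[a].append((b, ei))
        adj[b].append((a, ei))
    all_set = frozenset(labels)
    out: Dict[FrozenSet[str], float] = {}
    for ei, (a, b) in enumerate(edges):
        # leaves reachable from a without crossing edge ei
        seen = {a}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, e2 in adj[x]:
                if e2 != ei and y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(labels[v] for v in seen if v < n)
        if labels[0] in side:
            side = all_set - side
        out[side] = out.get(side, 0.0) + float(lengths[ei])
    return out


def random_additive_matrix(
    n: int, rng: np.random.Generator, lo: float = 0.05, hi: float = 0.5
) -> Tuple[np.ndarray, List[Edge], np.ndarray]:
    """A distance matrix that is exactly additive on a random topology
    with uniform edge lengths."""
    edges: List[Edge] = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for leaf in range(3, n):
        a, b = edges.pop(int(rng.integers(len(edges))))
        edges += [(a, nxt), (b, nxt), (leaf, nxt)]
        nxt += 1
    lens = rng.uniform(lo, hi, size=len(edges))
    A, pairs = path_matrix(edges, n)
    dvec = A @ lens
    D = np.zeros((n, n))
    for (i, j), dv in zip(pairs, dvec):
        D[i, j] = D[j, i] = dv
    return D, edges, lens


def grid_search_k(
    br: Dict, bc: Dict, k_max: float = 5.0, step: float = 1e-4
) -> Tuple[float, float]:
    """Brute-force scale factor minimizing the branch-length score."""
    union = sorted(set(br) | set(bc), key=lambda s: sorted(s))
    r = np.array([br.get(s, 0.0) for s in union])
    c = np.array([bc.get(s, 0.0) for s in union])
    ks = np.arange(0.0, k_max + step / 2, step)
    scores = np.sqrt((((ks[:, None] * c[None, :]) - r[None, :]) ** 2).sum(axis=1))
    i = int(np.argmin(scores))
    return float(ks[i]), float(scores[i])
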