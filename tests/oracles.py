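"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: length-bounded
walk enumeration instead of Floyd-Warshall, full link-subset enumeration
instead of factoring, and exhaustive path enumeration instead of Brandes
accumulation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _parity_matrix(cmap) -> tuple[list[str], np.ndarray]:
    factors = cmap.factors
    k = len(factors)
    pos = {f: i for i, f in enumerate(factors)}
    W = np.zeros((2 * k, 2 * k))
    for i, j, s, w in cmap.links():
        a, b = pos[i], pos[j]
        if s > 0:
            W[a, b] = max(W[a, b], w)
            W[k + a, k + b] = max(W[k + a, k + b], w)
        else:
            W[a, k + b] = max(W[a, k + b], w)
            W[k + a, b] = max(W[k + a, b], w)
    return factors, W


def fuzzy_tc_oracle(cmap) -> tuple[np.ndarray, np.ndarray]:
    """Max over all walks of length <= 2k of the min traversed magnitude,
    split by sign parity, via length-indexed dynamic programming."""
    factors, W = _parity_matrix(cmap)
    k = len(factors)
    best = W.copy()
    B = W.copy()  # best walks of exactly the current length
    for _ in range(2 * k - 1):
        B = np.max(np.minimum(B[:, :, None], W[None, :, :]), axis=1)
        best = np.maximum(best, B)
    return best[:k, :k], best[:k, k:]


def prob_tc_oracle(cmap) -> tuple[np.ndarray, np.ndarray]:
    """Exact reliability by enumerating every subset of sign-specific links."""
    links = list(cmap.links())
    L = len(links)
    assert L <= 15, "oracle is exponential in the link count"
    factors = cmap.factors
    k = len(factors)
    pos = {f: i for i, f in enumerate(factors)}
    n = 2 * k
    tcp = np.zeros((k, k))
    tcm = np.zeros((k, k))
    for bits in itertools.product((0, 1), repeat=L):
        p = 1.0
        A = np.zeros((n, n), dtype=bool)
        for up, (i, j, s, w) in zip(bits, links):
            p *= w if up else 1.0 - w
            if up:
                a, b = pos[i], pos[j]
                if s > 0:
                    A[a, b] = A[k + a, k + b] = True
                else:
                    A[a, k + b] = A[k + a, b] = True
        if p == 0.0:
            continue
        R = A.copy()
        for _ in range(n):
            R = R | (R @ A)
        tcp += p * R[:k, :k]
        tcm += p * R[:k, k:]
    return tcp, tcm


def betweenness_oracle(cmap) -> dict[str, float]:
    """Endpoint-excluded betweenness by exhaustive shortest-path enumeration."""
    factors = cmap.factors
    adj: dict[str, set[str]] = {f: set() for f in factors}
    for i, j, _s, _w in cmap.links():
        if i != j:
            adj[i].add(j)

    def all_paths(s: str, t: str) -> list[list[str]]:
        out: list[list[str]] = []

        def dfs(path: list[str]) -> None:
            u = path[-1]
            if u == t:
                out.append(list(path))
                return
            for v in sorted(adj[u]):
                if v not in path:
                    dfs(path + [v])

        dfs([s])
        return out

    bc = {f: 0.0 for f in factors}
    for s in factors:
        for t in factors:
            if s == t:
                continue
            paths = all_paths(s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sp = [p for p in paths if len(p) == shortest]
            for v in factors:
                if v in (s, t):
                    continue
                bc[v] += sum(1 for p in sp if v in p) / len(sp)
    return bc


def dbar_oracle(net_a: dict, net_b: dict) -> tuple[float, int]:
    """Direct recomputation of d-bar = sum |d| / N over compared links."""
    keys = set(net_a) | set(net_b)
    diffs = []
    for key in keys:
        a = net_a.get(key, 0.0)
        b = net_b.get(key, 0.0)
        if abs(a) > 1e-9 or abs(b) > 1e-9:
            diffs.append(abs(a - b))
    return (sum(diffs) / len(diffs) if diffs else math.nan), len(diffs)
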