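"""Transitive closure of bipolar weighted digraphs and the disagreement statistic.

A stakeholder map records only direct beliefs.  Transitive closure propagates
influence along every *walk* (chain of links), so each ordered factor pair
receives the strongest influence reachable through the whole map.  Two walk
semantics are supported:

* **fuzzy** — a walk is as strong as its weakest arrow (min rule); the pair
  value is the maximum over walks.  This is a max-min semiring closure.
* **probabilistic** — each arrow transmits independently with probability
  equal to its magnitude; a walk's weight is the product of its arrow
  weights, and walks combine under two-terminal network-reliability
  semantics (the probability that *some* transmitting path of the right
  sign exists).  A max-product rule is available as an alternative
  combination.

Signs propagate by parity: a walk is positive when it traverses an even
number of negative links, negative when odd.  Both procedures therefore run
on a *parity-doubled* auxiliary graph with two copies of every factor
(even/odd parity reached so far); positive links preserve parity, negative
links flip it.  The closure yields TC+ and TC- matrices; their difference is
the net TC used in correspondence tables and the disagreement statistic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TOL, ConceptMap, DisagreementReport, ValidationError, Walk

__all__ = [
    "ClosureResult",
    "fuzzy_closure",
    "probabilistic_closure",
    "net_tc",
    "strongest_walks",
    "disagreement",
    "harris_weights",
    "compare_weighting",
    "EXACT_LINK_CAP",
]

#: exact probabilistic closure refuses more relevant links than this per pair
EXACT_LINK_CAP = 25


@dataclass
class ClosureResult:
    """Transitive-closure matrices with optional witness walks.

    ``tc_plus`` / ``tc_minus`` hold the positive- and negative-sign closure
    magnitudes (both in [0, 1], origin rows, landing columns); ``net`` is
    their elementwise difference.  ``witness`` maps ``(origin, landing,
    sign)`` to one maximal-weight walk (fuzzy closure only).  ``mc_meta``
    carries seed, sample count and per-pair standard errors when Monte Carlo
    estimation was used.
    """

    tc_plus: pd.DataFrame
    tc_minus: pd.DataFrame
    method: str
    witness: dict[tuple[str, str, int], Walk] = field(default_factory=dict)
    mc_meta: dict = field(default_factory=dict)
    source: ConceptMap | None = None

    @property
    def net(self) -> pd.DataFrame:
        return self.tc_plus - self.tc_minus

    @property
    def factors(self) -> list[str]:
        return list(self.tc_plus.index)

    def as_map(self, provenance: str = "") -> ConceptMap:
        """Re-read the closure as a bipolar map (for SNA or re-closure)."""
        cmap = ConceptMap(self.factors, provenance=provenance or f"closure:{self.method}")
        if self.source is not None:
            cmap.outcome = set(self.source.outcome)
        for i in self.factors:
            for j in self.factors:
                if i == j:
                    continue
                p = float(self.tc_plus.loc[i, j])
                m = float(self.tc_minus.loc[i, j])
                cmap.set_link(i, j, wplus=p if p > TOL else 0.0, wminus=m if m > TOL else 0.0)
        cmap.closed = True
        return cmap

    def influence_column(self, outcome: str) -> pd.Series:
        """Net closure weights of every factor onto ``outcome``."""
        if outcome not in self.net.columns:
            raise KeyError(f"outcome {outcome!r} not among factors")
        col = self.net[outcome].drop(index=outcome)
        col.name = outcome
        return col


# ---------------------------------------------------------------------------
# Parity-doubled graph helpers
# ---------------------------------------------------------------------------


def _parity_arrays(cmap: ConceptMap) -> tuple[list[str], np.ndarray]:
    """Weighted adjacency of the parity-doubled graph.

    Node ``par * k + i`` is factor ``i`` reached with walk parity ``par``
    (0 = even number of negative links so far).  Positive links connect equal
    parities; negative links connect opposite parities.
    """
    factors = cmap.factors
    k = len(factors)
    pos = {f: n for n, f in enumerate(factors)}
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


# ---------------------------------------------------------------------------
# Fuzzy (max-min) closure
# ---------------------------------------------------------------------------


def fuzzy_closure(cmap: ConceptMap) -> ClosureResult:
    """Max-min transitive closure split by walk sign.

    Runs a max-min Floyd-Warshall pass over the parity-doubled graph
    (O(k^3) on 2k nodes).  Cycles are permitted: the max-min recursion
    converges because revisiting a node can never raise a walk's minimum.
    Among equally strong walks the shorter one is kept as witness, so the
    returned walks are deterministic for a given factor order.
    """
    factors, W = _parity_arrays(cmap)
    k = len(factors)
    n = 2 * k
    D = W.copy()
    for m in range(n):
        D = np.maximum(D, np.minimum(D[:, m, None], D[None, m, :]))

    idx = factors
    tc_plus = pd.DataFrame(D[:k, :k], index=idx, columns=idx)
    tc_minus = pd.DataFrame(D[:k, k:], index=idx, columns=idx)

    # Witness recovery: a walk achieves bottleneck D[a, v] iff it stays on
    # links of weight >= D[a, v], so a BFS on that threshold subgraph finds
    # the shortest such walk; sorted adjacency order makes it deterministic.
    def shortest_at_threshold(a: int, v: int, thr: float) -> list[int]:
        ok = W >= thr - TOL
        prev = np.full(n, -2, dtype=int)  # -2 unvisited, -1 = walk start
        frontier = [x for x in range(n) if ok[a, x]]
        for x in frontier:
            prev[x] = -1
        while frontier:
            if prev[v] != -2:
                break
            nxt = []
            for u in frontier:
                for x in np.flatnonzero(ok[u]):
                    if prev[x] == -2:
                        prev[x] = u
                        nxt.append(x)
            frontier = nxt
        path = [v]
        while prev[path[-1]] != -1:
            path.append(prev[path[-1]])
        path.append(a)
        return path[::-1]

    witness: dict[tuple[str, str, int], Walk] = {}
    for a in range(k):
        for b in range(k):
            for sign, v in ((+1, b), (-1, k + b)):
                w = D[a, v]
                if w > TOL:
                    nodes = tuple(factors[x % k] for x in shortest_at_threshold(a, v, w))
                    witness[(factors[a], factors[b], sign)] = Walk(nodes, sign, float(w))

    return ClosureResult(tc_plus, tc_minus, method="fuzzy", witness=witness, source=cmap)


# ---------------------------------------------------------------------------
# Probabilistic closure
# ---------------------------------------------------------------------------


def _sign_links(cmap: ConceptMap) -> list[tuple[int, int, int, float]]:
    pos = {f: n for n, f in enumerate(cmap.factors)}
    return [(pos[i], pos[j], s, w) for i, j, s, w in cmap.links()]


def _parity_reachable(k: int, links: list, present: set[int], start: int) -> np.ndarray:
    """Boolean reachability over parity nodes from (start, even), walks of length >= 1."""
    seen = np.zeros(2 * k, dtype=bool)
    stack = []
    adj: dict[int, list[int]] = {}
    for li in present:
        a, b, s, _w = links[li]
        for par in (0, 1):
            u = par * k + a
            v = (par if s > 0 else 1 - par) * k + b
            adj.setdefault(u, []).append(v)
    for v in adj.get(start, ()):  # length-1 walks seed the search
        if not seen[v]:
            seen[v] = True
            stack.append(v)
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if not seen[v]:
                seen[v] = True
                stack.append(v)
    return seen


def _reliability(k: int, links: list, relevant: list[int], probs: dict[int, float],
                 start: int, target: int) -> float:
    """Two-terminal reliability by factoring (recursive conditioning).

    Probability that target parity-node is reachable from (start, even) when
    each link transmits independently.  Prunes branches where the present
    links already realise the path, or where even all undecided links cannot.
    """

    def rec(present: frozenset[int], undecided: tuple[int, ...]) -> float:
        if _parity_reachable(k, links, set(present), start)[target]:
            return 1.0
        if not _parity_reachable(k, links, set(present) | set(undecided), start)[target]:
            return 0.0
        e, rest = undecided[0], undecided[1:]
        p = probs[e]
        return p * rec(present | {e}, rest) + (1 - p) * rec(present, rest)

    return rec(frozenset(), tuple(relevant))


def probabilistic_closure(
    cmap: ConceptMap,
    mode: str = "exact",
    *,
    samples: int = 100_000,
    seed: int | None = None,
    combine: str = "reliability",
) -> ClosureResult:
    """Transitive closure under the probability interpretation of weights.

    Each sign-specific link transmits independently with probability equal
    to its magnitude.  ``tc_plus[i, j]`` is the probability that at least one
    transmitting positive-sign path i -> j exists (``tc_minus`` analogous for
    negative sign).  ``mode="exact"`` computes this by factoring over the
    links relevant to each pair and refuses pairs with more than
    ``EXACT_LINK_CAP`` relevant links; ``mode="monte_carlo"`` samples link
    realisations (seed mandatory) and reports standard errors in
    ``mc_meta``.  ``combine="max_product"`` replaces reliability with the
    single strongest path product (a max-product semiring closure).
    """
    factors = cmap.factors
    k = len(factors)
    links = _sign_links(cmap)
    probs = {li: w for li, (_a, _b, _s, w) in enumerate(links)}
    idx = factors
    tcp = np.zeros((k, k))
    tcm = np.zeros((k, k))
    meta: dict = {"combine": combine}

    if combine == "max_product":
        _, D = _parity_arrays(cmap)
        n = 2 * k
        for m in range(n):
            D = np.maximum(D, D[:, m, None] * D[None, m, :])
        tcp, tcm = D[:k, :k], D[:k, k:]
        method = "probabilistic-max-product"
    elif mode == "exact":
        # forward/backward reachability on the underlying digraph prunes
        # the link set that can matter for a given ordered pair
        adj_f: dict[int, set[int]] = {}
        adj_b: dict[int, set[int]] = {}
        for a, b, _s, _w in links:
            adj_f.setdefault(a, set()).add(b)
            adj_b.setdefault(b, set()).add(a)

        def reach(adj: dict[int, set[int]], start: int) -> set[int]:
            seen = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in adj.get(u, ()):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            return seen

        fwd = {a: reach(adj_f, a) for a in range(k)}
        bwd = {b: reach(adj_b, b) for b in range(k)}
        for a in range(k):
            for b in range(k):
                relevant = [
                    li for li, (x, y, _s, _w) in enumerate(links)
                    if x in fwd[a] and y in bwd[b]
                ]
                if not relevant:
                    continue
                if len(relevant) > EXACT_LINK_CAP:
                    raise ValidationError(
                        f"exact probabilistic closure for pair ({factors[a]!r}, {factors[b]!r}) "
                        f"involves {len(relevant)} links (cap {EXACT_LINK_CAP}); "
                        "use mode='monte_carlo' with an explicit seed instead"
                    )
                tcp[a, b] = _reliability(k, links, relevant, probs, a, b)
                tcm[a, b] = _reliability(k, links, relevant, probs, a, k + b)
        method = "probabilistic-exact"
    elif mode == "monte_carlo":
        if seed is None:
            raise ValidationError("monte_carlo mode requires an explicit seed")
        rng = np.random.default_rng(seed)
        n = 2 * k
        base = np.zeros((n, n), dtype=bool)
        link_cells: list[tuple[int, int]] = []
        for a, b, s, _w in links:
            if s > 0:
                link_cells.append((a, b))
                link_cells.append((k + a, k + b))
            else:
                link_cells.append((a, k + b))
                link_cells.append((k + a, b))
        p_arr = np.array([w for _a, _b, _s, w in links])
        hits_p = np.zeros((k, k))
        hits_m = np.zeros((k, k))
        chunk = max(1, min(samples, 2048))
        done = 0
        n_sq = max(1, math.ceil(math.log2(max(n, 2))))
        while done < samples:
            size = min(chunk, samples - done)
            up = rng.random((size, len(links))) < p_arr  # link transmits?
            A = np.zeros((size, n, n), dtype=bool)
            for li in range(len(links)):
                (r1, c1), (r2, c2) = link_cells[2 * li], link_cells[2 * li + 1]
                A[:, r1, c1] = up[:, li]
                A[:, r2, c2] = up[:, li]
            R = A.copy()
            for _ in range(n_sq):  # repeated squaring covers all walk lengths
                R = R | np.matmul(R, R)
            hits_p += R[:, :k, :k].sum(axis=0)
            hits_m += R[:, :k, k:].sum(axis=0)
            done += size
        tcp = hits_p / samples
        tcm = hits_m / samples
        meta.update(
            seed=seed,
            samples=samples,
            se_plus=pd.DataFrame(np.sqrt(tcp * (1 - tcp) / samples), index=idx, columns=idx),
            se_minus=pd.DataFrame(np.sqrt(tcm * (1 - tcm) / samples), index=idx, columns=idx),
        )
        method = "probabilistic-monte-carlo"
    else:
        raise ValidationError(f"unknown mode {mode!r}; use 'exact' or 'monte_carlo'")

    return ClosureResult(
        pd.DataFrame(tcp, index=idx, columns=idx),
        pd.DataFrame(tcm, index=idx, columns=idx),
        method=method,
        mc_meta=meta,
        source=cmap,
    )


def net_tc(result: ClosureResult) -> pd.DataFrame:
    """Net transitive closure: TC+ contributes positively, TC- negatively."""
    return result.net


# ---------------------------------------------------------------------------
# Witness walks
# ---------------------------------------------------------------------------


def strongest_walks(
    result: ClosureResult,
    *,
    pair: tuple[str, str] | None = None,
    outcome: str | None = None,
    top_k: int = 10,
) -> list[Walk]:
    """Rank the recorded maximal-weight walks.

    For ``pair`` returns up to two walks (one per sign); for ``outcome``
    collects the witness walk of every factor onto the outcome.  Sorting is
    by weight descending, ties broken by shorter walk then lexicographic
    node order.  Unreachable pairs yield an empty list.
    """
    if not result.witness:
        raise ValidationError(
            f"closure method {result.method!r} did not record witness walks; use fuzzy_closure"
        )
    if (pair is None) == (outcome is None):
        raise ValidationError("pass exactly one of pair= or outcome=")
    if pair is not None:
        keys = [(pair[0], pair[1], s) for s in (+1, -1)]
    else:
        keys = [(f, outcome, s) for f in result.factors if f != outcome for s in (+1, -1)]
    walks = [result.witness[key] for key in keys if key in result.witness]
    walks.sort(key=lambda w: (-w.weight, len(w), w.nodes))
    return walks[:top_k]


# ---------------------------------------------------------------------------
# Disagreement statistic
# ---------------------------------------------------------------------------


def _as_series(obj, outcome: str | None) -> pd.Series:
    if isinstance(obj, pd.Series):
        return obj.astype(float)
    if isinstance(obj, ClosureResult):
        if outcome is None:
            raise ValidationError("outcome label required to compare closure results")
        return obj.influence_column(outcome)
    if isinstance(obj, ConceptMap):
        if outcome is None:
            raise ValidationError("outcome label required to compare maps")
        if outcome not in obj:
            raise ValidationError(f"outcome {outcome!r} absent from map")
        return pd.Series(
            {f: obj.net(f, outcome) for f in obj.factors if f != outcome}, name=outcome
        )
    raise TypeError(f"cannot interpret {type(obj).__name__} as an influence column")


def _as_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj.astype(float)
    if isinstance(obj, ClosureResult):
        return obj.net
    if isinstance(obj, ConceptMap):
        return obj.net_frame()
    raise TypeError(f"cannot interpret {type(obj).__name__} as a net matrix")


def disagreement(a, b, *, scope: str = "outcome", outcome: str | None = None) -> DisagreementReport:
    """Average degree of disagreement between two knowledge sources.

    For each link, ``|d|`` is the absolute difference of the two sources' net
    transitive-closure weights; d-bar sums ``|d|`` over the N compared links
    and divides by N.  A link is *compared* when its net weight is nonzero in
    at least one source (an unreported link counts as weight zero).

    ``scope="outcome"`` compares the links into a designated outcome —
    ``a``/``b`` may be net influence columns (pandas Series indexed by
    factor), closure results, or maps with ``outcome=`` given.
    ``scope="whole_map"`` compares full net matrices over the union factor
    set and additionally reports the whole-map value, the summed differences
    divided by k^2 (all cells of the adjacency matrix).
    """
    if scope == "outcome":
        sa, sb = _as_series(a, outcome), _as_series(b, outcome)
        labels = sa.index.union(sb.index, sort=False)
        va = sa.reindex(labels).fillna(0.0)
        vb = sb.reindex(labels).fillna(0.0)
        per = pd.DataFrame({"weight_a": va, "weight_b": vb})
        k2 = None
    elif scope == "whole_map":
        fa, fb = _as_frame(a), _as_frame(b)
        labels = fa.index.union(fb.index, sort=False)
        va = fa.reindex(index=labels, columns=labels).fillna(0.0).stack()
        vb = fb.reindex(index=labels, columns=labels).fillna(0.0).stack()
        per = pd.DataFrame({"weight_a": va, "weight_b": vb})
        k2 = len(labels) ** 2
    else:
        raise ValidationError(f"unknown scope {scope!r}")

    per["abs_diff"] = (per["weight_a"] - per["weight_b"]).abs()
    compared = per[(per["weight_a"].abs() > TOL) | (per["weight_b"].abs() > TOL)].copy()
    n = len(compared)
    if n == 0:
        raise ValidationError("no compared links: both sources are empty (N = 0)")
    dbar = float(compared["abs_diff"].sum()) / n
    return DisagreementReport(
        dbar=dbar,
        n_compared=n,
        dbar_normalized=dbar / 2.0,
        per_link=compared,
        whole_map_value=float(compared["abs_diff"].sum()) / k2 if k2 else None,
        scope=scope,
    )


# ---------------------------------------------------------------------------
# Operator-independent (frequency) weighting
# ---------------------------------------------------------------------------


def harris_weights(maps: list[ConceptMap], *, rescale: bool = False) -> ConceptMap:
    """Morpheme-frequency weighting across one knowledge source's maps.

    Treats each node-arrow-node relationship as a unit of meaning and weights
    it by its relative frequency: the fraction of maps that contain the link
    (per sign slot; magnitudes are ignored, presence matters).  With
    ``rescale=True`` frequencies are divided by the maximum observed
    frequency so the most often repeated link gets weight 1.
    """
    if not maps:
        raise ValidationError("harris_weights requires at least one map")
    n = len(maps)
    counts: dict[tuple[str, str, int], int] = {}
    out = ConceptMap(provenance=f"harris:{n} maps")
    for m in maps:
        for f in m.factors:
            out.add_factor(f)
        for i, j, s, _w in m.links():
            counts[(i, j, s)] = counts.get((i, j, s), 0) + 1
    denom = n if not rescale else max(counts.values())
    for (i, j, s), c in counts.items():
        out.strengthen_link(i, j, c / denom, "plus" if s > 0 else "minus")
    return out


def compare_weighting(participant_map: ConceptMap, harris_map: ConceptMap) -> DisagreementReport:
    """d-bar between participant-assigned and frequency-derived weights.

    Reuses the disagreement machinery on the two net matrices; N counts the
    links nonzero in at least one scheme.
    """
    return disagreement(participant_map, harris_map, scope="whole_map")
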