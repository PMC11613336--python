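"""Post-closure network centralities for priority-setting.

A raw stakeholder map is a pile of individual associations, so network
statistics only become interpretable after transitive closure turns it into
a knowledge network.  The measures here rank factors as prominent outcomes
(indegree), important causes (outdegree), strongly connected factors
(weighted degree over |weight|) or path brokers (betweenness), and scale
each measure to [0, 1] so 1 marks the map's maximum.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .closure import ClosureResult
from .model import ConceptMap, ValidationError

__all__ = [
    "degree_centrality",
    "weighted_centrality",
    "betweenness_centrality",
    "scale_unit",
    "centrality_table",
]


def _as_closed_map(obj: ConceptMap | ClosureResult) -> ConceptMap:
    if isinstance(obj, ClosureResult):
        return obj.as_map()
    if not obj.closed:
        warnings.warn(
            "computing network centralities on a map that is not a transitive "
            "closure; results are hard to interpret before closure"
        )
    return obj


def degree_centrality(obj: ConceptMap | ClosureResult, mode: str = "all") -> pd.Series:
    """Arrow counts per factor: incoming (``in``), outgoing (``out``) or both.

    Each sign-specific link is a distinct stated influence, so a pair
    carrying both a positive and a negative weight contributes two arrows.
    A self-loop counts once for in and once for out.
    """
    cmap = _as_closed_map(obj)
    if mode not in ("in", "out", "all"):
        raise ValidationError(f"mode must be in/out/all, got {mode!r}")
    vals = pd.Series(0.0, index=cmap.factors, name=f"degree_{mode}")
    for i, j, _s, _w in cmap.links():
        if mode in ("out", "all"):
            vals[i] += 1
        if mode in ("in", "all"):
            vals[j] += 1
    return vals


def weighted_centrality(obj: ConceptMap | ClosureResult, mode: str = "all") -> pd.Series:
    """Degree centrality weighted by the absolute value of each arrow.

    Of two factors with equal arrow counts, the one linked by stronger
    arrows scores higher.
    """
    cmap = _as_closed_map(obj)
    if mode not in ("in", "out", "all"):
        raise ValidationError(f"mode must be in/out/all, got {mode!r}")
    vals = pd.Series(0.0, index=cmap.factors, name=f"weighted_{mode}")
    for i, j, _s, w in cmap.links():
        if mode in ("out", "all"):
            vals[i] += abs(w)
        if mode in ("in", "all"):
            vals[j] += abs(w)
    return vals


def betweenness_centrality(
    obj: ConceptMap | ClosureResult, *, weighted: bool = False
) -> pd.Series:
    """How often a factor sits on shortest paths between other factor pairs.

    Uses Brandes' algorithm on the directed graph whose edges are the pairs
    with any nonzero magnitude (parallel signs do not change paths);
    self-loops are excluded.  Default distances are unweighted hop counts;
    ``weighted=True`` uses distance ``1 - max(|w+|, |w-|)`` so stronger links
    are shorter.  Endpoints are excluded; values are raw pair counts
    (sum over ordered pairs s != t != v of sigma_st(v) / sigma_st).
    """
    cmap = _as_closed_map(obj)
    g = nx.DiGraph()
    g.add_nodes_from(cmap.factors)
    for i, j, _s, w in cmap.links():
        if i == j:
            continue
        prev = g.edges[i, j]["strength"] if g.has_edge(i, j) else 0.0
        g.add_edge(i, j, strength=max(prev, w))
    if weighted:
        for _i, _j, data in g.edges(data=True):
            data["distance"] = 1.0 - data["strength"]
        bc = nx.betweenness_centrality(g, normalized=False, weight="distance")
    else:
        bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc, name="betweenness").reindex(cmap.factors)


def scale_unit(values: pd.Series | np.ndarray | list) -> pd.Series | np.ndarray:
    """Scale centralities to [0, 1] by dividing by the maximum.

    One marks the map's strongest factor; other values read like proportions
    of that maximum.  An all-zero input stays all zero (there is no maximum
    to scale against).
    """
    if isinstance(values, pd.Series):
        m = float(values.max())
        return values / m if m > 0 else values * 0.0
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("scale_unit needs at least one value")
    m = arr.max()
    return arr / m if m > 0 else arr * 0.0


def centrality_table(obj: ConceptMap | ClosureResult) -> pd.DataFrame:
    """All measures, raw and 0-1 scaled, one row per factor."""
    cols = {
        "indegree": degree_centrality(obj, "in"),
        "outdegree": degree_centrality(obj, "out"),
        "weighted_in": weighted_centrality(obj, "in"),
        "weighted_out": weighted_centrality(obj, "out"),
        "betweenness": betweenness_centrality(obj),
    }
    table = pd.DataFrame(cols)
    for name in list(cols):
        table[f"{name}_scaled"] = scale_unit(table[name])
    return table


def node_sizes(
    scaled: pd.Series, *, min_size: float = 10.0, max_size: float = 60.0
) -> dict[str, float]:
    """Map 0-1 scaled centralities linearly onto a drawing size range."""
    return {f: min_size + (max_size - min_size) * float(v) for f, v in scaled.items()}
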