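"""Readers and writers for the standard map formats.

Two tabular formats are supported, matching how maps are recorded in the
field: the *edge list* (three columns: origin, landing, weight, one row per
arrow) and the labelled square *adjacency matrix* (cell = weight of the
row->column link).  GraphML export/import provides interoperability with
graph editors such as yEd; negative links are styled dashed there by
convention.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .model import (
    PRECISION,
    TOL,
    ConceptMap,
    MapFormatError,
    RawMap,
    ValidationError,
    normalize_label,
)

_FACTOR_HEADER = "# factors:"


def _read_header_factors(path: Path) -> tuple[list[str], int]:
    """Collect isolated factors declared in leading ``# factors:`` lines."""
    declared: list[str] = []
    n_comments = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            if line.lower().startswith(_FACTOR_HEADER):
                declared.extend(
                    normalize_label(tok)
                    for tok in line[len(_FACTOR_HEADER):].split(",")
                    if tok.strip()
                )
    return declared, n_comments


def read_edge_list(
    path: str | Path,
    *,
    raw: bool = False,
    sep: str = ",",
    level: str = "factor",
    provenance: str = "",
) -> ConceptMap | RawMap:
    """Read a three-column edge list (``origin,landing,weight``).

    With ``raw=True`` weights are interpreted on the signed 1-5 elicitation
    scale and a :class:`RawMap` is returned; otherwise weights are signed
    values in [-1, 1] and a :class:`ConceptMap` is returned.  Leading
    comment lines of the form ``# factors: A, B`` declare isolated factors.
    Errors name the offending file row.
    """
    path = Path(path)
    declared, n_comments = _read_header_factors(path)
    try:
        table = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MapFormatError(f"{path}: cannot parse edge list: {exc}") from exc
    required = ["origin", "landing", "weight"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise MapFormatError(f"{path}: missing column(s) {missing}; header must be origin,landing,weight")

    def rowno(idx: int) -> int:
        # +1 header, +1 1-based
        return int(idx) + n_comments + 2

    if raw:
        rmap = RawMap(provenance=provenance)
        for idx, row in table.iterrows():
            w = row["weight"]
            try:
                w = float(w)
            except (TypeError, ValueError):
                raise MapFormatError(f"{path} row {rowno(idx)}: non-numeric weight {w!r}")
            if not w.is_integer() or w == 0 or abs(w) > 5:
                raise MapFormatError(
                    f"{path} row {rowno(idx)}: raw weight must be a nonzero integer with |w| <= 5, got {w}"
                )
            rmap.add(row["origin"], row["landing"], int(w))
        return rmap

    cmap = ConceptMap(declared, level=level, provenance=provenance)
    seen: dict[tuple[str, str, int], tuple[float, int]] = {}
    for idx, row in table.iterrows():
        try:
            w = float(row["weight"])
        except (TypeError, ValueError):
            raise MapFormatError(f"{path} row {rowno(idx)}: non-numeric weight {row['weight']!r}")
        if math.isnan(w):
            raise MapFormatError(f"{path} row {rowno(idx)}: non-numeric weight")
        i = normalize_label(row["origin"])
        j = normalize_label(row["landing"])
        sign = 1 if w >= 0 else -1
        key = (i, j, sign)
        if key in seen and abs(seen[key][0] - w) > TOL:
            raise MapFormatError(
                f"{path} row {rowno(idx)}: duplicate contradictory rows for link "
                f"{i!r} -> {j!r} (weight {w} vs {seen[key][0]} at row {seen[key][1]})"
            )
        seen[key] = (w, rowno(idx))
        try:
            cmap.add_link(i, j, w)
        except ValidationError as exc:
            raise MapFormatError(f"{path} row {rowno(idx)}: {exc}") from exc
    return cmap


def write_edge_list(cmap: ConceptMap, path: str | Path, *, sep: str = ",") -> None:
    """Write a map as an edge-list CSV; a bipolar pair emits two rows."""
    rows = [
        {"origin": i, "landing": j, "weight": round(s * w, PRECISION)}
        for i, j, s, w in sorted(cmap.links())
    ]
    table = pd.DataFrame(rows, columns=["origin", "landing", "weight"])
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        isolated = [f for f in cmap.factors]
        fh.write(f"{_FACTOR_HEADER} {', '.join(isolated)}\n")
        table.to_csv(fh, sep=sep, index=False)


def read_adjacency(path: str | Path, *, level: str = "factor", provenance: str = "") -> ConceptMap:
    """Read a labelled square adjacency matrix (signed weights, rows = origins)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover
        raise MapFormatError(f"{path}: cannot parse adjacency matrix: {exc}") from exc
    frame.index = [normalize_label(x) for x in frame.index]
    frame.columns = [normalize_label(x) for x in frame.columns]
    if frame.shape[0] != frame.shape[1]:
        raise MapFormatError(f"{path}: adjacency matrix is not square: {frame.shape}")
    if list(frame.index) != list(frame.columns):
        raise MapFormatError(f"{path}: row and column labels differ")
    if not frame.map(lambda v: isinstance(v, (int, float)) and not isinstance(v, bool)).all().all():
        raise MapFormatError(f"{path}: adjacency matrix contains non-numeric cells")
    return ConceptMap.from_frame(frame.astype(float), level=level, provenance=provenance)


def write_adjacency(obj: ConceptMap | pd.DataFrame, path: str | Path) -> None:
    """Write a signed adjacency CSV (maps must not carry both signs on a pair)."""
    frame = obj.signed_frame() if isinstance(obj, ConceptMap) else obj
    frame.round(PRECISION).to_csv(path)


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------


def to_networkx(cmap: ConceptMap, *, node_size: dict[str, float] | None = None) -> nx.MultiDiGraph:
    """Convert to a MultiDiGraph with signed ``weight``, ``sign`` and
    ``line_style`` edge attributes (negative links render dashed)."""
    g = nx.MultiDiGraph(level=cmap.level, provenance=cmap.provenance)
    for f in cmap.factors:
        attrs = {"is_outcome": f in cmap.outcome}
        if node_size is not None:
            attrs["size"] = float(node_size.get(f, 0.0))
        g.add_node(f, **attrs)
    for i, j, s, w in cmap.links():
        g.add_edge(
            i,
            j,
            weight=round(s * w, PRECISION),
            sign="+" if s > 0 else "-",
            line_style="solid" if s > 0 else "dashed",
        )
    return g


def write_graphml(
    obj: ConceptMap,
    path: str | Path,
    *,
    node_size: dict[str, float] | None = None,
) -> None:
    nx.write_graphml(to_networkx(obj, node_size=node_size), str(path))


def read_graphml(path: str | Path) -> ConceptMap:
    g = nx.read_graphml(str(path))
    cmap = ConceptMap(
        g.nodes,
        level=g.graph.get("level", "factor"),
        provenance=g.graph.get("provenance", ""),
    )
    for f, data in g.nodes(data=True):
        if data.get("is_outcome"):
            cmap.outcome.add(normalize_label(f))
    for i, j, data in g.edges(data=True):
        cmap.add_link(i, j, float(data["weight"]))
    return cmap
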