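"""Harmonising factor labels across maps and juxtaposing knowledge sources.

Different stakeholders name the same concept differently (or in different
languages).  Standardization renames raw labels to shared codes via a
lexicon, after which maps become comparable: pattern-correspondence tables
align factors across sources row by row, endorsement proportions summarise
how widely a factor is recognised, and same-group maps can be combined into
a single group map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .closure import ClosureResult
from .model import TOL, ConceptMap, Lexicon, ValidationError

__all__ = [
    "apply_lexicon",
    "CorrespondenceTable",
    "correspondence_table",
    "endorsement_proportion",
    "merge_group_maps",
]


def apply_lexicon(
    cmap: ConceptMap,
    lexicon: Lexicon,
    *,
    strict: bool = True,
    source: str | None = None,
    use_codes: bool = True,
) -> ConceptMap:
    """Rename a map's factors to their standard codes.

    When two raw factors merge into one standard factor, parallel same-sign
    links collapse to the maximum magnitude (the strongest channel wins,
    consistent with max-min closure; summing could exceed 1) while
    opposite-sign links coexist in their respective slots.  Merges are
    appended to the lexicon's decisions log.  In strict mode unmapped labels
    raise; otherwise they pass through unchanged with a warning.
    """
    mapping: dict[str, str] = {}
    unknown: list[str] = []
    for f in cmap.factors:
        entry = lexicon.lookup(f, source=source)
        if entry is None:
            unknown.append(f)
            mapping[f] = f
        else:
            code, label = entry
            mapping[f] = code if use_codes else label
    if unknown:
        if strict:
            raise ValidationError(f"labels not in lexicon: {unknown}")
        warnings.warn(f"passing through {len(unknown)} unmapped label(s): {unknown}")

    merged_targets = {t for t in mapping.values() if sum(v == t for v in mapping.values()) > 1}
    for target in sorted(merged_targets):
        sources = sorted(f for f, t in mapping.items() if t == target)
        lexicon.log(f"merged {sources} -> {target!r} (same-sign links collapse to max)")

    out = ConceptMap(
        [mapping[f] for f in cmap.factors],
        level=cmap.level,
        outcome=[mapping[o] for o in cmap.outcome],
        provenance=cmap.provenance,
    )
    for i, j, s, w in cmap.links():
        mi, mj = mapping[i], mapping[j]
        if mi == mj and cmap.level == "factor":
            lexicon.log(f"dropped link {i!r} -> {j!r}: both map to {mi!r} (factor-level self-link)")
            continue
        out.strengthen_link(mi, mj, w, "plus" if s > 0 else "minus")
    return out


@dataclass
class CorrespondenceTable:
    """Factors x knowledge-sources table with per-row sharing class.

    ``table`` cells hold a presence flag (presence mode) or the net
    transitive-closure influence of the factor on a named outcome
    (influence mode); NaN means the source did not mention the factor.
    ``sharing`` classifies each row as ``shared-by-all``,
    ``shared-by:<sources>`` or ``unique-to:<source>``, computed from
    presence in the original maps.  Rows are ordered similarities first
    (shared by all, then shared subsets, then unique factors).
    """

    table: pd.DataFrame
    sharing: pd.Series
    mode: str
    outcome: str | None = None

    def rendered(self, decimals: int = 1) -> pd.DataFrame:
        """Display form: one-decimal rounding; full precision stays internal."""
        if self.mode == "presence":
            return self.table
        return self.table.round(decimals)


def correspondence_table(
    maps: list[tuple[str, ConceptMap]],
    mode: str = "presence",
    *,
    outcome: str | None = None,
    closures: dict[str, ClosureResult] | None = None,
) -> CorrespondenceTable:
    """Juxtapose standardized maps in a pattern-correspondence table.

    ``mode="presence"`` marks which sources mention which factor;
    ``mode="influence"`` fills each cell with the source's net closure
    weight of the factor onto ``outcome`` and requires ``closures`` keyed
    by source name.
    """
    if not maps:
        raise ValidationError("need at least one (source, map) pair")
    source_names = [s for s, _m in maps]
    factors: dict[str, None] = {}
    for _s, m in maps:
        for f in m.factors:
            factors.setdefault(f)
    rows = [f for f in factors if not (mode == "influence" and f == outcome)]

    presence = pd.DataFrame(
        {s: [f in m for f in rows] for s, m in maps}, index=rows, dtype=bool
    )

    if mode == "presence":
        table = presence.astype("boolean").mask(~presence)
    elif mode == "influence":
        if outcome is None or closures is None:
            raise ValidationError("influence mode requires outcome= and closures=")
        for s, m in maps:
            if outcome not in m:
                raise ValidationError(f"outcome {outcome!r} absent from map of source {s!r}")
            if s not in closures:
                raise ValidationError(f"no closure result provided for source {s!r}")
        cols = {s: closures[s].influence_column(outcome) for s in source_names}
        table = pd.DataFrame(index=rows)
        for s in source_names:
            table[s] = cols[s].reindex(rows)
            table.loc[~presence[s], s] = float("nan")
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    sharing = _sharing_classes(presence)
    order = _similarities_first(presence, source_names)
    return CorrespondenceTable(
        table=table.loc[order], sharing=sharing.loc[order], mode=mode, outcome=outcome
    )


def correspondence_from_columns(columns: pd.DataFrame, outcome: str | None = None) -> CorrespondenceTable:
    """Build an influence-mode table from precomputed net-influence columns.

    Nonzero cells are taken as evidence the source mentioned the factor;
    zero cells are kept (a mentioned factor can have zero net influence
    only if the columns distinguish it, which plain numbers cannot), so this
    constructor classifies sharing by nonzero presence.
    """
    presence = columns.abs() > TOL
    sharing = _sharing_classes(presence)
    order = _similarities_first(presence, list(columns.columns))
    return CorrespondenceTable(
        table=columns.loc[order], sharing=sharing.loc[order], mode="influence", outcome=outcome
    )


def _sharing_classes(presence: pd.DataFrame) -> pd.Series:
    n_sources = presence.shape[1]
    out = {}
    for f, row in presence.iterrows():
        holders = [s for s in presence.columns if row[s]]
        if len(holders) == n_sources and n_sources > 1:
            out[f] = "shared-by-all"
        elif len(holders) > 1:
            out[f] = "shared-by:" + "+".join(holders)
        elif holders:
            out[f] = "unique-to:" + holders[0]
        else:
            out[f] = "absent"
    return pd.Series(out, name="sharing_class")


def _similarities_first(presence: pd.DataFrame, source_names: list[str]) -> list[str]:
    """Row layout: shared by all, then shared subsets, then unique factors."""
    def rank(f: str) -> tuple:
        holders = [s for s in source_names if presence.loc[f, s]]
        n = len(holders)
        if n == len(source_names) and n > 1:
            return (0, ())
        if n > 1:
            return (1, tuple(source_names.index(s) for s in holders))
        return (2, tuple(source_names.index(s) for s in holders))
    # stable: preserve first-mention order within each class
    return sorted(presence.index, key=rank)


def endorsement_proportion(factor: str, maps: list[ConceptMap]) -> float:
    """Fraction of maps that mention the factor (a first hint of consensus)."""
    if not maps:
        raise ValidationError("need at least one map")
    hits = sum(1 for m in maps if factor in m)
    if hits == 0:
        warnings.warn(f"factor {factor!r} appears in none of the {len(maps)} maps")
    return hits / len(maps)


def merge_group_maps(maps: list[ConceptMap], method: str = "mean") -> ConceptMap:
    """Combine maps from one stakeholder group into a single group map.

    Methods (applied per sign slot over the union factor set):

    * ``"mean"`` (default) — arithmetic mean counting absent links as zero,
      consistent with the convention that an unreported link has weight 0;
    * ``"mean_over_mentions"`` — mean over only the maps that report the link;
    * ``"max"`` — strongest statement across maps.
    """
    if not maps:
        raise ValidationError("need at least one map")
    if method not in ("mean", "mean_over_mentions", "max"):
        raise ValidationError(f"unknown method {method!r}")
    n = len(maps)
    out = ConceptMap(provenance=f"merged:{method}:{n} maps")
    sums: dict[tuple[str, str, int], list[float]] = {}
    for m in maps:
        for f in m.factors:
            out.add_factor(f)
        for o in m.outcome:
            out.outcome.add(o)
        for i, j, s, w in m.links():
            sums.setdefault((i, j, s), []).append(w)
    for (i, j, s), ws in sums.items():
        if method == "mean":
            val = sum(ws) / n
        elif method == "mean_over_mentions":
            val = sum(ws) / len(ws)
        else:
            val = max(ws)
        out.strengthen_link(i, j, val, "plus" if s > 0 else "minus")
    return out
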