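"""Map reduction: categorization, condensation, aggregation, restriction.

Large maps overwhelm discussion.  Reduction produces communicable summaries:
*categorization* groups factors into themes, *condensation* sums the
factor-level weights between (and within) categories, *aggregation* averages
them over all possible member pairs, and *restriction* keeps only the
strongest links while auditing what was dropped.

Category-level numbers are not interpretable like factor-level numbers:
condensed sums can exceed 1 (they are flagged as category-scale) and a
category's internal links become a self-loop.  Every output therefore
carries a level tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TOL, CategoryScheme, ConceptMap, ValidationError

__all__ = ["Categorization", "categorize", "condense", "aggregate", "restrict"]


@dataclass
class Categorization:
    """A factor-level map viewed through a category scheme.

    Keeps the full factor-level map for drill-down: strong category-level
    relationships should send the analyst back to the member factors that
    produce them.
    """

    source: ConceptMap
    scheme: CategoryScheme
    categories: list[str]
    members: dict[str, list[str]]
    uncategorized: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.categories)

    def category_map(self) -> ConceptMap:
        """Category-level skeleton: a link wherever any member pair is linked
        (max magnitude per sign), intra-category links as self-loops."""
        cmap = ConceptMap(self.categories, level="category",
                          provenance=f"categorized:{self.source.provenance}")
        cat_of = {f: c for c, fs in self.members.items() for f in fs}
        for i, j, s, w in self.source.links():
            cmap.strengthen_link(cat_of[i], cat_of[j], w, "plus" if s > 0 else "minus")
        return cmap

    def drill_down(self, category: str) -> ConceptMap:
        """Factor-level subgraph of one category (its self-loop, unpacked)."""
        fs = set(self.members[category])
        sub = ConceptMap(self.members[category], provenance=f"{category} members")
        for i, j, s, w in self.source.links():
            if i in fs and j in fs:
                sub.strengthen_link(i, j, w, "plus" if s > 0 else "minus")
        return sub


def categorize(
    cmap: ConceptMap,
    scheme: CategoryScheme,
    *,
    strict: bool = True,
    uncategorized_bucket: str | None = None,
) -> Categorization:
    """Assign every factor of a map to its category.

    In strict mode an unassigned factor raises; alternatively
    ``uncategorized_bucket`` names a catch-all category for them.
    """
    members: dict[str, list[str]] = {}
    categories: dict[str, None] = {}
    loose: list[str] = []
    for f in cmap.factors:
        cat = scheme.category_of(f)
        if cat is None:
            if uncategorized_bucket is not None:
                cat = uncategorized_bucket
                loose.append(f)
            elif strict:
                raise ValidationError(f"factor {f!r} has no category assignment")
            else:
                cat = f  # its own singleton category
        categories.setdefault(cat)
        members.setdefault(cat, []).append(f)
    return Categorization(
        source=cmap, scheme=scheme, categories=list(categories), members=members,
        uncategorized=loose,
    )


def _member_matrix(cat: Categorization, slot: str) -> tuple[pd.DataFrame, list[str]]:
    plus, minus = cat.source.to_frames()
    if slot not in ("plus", "minus"):
        raise ValidationError(f"sign slot must be 'plus' or 'minus', got {slot!r}")
    return (plus if slot == "plus" else minus), cat.source.factors


def condense(cat: Categorization, slot: str = "plus") -> pd.DataFrame:
    """Net category influence: sum of all member-pair weights, per sign slot.

    ``out.loc[A, B]`` sums every factor-level weight from a member of A to a
    member of B; the diagonal holds each category's self-loop (sum of its
    intra-category links).  Sums can exceed 1 — the result is on the
    category scale (``out.attrs["scale"]``) and must not be fed back into
    closure without explicit renormalization.
    """
    W, factors = _member_matrix(cat, slot)
    out = pd.DataFrame(0.0, index=cat.categories, columns=cat.categories)
    for a in cat.categories:
        for b in cat.categories:
            out.loc[a, b] = float(W.loc[cat.members[a], cat.members[b]].to_numpy().sum())
    out.attrs.update(level="category", scale="category-sum", slot=slot)
    return out


def aggregate(
    cat: Categorization,
    slot: str = "plus",
    *,
    relevance: bool | dict[str, float] = False,
    include_diagonal: bool = True,
) -> pd.DataFrame:
    """Average category influence over all possible member pairs.

    Unweighted, ``out.loc[A, B]`` divides the summed member-pair weights by
    ``|A| * |B|`` (absent links count as zero), so values stay in [0, 1]; a
    self-loop divides by ``|A|^2``, consistent with the whole-map k^2
    convention.  With ``include_diagonal=False`` the self-loop denominator
    excludes the |A| diagonal cells (``|A|^2 - |A|``).

    With relevance weighting each term is multiplied by
    ``r(origin) * r(landing)`` and the denominator is the sum of those
    products over the counted member pairs; ``relevance=True`` takes r from
    the category scheme, or pass an explicit ``{factor: r}`` mapping.
    """
    W, _factors = _member_matrix(cat, slot)
    if relevance is True:
        rel = {f: cat.scheme.relevance_of(f) for f in cat.source.factors}
    elif relevance:
        rel = {f: float(relevance.get(f, 1.0)) for f in cat.source.factors}
    else:
        rel = None
    out = pd.DataFrame(0.0, index=cat.categories, columns=cat.categories)
    for a in cat.categories:
        for b in cat.categories:
            ma, mb = cat.members[a], cat.members[b]
            num = den = 0.0
            for i in ma:
                for j in mb:
                    if a == b and i == j and not include_diagonal:
                        continue
                    r = 1.0 if rel is None else rel[i] * rel[j]
                    num += r * float(W.loc[i, j])
                    den += r
            if den <= 0:
                if a == b and not include_diagonal and len(ma) == 1:
                    out.loc[a, b] = 0.0  # singleton self-loop has no off-diagonal pairs
                    continue
                raise ValidationError(f"zero total relevance for category pair ({a!r}, {b!r})")
            out.loc[a, b] = num / den
    out.attrs.update(level="category", scale="unit", slot=slot)
    return out


def restrict(
    obj: ConceptMap | pd.DataFrame,
    rule: str = "top_k",
    *,
    k: int | None = None,
    threshold: float | None = None,
    per: str = "whole-map",
) -> tuple[ConceptMap | pd.DataFrame, pd.DataFrame]:
    """Keep only the strongest links; return ``(reduced, audit)``.

    ``rule="top_k"`` retains the k largest |weight| links (ties at the cut
    are retained together, so the count may exceed k); ``rule="threshold"``
    retains links with |weight| >= threshold.  ``per="per-outcome"`` applies
    the rule separately to each landing factor's incoming links.  The audit
    table lists every input link with a ``retained`` flag, so nothing
    disappears silently.
    """
    if isinstance(obj, ConceptMap):
        rows = [
            {"origin": i, "landing": j, "weight": s * w, "abs_weight": w}
            for i, j, s, w in obj.links()
        ]
    else:
        rows = [
            {"origin": i, "landing": j, "weight": float(obj.loc[i, j]),
             "abs_weight": abs(float(obj.loc[i, j]))}
            for i in obj.index for j in obj.columns
            if abs(float(obj.loc[i, j])) > TOL
        ]
    audit = pd.DataFrame(rows, columns=["origin", "landing", "weight", "abs_weight"])
    audit = audit.sort_values(["abs_weight", "origin", "landing"],
                              ascending=[False, True, True]).reset_index(drop=True)

    if rule == "top_k":
        if not k or k < 1:
            raise ValidationError("top_k rule needs k >= 1")

        def keep(group: pd.DataFrame) -> pd.Series:
            if len(group) <= k:
                return pd.Series(True, index=group.index)
            cut = group["abs_weight"].nlargest(k).iloc[-1]
            return group["abs_weight"] >= cut - TOL

    elif rule == "threshold":
        if threshold is None or not (0 < threshold <= 1):
            raise ValidationError("threshold rule needs threshold in (0, 1]")

        def keep(group: pd.DataFrame) -> pd.Series:
            return group["abs_weight"] >= threshold - TOL

    else:
        raise ValidationError(f"unknown rule {rule!r}")

    if audit.empty:
        audit["retained"] = pd.Series(dtype=bool)
    elif per == "per-outcome":
        audit["retained"] = audit.groupby("landing", group_keys=False).apply(
            keep, include_groups=False
        ).reindex(audit.index)
    elif per == "whole-map":
        audit["retained"] = keep(audit)
    else:
        raise ValidationError(f"unknown per={per!r}")

    kept = audit[audit["retained"]]
    if isinstance(obj, ConceptMap):
        reduced = ConceptMap(obj.factors, level=obj.level, outcome=obj.outcome,
                             provenance=obj.provenance)
        for _, r in kept.iterrows():
            reduced.add_link(r["origin"], r["landing"], r["weight"])
        return reduced, audit
    red = obj.copy() * 0.0
    for _, r in kept.iterrows():
        red.loc[r["origin"], r["landing"]] = r["weight"]
    red.attrs.update(obj.attrs)
    return red, audit
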