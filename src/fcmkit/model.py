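"""Core data model for bipolar fuzzy cognitive maps.

A fuzzy cognitive map (FCM) is a directed graph of causal beliefs: *factors*
(nodes) connected by weighted arrows expressing how strongly map authors
perceive one factor to influence another.  Weights are elicited on a 1-5
scale with sign (an increase in the cause increases or decreases the effect)
and scaled to [0, 1] for computation; an unreported relationship is exactly
zero.

Weights are stored *bipolar*: every ordered factor pair carries a positive
magnitude ``wplus`` and a negative magnitude ``wminus``, both in [0, 1].
This mirrors the positive/negative transitive-closure matrices (TC+/TC-)
downstream and lets merged maps carry conflicting signs for the same pair.
"""

from __future__ import annotations

import json
import math
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: absolute tolerance for all weight comparisons
TOL = 1e-9

#: decimal places used when serialising weights
PRECISION = 6


class ValidationError(ValueError):
    """Raised when map content violates a model invariant."""


class MapFormatError(ValueError):
    """Raised when an input file cannot be parsed as a map."""


def normalize_label(label: str) -> str:
    """Canonical factor identity: Unicode NFC plus whitespace trimming.

    No fuzzy matching happens at this layer; semantic harmonisation of
    labels is the lexicon's job (:mod:`fcmkit.standardize`).
    """
    return unicodedata.normalize("NFC", str(label)).strip()


# ---------------------------------------------------------------------------
# Raw (elicitation-scale) maps
# ---------------------------------------------------------------------------


@dataclass
class RawEdge:
    """One elicited causal link with its raw signed weight in {-5..-1, 1..5}."""

    origin: str
    landing: str
    weight: int
    note: str = ""


@dataclass
class RawMap:
    """A map as recorded in a mapping session, before scaling to [0, 1].

    Raw weights are nonzero signed integers with absolute value at most 5.
    Whether the elicitation recorded sign together with the 1-5 magnitude or
    separately is session-dependent; the signed-integer convention here
    accommodates both, and ``notes`` can record which was used.
    """

    edges: list[RawEdge] = field(default_factory=list)
    provenance: str = ""
    notes: str = ""

    def add(self, origin: str, landing: str, weight: int, note: str = "") -> None:
        self.edges.append(RawEdge(normalize_label(origin), normalize_label(landing), weight, note))

    @property
    def factors(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.origin)
            seen.setdefault(e.landing)
        return list(seen)

    def validate(self) -> None:
        for e in self.edges:
            w = e.weight
            if not float(w).is_integer() or w == 0 or abs(w) > 5:
                raise ValidationError(
                    f"raw weight must be a nonzero integer with |w| <= 5; "
                    f"edge ({e.origin!r} -> {e.landing!r}) has weight {w!r}"
                )


def scale_raw(raw: RawMap, levels: int = 5) -> "ConceptMap":
    """Scale a raw 1-5 map to fuzzy magnitudes in [0, 1].

    Scaling is linear, ``|weight| / levels``, preserving the equal spacing of
    the elicitation scale.  Sign routes the magnitude to the positive or
    negative slot.  Parallel duplicate raw edges of equal sign collapse to
    the maximum magnitude (the strongest statement of the link wins).
    """
    raw.validate()
    cmap = ConceptMap(provenance=raw.provenance)
    for e in raw.edges:
        cmap.add_factor(e.origin)
        cmap.add_factor(e.landing)
    for e in raw.edges:
        mag = abs(e.weight) / levels
        slot = "plus" if e.weight > 0 else "minus"
        cmap.strengthen_link(e.origin, e.landing, mag, slot)
    return cmap


# ---------------------------------------------------------------------------
# Scaled concept maps
# ---------------------------------------------------------------------------


class ConceptMap:
    """Directed graph over labelled factors with bipolar weights in [0, 1].

    Parameters
    ----------
    factors :
        Initial ordered collection of factor labels (optional; factors are
        also added implicitly by :meth:`add_link`).
    level :
        ``"factor"`` (default) or ``"category"``.  Self-links are permitted
        only at category level, where a category's internal factor-level
        dynamics appear as a self-loop.
    outcome :
        Optional labels of designated outcome factor(s).
    provenance :
        Free-text source tag (stakeholder group, session id).
    """

    def __init__(
        self,
        factors: Iterable[str] = (),
        *,
        level: str = "factor",
        outcome: Iterable[str] = (),
        provenance: str = "",
    ) -> None:
        if level not in ("factor", "category"):
            raise ValidationError(f"level must be 'factor' or 'category', got {level!r}")
        self.level = level
        self.provenance = provenance
        self.closed = False  # set on maps rebuilt from a transitive closure
        self._factors: dict[str, None] = {}
        self._plus: dict[tuple[str, str], float] = {}
        self._minus: dict[tuple[str, str], float] = {}
        for f in factors:
            self.add_factor(f)
        self.outcome: set[str] = set()
        for o in outcome:
            o = normalize_label(o)
            self.add_factor(o)
            self.outcome.add(o)

    # -- structure ----------------------------------------------------------

    @property
    def factors(self) -> list[str]:
        return list(self._factors)

    @property
    def k(self) -> int:
        return len(self._factors)

    def add_factor(self, label: str) -> str:
        label = normalize_label(label)
        if not label:
            raise ValidationError("factor label must be non-empty")
        self._factors.setdefault(label)
        return label

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in self._factors

    def _check_pair(self, origin: str, landing: str) -> tuple[str, str]:
        origin = self.add_factor(origin)
        landing = self.add_factor(landing)
        if origin == landing and self.level == "factor":
            raise ValidationError(
                f"self-link on {origin!r}: self-links are permitted only on category-level maps"
            )
        return origin, landing

    @staticmethod
    def _check_mag(mag: float) -> float:
        mag = float(mag)
        if not (-TOL <= mag <= 1 + TOL):
            raise ValidationError(f"magnitude {mag} outside [0, 1]")
        return min(max(mag, 0.0), 1.0)

    def set_link(
        self,
        origin: str,
        landing: str,
        *,
        wplus: float | None = None,
        wminus: float | None = None,
    ) -> None:
        """Set one or both sign-slots of an ordered pair (0 removes the slot)."""
        origin, landing = self._check_pair(origin, landing)
        for slot, store in (("plus", self._plus), ("minus", self._minus)):
            val = wplus if slot == "plus" else wminus
            if val is None:
                continue
            val = self._check_mag(val)
            if val <= TOL:
                store.pop((origin, landing), None)
            else:
                store[(origin, landing)] = val

    def add_link(self, origin: str, landing: str, weight: float) -> None:
        """Add a signed link: positive weight fills ``wplus``, negative ``wminus``."""
        w = float(weight)
        if w >= 0:
            self.set_link(origin, landing, wplus=w)
        else:
            self.set_link(origin, landing, wminus=-w)

    def strengthen_link(self, origin: str, landing: str, mag: float, slot: str) -> None:
        """Keep the maximum of the existing and the new magnitude in a slot."""
        origin, landing = self._check_pair(origin, landing)
        mag = self._check_mag(mag)
        store = self._plus if slot == "plus" else self._minus
        if mag > store.get((origin, landing), 0.0):
            store[(origin, landing)] = mag

    # -- queries ------------------------------------------------------------

    def wplus(self, origin: str, landing: str) -> float:
        return self._plus.get((normalize_label(origin), normalize_label(landing)), 0.0)

    def wminus(self, origin: str, landing: str) -> float:
        return self._minus.get((normalize_label(origin), normalize_label(landing)), 0.0)

    def net(self, origin: str, landing: str) -> float:
        return self.wplus(origin, landing) - self.wminus(origin, landing)

    def links(self) -> Iterator[tuple[str, str, int, float]]:
        """Iterate sign-specific links as ``(origin, landing, sign, magnitude)``."""
        for (i, j), w in self._plus.items():
            yield i, j, +1, w
        for (i, j), w in self._minus.items():
            yield i, j, -1, w

    @property
    def n_links(self) -> int:
        return len(self._plus) + len(self._minus)

    # -- matrix views -------------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Positive and negative magnitude matrices (origin rows, landing cols)."""
        idx = self.factors
        plus = pd.DataFrame(0.0, index=idx, columns=idx)
        minus = pd.DataFrame(0.0, index=idx, columns=idx)
        for (i, j), w in self._plus.items():
            plus.loc[i, j] = w
        for (i, j), w in self._minus.items():
            minus.loc[i, j] = w
        return plus, minus

    def net_frame(self) -> pd.DataFrame:
        plus, minus = self.to_frames()
        return plus - minus

    def signed_frame(self) -> pd.DataFrame:
        """Single signed adjacency matrix.

        Raises if any pair carries both signs, which a single signed number
        cannot represent; use :meth:`to_frames` for such maps.
        """
        both = set(self._plus) & set(self._minus)
        if both:
            raise ValidationError(
                f"{len(both)} pair(s) carry both signs (e.g. {sorted(both)[0]}); "
                "a single signed adjacency matrix cannot represent them"
            )
        return self.net_frame()

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, *, level: str = "factor", provenance: str = ""
    ) -> "ConceptMap":
        """Build a map from a signed adjacency matrix (rows = origins)."""
        if list(frame.index) != list(frame.columns):
            raise MapFormatError("adjacency matrix row and column labels must match")
        cmap = cls(frame.index, level=level, provenance=provenance)
        for i in frame.index:
            for j in frame.columns:
                w = float(frame.loc[i, j])
                if abs(w) > TOL:
                    cmap.add_link(i, j, w)
        return cmap

    # -- equality & serialisation -------------------------------------------

    def equals(self, other: "ConceptMap", tol: float = TOL) -> bool:
        if set(self._factors) != set(other._factors):
            return False
        pairs = set(self._plus) | set(self._minus) | set(other._plus) | set(other._minus)
        return all(
            math.isclose(self.wplus(i, j), other.wplus(i, j), abs_tol=tol)
            and math.isclose(self.wminus(i, j), other.wminus(i, j), abs_tol=tol)
            for i, j in pairs
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - delegates
        return isinstance(other, ConceptMap) and self.equals(other)

    def copy(self) -> "ConceptMap":
        new = ConceptMap(
            self.factors, level=self.level, outcome=self.outcome, provenance=self.provenance
        )
        new._plus = dict(self._plus)
        new._minus = dict(self._minus)
        new.closed = self.closed
        return new

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "provenance": self.provenance,
            "factors": self.factors,
            "outcome": sorted(self.outcome),
            "links": [
                {"origin": i, "landing": j, "sign": s, "weight": round(w, PRECISION)}
                for i, j, s, w in self.links()
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ConceptMap":
        cmap = cls(
            data.get("factors", ()),
            level=data.get("level", "factor"),
            outcome=data.get("outcome", ()),
            provenance=data.get("provenance", ""),
        )
        for link in data.get("links", ()):
            slot = "plus" if link["sign"] > 0 else "minus"
            cmap.strengthen_link(link["origin"], link["landing"], link["weight"], slot)
        return cmap

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<ConceptMap level={self.level} k={self.k} links={self.n_links}"
            f"{' provenance=' + self.provenance if self.provenance else ''}>"
        )


# ---------------------------------------------------------------------------
# Map summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MapStats:
    """Size summary of a map: factor count, sign-specific link count,
    density and the fraction of links that are negative."""

    k: int
    n_links: int
    density: float
    negative_fraction: float


def map_stats(cmap: ConceptMap) -> MapStats:
    """Summarise a map; each sign-specific link counts individually.

    Density divides by the number of possible ordered pairs: ``k(k-1)`` at
    factor level (no self-links) and ``k^2`` at category level.
    """
    k = cmap.k
    n = cmap.n_links
    possible = k * k if cmap.level == "category" else k * (k - 1)
    n_neg = sum(1 for *_ij, s, _w in cmap.links() if s < 0)
    return MapStats(
        k=k,
        n_links=n,
        density=n / possible if possible else 0.0,
        negative_fraction=n_neg / n if n else 0.0,
    )


# ---------------------------------------------------------------------------
# Lexicon and category scheme
# ---------------------------------------------------------------------------


class Lexicon:
    """Raw label -> (standard code, standard label) dictionary.

    Entries may optionally be qualified by knowledge source, because the
    same raw phrase can legitimately mean different things in different
    communities.  Within one source every raw label maps to exactly one
    code.  ``decisions_log`` accumulates free-text assumptions made while
    reconciling meanings, for transparency.
    """

    def __init__(self) -> None:
        # keyed by (source or None, normalized raw label)
        self._entries: dict[tuple[str | None, str], tuple[str, str]] = {}
        self._code_to_label: dict[str, str] = {}
        self.decisions_log: list[str] = []

    def add(
        self, raw: str, code: str, standard_label: str = "", *, source: str | None = None
    ) -> None:
        raw = normalize_label(raw)
        code = normalize_label(code)
        standard_label = normalize_label(standard_label) or code
        key = (source, raw)
        if key in self._entries and self._entries[key][0] != code:
            raise ValidationError(
                f"raw label {raw!r} already mapped to {self._entries[key][0]!r}, "
                f"cannot remap to {code!r} (source={source!r})"
            )
        known = self._code_to_label.get(code)
        if known is not None and known != standard_label:
            raise ValidationError(
                f"code {code!r} already bound to label {known!r}, got {standard_label!r}"
            )
        self._entries[key] = (code, standard_label)
        self._code_to_label[code] = standard_label

    def lookup(self, raw: str, *, source: str | None = None) -> tuple[str, str] | None:
        """Resolve a raw label; source-qualified entries take precedence."""
        raw = normalize_label(raw)
        if source is not None and (source, raw) in self._entries:
            return self._entries[(source, raw)]
        return self._entries.get((None, raw))

    def label_for(self, code: str) -> str | None:
        return self._code_to_label.get(normalize_label(code))

    @property
    def codes(self) -> list[str]:
        return list(self._code_to_label)

    def __len__(self) -> int:
        return len(self._entries)

    def log(self, message: str) -> None:
        self.decisions_log.append(message)

    # CSV round trip: raw_label,standard_code,standard_label[,source]
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"raw_label": raw, "standard_code": code, "standard_label": lbl, "source": src or ""}
            for (src, raw), (code, lbl) in self._entries.items()
        ]
        return pd.DataFrame(rows, columns=["raw_label", "standard_code", "standard_label", "source"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Lexicon":
        required = {"raw_label", "standard_code"}
        if not required.issubset(frame.columns):
            raise MapFormatError(f"lexicon table needs columns {sorted(required)}")
        lex = cls()
        for _, row in frame.iterrows():
            src = row.get("source") or None
            if isinstance(src, float) and math.isnan(src):
                src = None
            lex.add(
                row["raw_label"],
                row["standard_code"],
                row.get("standard_label", "") or "",
                source=src,
            )
        return lex


class CategoryScheme:
    """Assignment of standard factors to categories, with optional relevance.

    Every categorised factor belongs to exactly one category.  Relevance
    factors are strictly positive multipliers (default 1) that up-weight more
    important factors in weighted aggregation.
    """

    def __init__(self) -> None:
        self._assignment: dict[str, str] = {}
        self._relevance: dict[str, float] = {}

    def assign(self, factor: str, category: str, relevance: float = 1.0) -> None:
        factor = normalize_label(factor)
        category = normalize_label(category)
        if relevance <= 0:
            raise ValidationError(f"relevance factor for {factor!r} must be > 0, got {relevance}")
        if factor in self._assignment and self._assignment[factor] != category:
            raise ValidationError(
                f"factor {factor!r} already assigned to {self._assignment[factor]!r}"
            )
        self._assignment[factor] = category
        self._relevance[factor] = float(relevance)

    def category_of(self, factor: str) -> str | None:
        return self._assignment.get(normalize_label(factor))

    def relevance_of(self, factor: str) -> float:
        return self._relevance.get(normalize_label(factor), 1.0)

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for cat in self._assignment.values():
            seen.setdefault(cat)
        return list(seen)

    def members(self, category: str) -> list[str]:
        category = normalize_label(category)
        return [f for f, c in self._assignment.items() if c == category]

    def __len__(self) -> int:
        return len(self._assignment)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"standard_code": f, "category": c, "relevance": self._relevance[f]}
            for f, c in self._assignment.items()
        ]
        return pd.DataFrame(rows, columns=["standard_code", "category", "relevance"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CategoryScheme":
        if not {"standard_code", "category"}.issubset(frame.columns):
            raise MapFormatError("category scheme needs columns standard_code, category")
        scheme = cls()
        for _, row in frame.iterrows():
            rel = row.get("relevance", 1.0)
            if rel is None or (isinstance(rel, float) and math.isnan(rel)):
                rel = 1.0
            scheme.assign(row["standard_code"], row["category"], float(rel))
        return scheme


# ---------------------------------------------------------------------------
# Walks and disagreement reports (filled by fcmkit.closure)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Walk:
    """A chain of linked factors through which influence propagates.

    ``sign`` is the product of traversed link signs (+1 for an even number
    of negative links, -1 for odd); ``weight`` is the walk's value under the
    closure rule that produced it (min magnitude for fuzzy closure).
    """

    nodes: tuple[str, ...]
    sign: int
    weight: float

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class DisagreementReport:
    """Average degree of disagreement between two knowledge sources.

    ``dbar`` is the mean absolute difference of net transitive-closure
    weights over the N compared links; it lies in [0, 2], reaching 2 only
    when one source puts +1 and the other -1 on every compared link.
    ``dbar_normalized`` divides by that maximum.  ``whole_map_value`` (when
    computed) divides the summed differences by k^2, the number of cells in
    the adjacency matrix over the union factor set.
    """

    dbar: float
    n_compared: int
    dbar_normalized: float
    per_link: pd.DataFrame
    whole_map_value: float | None = None
    scope: str = "outcome"

    def rounded(self, decimals: int = 1) -> float:
        """Display-rounded d-bar; rounding never happens inside computation."""
        return round(self.dbar, decimals)
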