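"""Seeded generators of synthetic stakeholder maps.

These emulate the elicitation conditions of a mapping session: signed 1-5
weights, unreported links equal to zero, a group of 12 maps or so per
stakeholder group (map building typically saturates at 12-15 maps), and
label drift between sessions that standardization must undo.  All
generators are pure functions of their parameters and seed (numpy
``default_rng``; no global state).
"""

from __future__ import annotations

import numpy as np

from .model import ConceptMap, Lexicon, RawMap, ValidationError

__all__ = ["generate_map", "generate_group", "generate_pair_with_disagreement"]

DEFAULT_GROUP_SIZE = 12


def generate_map(
    k: int,
    density: float = 0.3,
    neg_prob: float = 0.2,
    weight_levels: int = 5,
    *,
    seed: int,
) -> RawMap:
    """One synthetic raw map on ``k`` factors.

    Every ordered non-self pair receives a link with probability
    ``density``; its raw magnitude is uniform on {1..weight_levels} and its
    sign is negative with probability ``neg_prob``.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if not (0 < density <= 1):
        raise ValidationError("density must be in (0, 1]")
    if not (0 <= neg_prob <= 1):
        raise ValidationError("neg_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = [f"N{i + 1:02d}" for i in range(k)]
    rmap = RawMap(provenance=f"synthetic:seed={seed}")
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            if rng.random() < density:
                mag = int(rng.integers(1, weight_levels + 1))
                sign = -1 if rng.random() < neg_prob else 1
                rmap.add(labels[a], labels[b], sign * mag)
    return rmap


def generate_group(
    base_map: RawMap,
    n_maps: int = DEFAULT_GROUP_SIZE,
    drop_prob: float = 0.1,
    jitter_levels: int = 1,
    synonym_rate: float = 0.0,
    *,
    seed: int,
) -> tuple[list[RawMap], Lexicon]:
    """A family of maps from one stakeholder group, plus its ground-truth lexicon.

    Each member map independently drops links (``drop_prob``), jitters raw
    magnitudes by up to ``jitter_levels`` (clipped to 1..5; sign preserved)
    and rewrites a fraction ``synonym_rate`` of its labels with generated
    synonyms.  The returned lexicon maps every synonym (and every base
    label) back to the base label, so ``apply_lexicon`` recovers the shared
    label space exactly.
    """
    if n_maps < 1:
        raise ValidationError("n_maps must be >= 1")
    for name, r, hi in (("drop_prob", drop_prob, 1), ("synonym_rate", synonym_rate, 1)):
        if not (0 <= r <= hi):
            raise ValidationError(f"{name} must be in [0, 1]")
    if jitter_levels < 0:
        raise ValidationError("jitter_levels must be >= 0")
    rng = np.random.default_rng(seed)
    lexicon = Lexicon()
    for f in base_map.factors:
        lexicon.add(f, f, f)
    maps: list[RawMap] = []
    for m in range(n_maps):
        rename: dict[str, str] = {}
        for f in base_map.factors:
            if rng.random() < synonym_rate:
                syn = f"{f}~v{m + 1}"
                rename[f] = syn
                lexicon.add(syn, f, f)
        rmap = RawMap(provenance=f"{base_map.provenance}:member{m + 1}")
        for e in base_map.edges:
            if rng.random() < drop_prob:
                continue
            mag = abs(e.weight)
            if jitter_levels:
                mag = int(np.clip(mag + rng.integers(-jitter_levels, jitter_levels + 1), 1, 5))
            sign = 1 if e.weight > 0 else -1
            rmap.add(rename.get(e.origin, e.origin), rename.get(e.landing, e.landing), sign * mag)
        maps.append(rmap)
    return maps, lexicon


def generate_pair_with_disagreement(
    k: int, target_dbar: float, *, seed: int
) -> tuple[ConceptMap, ConceptMap]:
    """Two maps over a shared factor set with a prescribed disagreement.

    Builds a star into a designated outcome: every other factor links to it
    in both maps, with net weights chosen so each link's |d| equals the
    target exactly (positive weight ``min(1, t)`` on one side, the remainder
    as a negative weight on the other), hence d-bar = target by
    construction.  The seed shuffles factor order only.
    """
    if not (0 <= target_dbar <= 2):
        raise ValidationError("target_dbar must be in [0, 2]")
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    labels = [f"N{i + 1:02d}" for i in range(k - 1)]
    rng.shuffle(labels)
    outcome = "OUT"
    a = ConceptMap(labels, outcome=[outcome], provenance="pair-A")
    b = ConceptMap(labels, outcome=[outcome], provenance="pair-B")
    t = float(target_dbar)
    wa = min(1.0, t) if t > 0 else 0.5
    wb = (wa - t) if t > 0 else 0.5  # negative value routes to the minus slot
    for f in labels:
        a.add_link(f, outcome, wa)
        b.add_link(f, outcome, wb)
    return a, b
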