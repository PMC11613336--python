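import numpy as np
import pytest

from fcmkit import ConceptMap, scale_raw
from fcmkit.synth import generate_map


def random_concept_map(seed: int, k: int = 5, density: float = 0.4,
                       neg_prob: float = 0.3) -> ConceptMap:
    """Seeded random scaled map used across the property suites."""
    return scale_raw(generate_map(k, density, neg_prob, seed=seed))


@pytest.fixture
def chain_map() -> ConceptMap:
    """A -> B (0.5) -> C (0.8): the canonical min-rule example."""
    m = ConceptMap()
    m.add_link("A", "B", 0.5)
    m.add_link("B", "C", 0.8)
    return m


@pytest.fixture
def mixed_sign_map() -> ConceptMap:
    """A->B +0.6, B->C -0.9, direct A->C -0.3: the indirect negative walk
    (min 0.6) beats the direct negative link."""
    m = ConceptMap()
    m.add_link("A", "B", 0.6)
    m.add_link("B", "C", -0.9)
    m.add_link("A", "C", -0.3)
    return m
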