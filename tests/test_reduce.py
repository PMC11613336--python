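"""Categorization, condensation, aggregation and restriction."""

import numpy as np
import pytest

from fcmkit import (
    CategoryScheme,
    ConceptMap,
    ValidationError,
    aggregate,
    categorize,
    condense,
    restrict,
)
from fcmkit.datasets import midwife_categories
from conftest import random_concept_map


@pytest.fixture
def two_cat():
    """A={f1,f2}, B={f3} with f1->f3 0.4, f2->f3 0.3, intra link f1->f2 0.5."""
    m = ConceptMap()
    m.add_link("f1", "f3", 0.4)
    m.add_link("f2", "f3", 0.3)
    m.add_link("f1", "f2", 0.5)
    scheme = CategoryScheme()
    scheme.assign("f1", "A", 2.0)
    scheme.assign("f2", "A", 1.0)
    scheme.assign("f3", "B", 1.0)
    return categorize(m, scheme)


class TestCategorize:
    def test_bundled_scheme_has_twelve_categories(self):
        scheme = midwife_categories()
        m = ConceptMap([f"F{i}" for i in range(1, 23)])
        cat = categorize(m, scheme)
        assert cat.k == 12

    def test_identity_categorization_isomorphic(self):
        m = random_concept_map(4, k=5, density=0.5, neg_prob=0.3)
        scheme = CategoryScheme()
        for f in m.factors:
            scheme.assign(f, f"cat:{f}")
        cat = categorize(m, scheme)
        sk = cat.category_map()
        assert sk.k == m.k
        for i, j, s, w in m.links():
            getter = sk.wplus if s > 0 else sk.wminus
            assert getter(f"cat:{i}", f"cat:{j}") == pytest.approx(w)

    def test_intra_category_link_becomes_self_loop(self, two_cat):
        sk = two_cat.category_map()
        assert sk.wplus("A", "A") == pytest.approx(0.5)

    def test_unassigned_factor_strict_raises(self):
        m = ConceptMap(["f1", "loose"])
        scheme = CategoryScheme()
        scheme.assign("f1", "A")
        with pytest.raises(ValidationError, match="loose"):
            categorize(m, scheme)
        cat = categorize(m, scheme, uncategorized_bucket="other")
        assert "other" in cat.categories

    def test_drill_down_recovers_subgraph(self, two_cat):
        sub = two_cat.drill_down("A")
        assert set(sub.factors) == {"f1", "f2"}
        assert sub.wplus("f1", "f2") == pytest.approx(0.5)
        assert sub.n_links == 1


class TestCondense:
    def test_sum_rule(self, two_cat):
        mat = condense(two_cat, "plus")
        assert mat.loc["A", "B"] == pytest.approx(0.7)
        assert mat.loc["A", "A"] == pytest.approx(0.5)  # self-loop
        assert mat.loc["B", "A"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("slot", ["plus", "minus"])
    def test_conservation_per_sign_slot(self, seed, slot):
        m = random_concept_map(seed, k=6, density=0.5, neg_prob=0.4)
        scheme = CategoryScheme()
        for idx, f in enumerate(m.factors):
            scheme.assign(f, f"C{idx % 3}")
        mat = condense(categorize(m, scheme), slot)
        plus, minus = m.to_frames()
        factor_total = (plus if slot == "plus" else minus).to_numpy().sum()
        assert mat.to_numpy().sum() == pytest.approx(factor_total)

    def test_marked_category_scale(self, two_cat):
        mat = condense(two_cat, "plus")
        assert mat.attrs["scale"] == "category-sum"


class TestAggregate:
    def test_mean_over_possible_pairs(self, two_cat):
        mat = aggregate(two_cat, "plus")
        assert mat.loc["A", "B"] == pytest.approx((0.4 + 0.3) / 2)
        assert mat.loc["A", "A"] == pytest.approx(0.5 / 4)  # |A|^2 denominator

    def test_weighted_mean_with_relevance(self, two_cat):
        # r(f1)=2, r(f2)=1: (2*0.4 + 1*0.3) / (2 + 1), r(f3)=1
        mat = aggregate(two_cat, "plus", relevance=True)
        assert mat.loc["A", "B"] == pytest.approx((2 * 0.4 + 1 * 0.3) / 3)

    def test_single_member_categories_equal_factor_level(self):
        m = ConceptMap()
        m.add_link("f1", "f2", 0.4)
        scheme = CategoryScheme()
        scheme.assign("f1", "A")
        scheme.assign("f2", "B")
        mat = aggregate(categorize(m, scheme), "plus")
        assert mat.loc["A", "B"] == pytest.approx(0.4)

    def test_diagonal_switch(self, two_cat):
        mat = aggregate(two_cat, "plus", include_diagonal=False)
        assert mat.loc["A", "A"] == pytest.approx(0.5 / 2)  # |A|^2 - |A| = 2

    @pytest.mark.parametrize("seed", range(4))
    def test_bounded_by_condense_and_unit(self, seed):
        m = random_concept_map(seed, k=6, density=0.6, neg_prob=0.3)
        scheme = CategoryScheme()
        for idx, f in enumerate(m.factors):
            scheme.assign(f, f"C{idx % 2}")
        cat = categorize(m, scheme)
        agg = aggregate(cat, "plus").to_numpy()
        con = condense(cat, "plus").to_numpy()
        assert (agg <= con + 1e-9).all()
        assert ((agg >= 0) & (agg <= 1)).all()


class TestRestrict:
    def test_top_k_keeps_strongest(self):
        m = random_concept_map(7, k=6, density=0.6, neg_prob=0.3)
        reduced, audit = restrict(m, "top_k", k=5)
        assert reduced.n_links >= min(5, m.n_links)
        kept = audit[audit["retained"]]
        dropped = audit[~audit["retained"]]
        if not dropped.empty:
            assert kept["abs_weight"].min() >= dropped["abs_weight"].max() - 1e-9
        # audit covers the input exactly
        assert len(audit) == m.n_links

    def test_ties_retained_together(self):
        m = ConceptMap()
        for j, lbl in enumerate(["B", "C", "D"]):
            m.add_link("A", lbl, 0.6)
        reduced, audit = restrict(m, "top_k", k=1)
        assert reduced.n_links == 3  # all tied at the cut

    def test_top_k_at_least_link_count_is_identity(self):
        m = random_concept_map(8, k=5, density=0.5)
        reduced, _ = restrict(m, "top_k", k=m.n_links + 5)
        assert reduced.equals(m)

    def test_threshold_above_max_empties_map(self):
        m = ConceptMap()
        m.add_link("A", "B", 0.9)
        reduced, audit = restrict(m, "threshold", threshold=1.0)
        assert reduced.n_links == 0
        assert len(audit) == 1 and not audit["retained"].any()

    def test_per_outcome_rule(self):
        m = ConceptMap()
        m.add_link("A", "Out1", 0.9)
        m.add_link("B", "Out1", 0.2)
        m.add_link("C", "Out2", 0.1)
        reduced, _ = restrict(m, "top_k", k=1, per="per-outcome")
        assert reduced.wplus("A", "Out1") > 0
        assert reduced.wplus("B", "Out1") == 0
        assert reduced.wplus("C", "Out2") > 0  # best of its own outcome

    def test_matrix_input_round_trip(self, two_cat):
        mat = condense(two_cat, "plus")
        red, audit = restrict(mat, "threshold", threshold=0.5)
        assert red.loc["A", "B"] == pytest.approx(0.7)
        assert red.loc["A", "A"] == pytest.approx(0.5)
        assert set(audit.columns) >= {"origin", "landing", "weight", "retained"}
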