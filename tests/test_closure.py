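"""Fuzzy and probabilistic closure, witness walks, disagreement, Harris weights."""

import numpy as np
import pandas as pd
import pytest

from fcmkit import (
    ConceptMap,
    ValidationError,
    compare_weighting,
    disagreement,
    fuzzy_closure,
    harris_weights,
    net_tc,
    probabilistic_closure,
    strongest_walks,
)
from conftest import random_concept_map
from oracles import dbar_oracle, fuzzy_tc_oracle, prob_tc_oracle


class TestFuzzyClosure:
    def test_single_link(self):
        m = ConceptMap()
        m.add_link("A", "B", 0.7)
        res = fuzzy_closure(m)
        assert res.tc_plus.loc["A", "B"] == pytest.approx(0.7)
        assert res.tc_minus.loc["A", "B"] == 0.0

    def test_chain_min_rule(self, chain_map):
        res = fuzzy_closure(chain_map)
        assert res.tc_plus.loc["A", "C"] == pytest.approx(0.5)

    def test_indirect_negative_beats_direct(self, mixed_sign_map):
        # frozen from the walk-enumeration oracle on this 3-node instance
        res = fuzzy_closure(mixed_sign_map)
        assert res.tc_minus.loc["A", "C"] == pytest.approx(0.6)
        tcp, tcm = fuzzy_tc_oracle(mixed_sign_map)
        assert np.allclose(res.tc_plus.to_numpy(), tcp)
        assert np.allclose(res.tc_minus.to_numpy(), tcm)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_walk_enumeration_oracle(self, seed):
        m = random_concept_map(seed, k=3 + seed % 4, density=0.5, neg_prob=0.4)
        res = fuzzy_closure(m)
        tcp, tcm = fuzzy_tc_oracle(m)
        assert np.allclose(res.tc_plus.to_numpy(), tcp, atol=1e-9)
        assert np.allclose(res.tc_minus.to_numpy(), tcm, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent_and_dominant(self, seed):
        m = random_concept_map(seed, k=5, density=0.5, neg_prob=0.3)
        res = fuzzy_closure(m)
        # closure never loses a direct link
        plus, minus = m.to_frames()
        assert (res.tc_plus.to_numpy() >= plus.to_numpy() - 1e-9).all()
        assert (res.tc_minus.to_numpy() >= minus.to_numpy() - 1e-9).all()
        assert ((res.tc_plus.to_numpy() >= 0) & (res.tc_plus.to_numpy() <= 1)).all()
        # re-closing the closure changes nothing
        again = fuzzy_closure(res.as_map())
        assert np.allclose(res.tc_plus.to_numpy(), again.tc_plus.to_numpy(), atol=1e-9)
        assert np.allclose(res.tc_minus.to_numpy(), again.tc_minus.to_numpy(), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_link_weights(self, seed):
        m = random_concept_map(seed, k=5, density=0.5, neg_prob=0.3)
        links = list(m.links())
        if not links:
            pytest.skip("empty random map")
        before = fuzzy_closure(m)
        i, j, s, w = links[seed % len(links)]
        m.strengthen_link(i, j, min(1.0, w + 0.3), "plus" if s > 0 else "minus")
        after = fuzzy_closure(m)
        assert (after.tc_plus.to_numpy() >= before.tc_plus.to_numpy() - 1e-9).all()
        assert (after.tc_minus.to_numpy() >= before.tc_minus.to_numpy() - 1e-9).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_witness_walks_achieve_their_weight(self, seed):
        m = random_concept_map(seed, k=5, density=0.5, neg_prob=0.4)
        res = fuzzy_closure(m)
        for (i, j, sign), walk in res.witness.items():
            assert walk.nodes[0] == i and walk.nodes[-1] == j
            assert walk.sign == sign
            # every step must offer a link of at least the walk weight, and
            # some choice of step signs must multiply to the walk sign
            attainable = {1}
            for a, b in zip(walk.nodes, walk.nodes[1:]):
                signs = set()
                if m.wplus(a, b) >= walk.weight - 1e-9:
                    signs.add(1)
                if m.wminus(a, b) >= walk.weight - 1e-9:
                    signs.add(-1)
                assert signs, f"step {a}->{b} weaker than walk weight"
                attainable = {p * s for p in attainable for s in signs}
            assert sign in attainable


class TestProbabilisticClosure:
    def test_series_product(self, chain_map):
        res = probabilistic_closure(chain_map)
        assert res.tc_plus.loc["A", "C"] == pytest.approx(0.4)

    def test_parallel_paths_reliability(self):
        # two disjoint 0.5 paths: 1 - (1 - 0.5)^2 = 0.75 (subset-enumeration value)
        m = ConceptMap()
        m.add_link("A", "B", 0.5)
        m.add_link("B", "D", 1.0)
        m.add_link("A", "C", 0.5)
        m.add_link("C", "D", 1.0)
        res = probabilistic_closure(m)
        assert res.tc_plus.loc["A", "D"] == pytest.approx(0.75)
        tcp, _ = prob_tc_oracle(m)
        assert np.allclose(res.tc_plus.to_numpy(), tcp, atol=1e-12)

    def test_single_link(self):
        m = ConceptMap()
        m.add_link("A", "B", 0.3)
        assert probabilistic_closure(m).tc_plus.loc["A", "B"] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_subset_enumeration(self, seed):
        m = random_concept_map(seed, k=4, density=0.5, neg_prob=0.4)
        if m.n_links > 15:
            pytest.skip("oracle limited to 15 links")
        res = probabilistic_closure(m, "exact")
        tcp, tcm = prob_tc_oracle(m)
        assert np.allclose(res.tc_plus.to_numpy(), tcp, atol=1e-9)
        assert np.allclose(res.tc_minus.to_numpy(), tcm, atol=1e-9)

    def test_monte_carlo_within_four_se_of_exact(self):
        m = random_concept_map(11, k=4, density=0.6, neg_prob=0.3)
        exact = probabilistic_closure(m, "exact")
        mc = probabilistic_closure(m, "monte_carlo", samples=20_000, seed=123)
        for name in ("tc_plus", "tc_minus"):
            e = getattr(exact, name).to_numpy()
            est = getattr(mc, name).to_numpy()
            se = mc.mc_meta["se_plus" if name == "tc_plus" else "se_minus"].to_numpy()
            assert (np.abs(est - e) <= 4 * np.maximum(se, 1e-6)).all()

    def test_monte_carlo_requires_seed(self, chain_map):
        with pytest.raises(ValidationError, match="seed"):
            probabilistic_closure(chain_map, "monte_carlo")

    def test_exact_cap_suggests_monte_carlo(self):
        m = random_concept_map(3, k=8, density=0.9, neg_prob=0.2)
        assert m.n_links > 25
        with pytest.raises(ValidationError, match="monte_carlo"):
            probabilistic_closure(m, "exact")

    def test_max_product_reduces_to_strongest_path(self, chain_map):
        chain_map.add_link("A", "C", 0.6)
        res = probabilistic_closure(chain_map, combine="max_product")
        assert res.tc_plus.loc["A", "C"] == pytest.approx(0.6)
        assert res.method == "probabilistic-max-product"


class TestNetTC:
    @pytest.mark.parametrize(
        "wp,wm,expected", [(0.6, 0.0, 0.6), (0.0, 0.5, -0.5), (0.4, 0.4, 0.0)]
    )
    def test_signed_sum(self, wp, wm, expected):
        m = ConceptMap()
        m.set_link("A", "B", wplus=wp, wminus=wm)
        res = fuzzy_closure(m)
        assert net_tc(res).loc["A", "B"] == pytest.approx(expected)


class TestStrongestWalks:
    def test_chain_then_direct(self, chain_map):
        res = fuzzy_closure(chain_map)
        walks = strongest_walks(res, pair=("A", "C"))
        assert walks[0].nodes == ("A", "B", "C")
        assert walks[0].weight == pytest.approx(0.5)
        chain_map.add_link("A", "C", 0.6)
        walks = strongest_walks(fuzzy_closure(chain_map), pair=("A", "C"))
        assert walks[0].nodes == ("A", "C")
        assert walks[0].weight == pytest.approx(0.6)

    def test_outcome_collects_available_walks(self, chain_map):
        res = fuzzy_closure(chain_map)
        walks = strongest_walks(res, outcome="C", top_k=5)
        assert [w.nodes[0] for w in walks] == ["B", "A"]  # sorted by weight

    def test_unreachable_pair_empty(self, chain_map):
        res = fuzzy_closure(chain_map)
        assert strongest_walks(res, pair=("C", "A")) == []


class TestDisagreement:
    def test_identical_maps_zero(self):
        col = pd.Series({"A": 0.4, "B": 0.2})
        rep = disagreement(col, col.copy())
        assert rep.dbar == 0.0
        assert rep.n_compared == 2

    def test_worked_absolute_difference(self):
        # 0.2 in one source vs 0.8 in the other differ by 0.6
        rep = disagreement(pd.Series({"X": 0.2}), pd.Series({"X": 0.8}))
        assert rep.per_link["abs_diff"].iloc[0] == pytest.approx(0.6)

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_maximum_bound_construction(self, k):
        factors = [f"F{i}" for i in range(k)]
        plus = pd.Series(1.0, index=factors)
        minus = pd.Series(-1.0, index=factors)
        rep = disagreement(plus, minus)
        assert rep.dbar == pytest.approx(2.0)
        assert rep.dbar_normalized == pytest.approx(1.0)

    def test_symmetric_and_bounded(self):
        for seed in range(8):
            a = random_concept_map(seed, k=5, density=0.5, neg_prob=0.4)
            b = random_concept_map(seed + 100, k=5, density=0.5, neg_prob=0.4)
            r1 = disagreement(a, b, scope="whole_map")
            r2 = disagreement(b, a, scope="whole_map")
            assert r1.dbar == pytest.approx(r2.dbar)
            assert 0 <= r1.dbar <= 2

    def test_whole_map_uses_k_squared(self):
        a = ConceptMap(["A", "B", "C"])
        a.add_link("A", "B", 1.0)
        b = ConceptMap(["A", "B", "C"])
        rep = disagreement(a, b, scope="whole_map")
        assert rep.whole_map_value == pytest.approx(1.0 / 9)
        assert rep.dbar == pytest.approx(1.0)  # one compared link

    def test_empty_comparison_rejected(self):
        with pytest.raises(ValidationError, match="N = 0"):
            disagreement(pd.Series(dtype=float), pd.Series(dtype=float))

    def test_matches_brute_force(self):
        for seed in range(5):
            a = random_concept_map(seed, k=5, density=0.5, neg_prob=0.4)
            b = random_concept_map(seed + 50, k=5, density=0.5, neg_prob=0.4)
            rep = disagreement(a, b, scope="whole_map")
            na = {(i, j): a.net(i, j) for i in a.factors for j in a.factors}
            nb = {(i, j): b.net(i, j) for i in b.factors for j in b.factors}
            expected, n = dbar_oracle(na, nb)
            assert rep.dbar == pytest.approx(expected)
            assert rep.n_compared == n


class TestHarrisWeights:
    def _maps_with_link_in(self, present: int, total: int):
        maps = []
        for i in range(total):
            m = ConceptMap(["A", "B", "C"])
            if i < present:
                m.add_link("A", "B", 0.5)  # magnitude must not matter
            m.add_link("B", "C", 0.1)
            maps.append(m)
        return maps

    def test_relative_frequency(self):
        hw = harris_weights(self._maps_with_link_in(6, 12))
        assert hw.wplus("A", "B") == pytest.approx(0.5)
        assert hw.wplus("B", "C") == pytest.approx(1.0)

    def test_rescale_to_max(self):
        maps = self._maps_with_link_in(6, 12)
        for m in maps:
            m.set_link("B", "C", wplus=0.0)
        maps[0].add_link("C", "A", 0.9)
        hw = harris_weights(maps, rescale=True)
        assert hw.wplus("A", "B") == pytest.approx(1.0)  # 6/6, max count is 6
        assert hw.wplus("C", "A") == pytest.approx(1 / 6)

    def test_signs_counted_separately(self):
        maps = [ConceptMap(), ConceptMap()]
        maps[0].add_link("A", "B", 0.5)
        maps[1].add_link("A", "B", -0.5)
        hw = harris_weights(maps)
        assert hw.wplus("A", "B") == pytest.approx(0.5)
        assert hw.wminus("A", "B") == pytest.approx(0.5)

    def test_compare_weighting_identical_zero_and_arithmetic(self):
        m = random_concept_map(2, k=5, density=0.5)
        assert compare_weighting(m, m.copy()).dbar == 0.0
        a = ConceptMap()
        b = ConceptMap()
        for idx, (i, j) in enumerate([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]):
            a.add_link(i, j, 0.5)
            b.add_link(i, j, 0.5 if idx else 0.9)  # one link differs by 0.4
        assert compare_weighting(a, b).dbar == pytest.approx(0.1)
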