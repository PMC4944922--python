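"""Action values: backward induction vs the 32-path enumeration oracle."""

import math

import numpy as np
import pytest

from infoseek import (
    DiscountParams,
    InfoBonusParams,
    TrialConfig,
    UPParams,
    build_state_tree,
    discounted_action_values,
    enumerate_action_values,
    evi_action_values,
    info_bonus_action_values,
    up_action_values,
)
from infoseek.valuation import action_values_fast

# Frozen regression values from the 32-path enumeration oracle.
UP_K01_C0_QI = 7.698568218555157
UP_K01_C0_QN = 10.0 * math.exp(-0.5)


class TestEVI:
    def test_zero_cost_indifference(self, trees):
        av = evi_action_values(trees[0])
        assert av.q_informative == av.q_noninformative == 10.0

    @pytest.mark.parametrize("cost", [0, 1, 3, 5])
    def test_values_match_closed_form(self, trees, cost):
        av = evi_action_values(trees[cost])
        assert av.q_informative == pytest.approx((20 - cost) / 2, abs=1e-12)
        assert av.q_noninformative == 10.0  # cost applies only to I

    def test_cost_mismatch_rejected(self, trees):
        with pytest.raises(ValueError):
            evi_action_values(trees[3], cost=5)


class TestUP:
    def test_k_zero_reduces_to_evi(self, trees):
        for cost, tree in trees.items():
            up = up_action_values(tree, UPParams(0.0))
            evi = evi_action_values(tree)
            assert up.q_informative == evi.q_informative
            assert up.q_noninformative == evi.q_noninformative

    def test_noninformative_closed_form(self, trees):
        """Five consecutive maximal-entropy states each contribute e^-k."""
        up = up_action_values(trees[0], UPParams(0.1))
        assert up.q_noninformative == pytest.approx(UP_K01_C0_QN, abs=1e-12)

    def test_informative_frozen_value(self, trees):
        up = up_action_values(trees[0], UPParams(0.1))
        assert up.q_informative == pytest.approx(UP_K01_C0_QI, abs=1e-9)
        assert up.q_informative > UP_K01_C0_QN  # info preferred at zero cost

    def test_gap_strictly_increasing_in_k_below_the_peak(self, trees):
        # the informative-minus-noninformative gap rises with uncertainty
        # aversion throughout the moderate regime (it peaks near k ~ 0.3
        # and shrinks again once the penalty crushes both branches)
        for cost, tree in trees.items():
            gaps = [
                up_action_values(tree, UPParams(k)).difference
                for k in np.linspace(-0.5, 0.29, 9)
            ]
            assert all(b > a for a, b in zip(gaps, gaps[1:]))

    def test_informative_value_decreasing_in_cost(self, trees):
        k = 0.3
        q_i = [up_action_values(trees[c], UPParams(k)).q_informative for c in (0, 1, 3, 5)]
        q_n = [up_action_values(trees[c], UPParams(k)).q_noninformative for c in (0, 1, 3, 5)]
        assert all(b < a for a, b in zip(q_i, q_i[1:]))
        assert len(set(q_n)) == 1


class TestInfoBonus:
    def test_k_hat_zero_reduces_to_evi(self, trees):
        for cost, tree in trees.items():
            ib = info_bonus_action_values(tree, InfoBonusParams(0.0))
            evi = evi_action_values(tree)
            assert ib.q_informative == evi.q_informative
            assert ib.q_noninformative == evi.q_noninformative

    def test_positive_bonus_prefers_information(self, trees):
        ib = info_bonus_action_values(trees[0], InfoBonusParams(0.1))
        assert ib.q_informative > ib.q_noninformative
        # one bit of expected uncertainty reduction per trial: gap = k_hat
        assert ib.difference == pytest.approx(0.1, abs=1e-12)

    def test_frozen_value(self, trees):
        ib = info_bonus_action_values(trees[0], InfoBonusParams(0.1))
        assert ib.q_informative == pytest.approx(10.1, abs=1e-10)
        assert ib.q_noninformative == pytest.approx(10.0, abs=1e-12)


class TestDiscounted:
    def test_gamma_one_identity(self, trees):
        for cost, tree in trees.items():
            d = discounted_action_values(tree, InfoBonusParams(0.1), DiscountParams(1.0))
            ib = info_bonus_action_values(tree, InfoBonusParams(0.1))
            assert d.q_informative == ib.q_informative
            assert d.q_noninformative == ib.q_noninformative

    def test_no_bonus_equals_evi(self, trees):
        d = discounted_action_values(trees[3], InfoBonusParams(0.0), DiscountParams(0.8))
        evi = evi_action_values(trees[3])
        assert d.q_informative == evi.q_informative

    def test_slower_rates_shrink_the_information_gap(self):
        gaps = {}
        for rate in (1, 5):
            tree = build_state_tree(TrialConfig(cost_cents=0, rate_seconds_per_card=rate))
            gaps[rate] = discounted_action_values(
                tree, InfoBonusParams(0.1), DiscountParams(0.95), rate=rate
            ).difference
        assert gaps[1] > gaps[5] > 0

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            DiscountParams(0.0)
        with pytest.raises(ValueError):
            DiscountParams(1.2)


class TestEnumerationOracle:
    """Dynamic programming must agree with explicit 32-path summation."""

    @pytest.mark.parametrize("cost", [0, 1, 3, 5])
    @pytest.mark.parametrize("k", [-0.5, 0.0, 0.1, 0.4, 1.0])
    def test_up_agreement(self, trees, cost, k):
        dp = up_action_values(trees[cost], UPParams(k))
        oracle = enumerate_action_values(cost, "up", k=k)
        assert dp.q_informative == pytest.approx(oracle.q_informative, abs=1e-10)
        assert dp.q_noninformative == pytest.approx(oracle.q_noninformative, abs=1e-10)

    @pytest.mark.parametrize("cost", [0, 5])
    @pytest.mark.parametrize("k_hat", [0.0, 0.1, -0.3, 0.8])
    def test_info_bonus_agreement(self, trees, cost, k_hat):
        dp = info_bonus_action_values(trees[cost], InfoBonusParams(k_hat))
        oracle = enumerate_action_values(cost, "info_bonus", k_hat=k_hat)
        assert dp.q_informative == pytest.approx(oracle.q_informative, abs=1e-10)
        assert dp.q_noninformative == pytest.approx(oracle.q_noninformative, abs=1e-10)

    @pytest.mark.parametrize("rate", [1, 3, 5])
    @pytest.mark.parametrize("gamma", [0.9, 0.99, 1.0])
    def test_discounted_agreement(self, rate, gamma):
        tree = build_state_tree(TrialConfig(cost_cents=1, rate_seconds_per_card=rate))
        dp = discounted_action_values(
            tree, InfoBonusParams(0.2), DiscountParams(gamma), rate=rate
        )
        oracle = enumerate_action_values(1, "discounted", k_hat=0.2, gamma=gamma, rate=rate)
        assert dp.q_informative == pytest.approx(oracle.q_informative, abs=1e-10)
        assert dp.q_noninformative == pytest.approx(oracle.q_noninformative, abs=1e-10)

    @pytest.mark.parametrize("model, kwargs", [
        ("evi", {}),
        ("up", {"k": 0.25}),
        ("info_bonus", {"k_hat": 0.25}),
        ("discounted", {"k_hat": 0.25, "gamma": 0.9}),
    ])
    @pytest.mark.parametrize("cost", [0, 3])
    def test_fast_layer_agreement(self, model, kwargs, cost):
        fast = action_values_fast(model, cost, **kwargs)
        oracle = enumerate_action_values(cost, model, **kwargs)
        assert fast.q_informative == pytest.approx(oracle.q_informative, abs=1e-12)
        assert fast.q_noninformative == pytest.approx(oracle.q_noninformative, abs=1e-12)


def test_up_and_info_bonus_are_ordinally_but_not_exactly_equivalent(trees):
    """The two parametrisations agree on the sign of the information
    preference but are not related by an exact parameter mapping: the UP
    gap is nonlinear in cost, the bonus gap exactly linear."""
    for k in (0.1, 0.4):
        up_gap = up_action_values(trees[0], UPParams(k)).difference
        ib_gap = info_bonus_action_values(trees[0], InfoBonusParams(k)).difference
        assert (up_gap > 0) == (ib_gap > 0)
    # matching the zero-cost gap with k_hat does not match it at cost 5
    k = 0.4
    up0 = up_action_values(trees[0], UPParams(k)).difference
    up5 = up_action_values(trees[5], UPParams(k)).difference
    ib5 = info_bonus_action_values(trees[5], InfoBonusParams(up0)).difference
    assert abs(ib5 - up5) > 1e-3
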