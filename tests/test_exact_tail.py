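"""Order-statistics integration: word probabilities, closed forms, engines."""

import math
from math import comb

import numpy as np
import pytest
from scipy.stats import norm

from exactroc.counting import mann_whitney_null
from exactroc.exact_tail import (TN, TP, auc_probability, partition_to_word,
                                 partitions_box, second_prob_closed_form,
                                 tail_table, top_prob_closed_form,
                                 word_probability)
from exactroc.models import BinormalModel, IntegrationGrid, TabulatedModel


class TestPartitionsAndWords:
    def test_partition_count_matches_curve_count(self):
        from exactroc.counting import count_roc_curves

        for i in range(9):
            parts = list(partitions_box(i, 4, 5))
            assert len(parts) == count_roc_curves(i, 4, 5)

    def test_word_deficit_equals_partition_sum(self):
        for i in range(7):
            for part in partitions_box(i, 3, 4):
                word = partition_to_word(part, 3, 4)
                deficit = 0
                placed_tp = 0
                for lab in word:
                    if lab == TP:
                        placed_tp += 1
                    else:
                        deficit += placed_tp
                assert deficit == sum(part)

    def test_words_are_distinct_across_partitions(self):
        words = [tuple(partition_to_word(p, 5, 6))
                 for i in range(10) for p in partitions_box(i, 5, 6)]
        assert len(words) == len(set(words))


class TestWordProbability:
    def test_exchangeable_pair_is_half(self, equal_model):
        assert word_probability([TN, TP], equal_model) == pytest.approx(
            0.5, abs=1e-5)

    def test_binormal_pair_closed_form(self, unit_model):
        # P(X > Y) for X ~ N(1,1), Y ~ N(0,1) is Phi(1/sqrt(2))
        expected = norm.cdf(1 / math.sqrt(2))
        assert word_probability([TN, TP], unit_model) == pytest.approx(
            expected, rel=1e-5)

    @pytest.mark.parametrize("word", [
        [TN, TP, TN, TP], [TP, TN, TN, TP], [TN, TN, TP, TP],
        [TP, TP, TN, TN, TN],
    ])
    def test_uniform_ordering_when_distributions_equal(self, word, equal_model):
        n = sum(1 for w in word if w == TP)
        m = len(word) - n
        assert word_probability(word, equal_model) == pytest.approx(
            1 / comb(n + m, n), rel=1e-4)

    def test_wrong_label_counts_rejected(self, equal_model):
        with pytest.raises(ValueError):
            word_probability([TP, TP], equal_model)


class TestClosedForms:
    def test_top_prob_uniform_case(self, equal_model):
        assert top_prob_closed_form(equal_model, 5, 6) == pytest.approx(
            1 / 462, rel=1e-8)

    def test_top_prob_binormal_pair(self, unit_model):
        assert top_prob_closed_form(unit_model, 1, 1) == pytest.approx(
            norm.cdf(1 / math.sqrt(2)), rel=1e-8)

    def test_top_prob_equals_separated_word(self, unit_model):
        sep = [TN] * 6 + [TP] * 5
        assert top_prob_closed_form(unit_model, 5, 6) == pytest.approx(
            word_probability(sep, unit_model), rel=1e-4)

    def test_second_prob_uniform_case(self, equal_model):
        assert second_prob_closed_form(equal_model, 5, 6) == pytest.approx(
            1 / 462, rel=1e-4)

    def test_second_prob_cross_checks_word_sum(self, unit_model):
        assert second_prob_closed_form(unit_model, 3, 4) == pytest.approx(
            auc_probability(1, unit_model, 3, 4), rel=1e-4)

    def test_second_prob_needs_two_tps(self, unit_model):
        with pytest.raises(ValueError):
            second_prob_closed_form(unit_model, 1, 3)


class TestTailTable:
    def test_uniform_case_equals_mann_whitney_null(self, equal_model):
        tt = tail_table(equal_model, 4, 4, 16)
        mw = mann_whitney_null(4, 4)
        assert tt.probs == pytest.approx(mw, rel=1e-7)

    def test_full_support_normalises(self, unit_model):
        tt = tail_table(unit_model, 3, 3, 9)
        assert tt.probs.sum() == pytest.approx(1.0, abs=1e-8)

    def test_engines_agree_algebraically_under_linear_rule(self, unit_model):
        # trapezoid is linear, so DP state merging is algebraically exact
        dp = tail_table(unit_model, 4, 5, 8, richardson=False,
                        rule="trapezoid")
        ws = tail_table(unit_model, 4, 5, 8, engine="word_sum",
                        rule="trapezoid")
        assert dp.probs == pytest.approx(ws.probs, rel=1e-10)

    def test_engines_agree_under_default_rule(self, unit_model):
        dp = tail_table(unit_model, 4, 5, 8, richardson=False)
        ws = tail_table(unit_model, 4, 5, 8, engine="word_sum")
        assert dp.probs == pytest.approx(ws.probs, rel=5e-6)

    def test_auc_probability_i0_matches_closed_form(self, unit_model):
        assert auc_probability(0, unit_model, 4, 4) == pytest.approx(
            top_prob_closed_form(unit_model, 4, 4), rel=1e-4)

    def test_grid_refinement_stability(self, unit_model):
        base = unit_model.default_grid(2001)
        fine = base.refined(2)
        t1 = tail_table(unit_model, 4, 4, 6, grid=base)
        t2 = tail_table(unit_model, 4, 4, 6, grid=fine)
        assert t1.probs == pytest.approx(t2.probs, rel=1e-3)

    @pytest.mark.parametrize("i", range(6))
    def test_top_mass_nondecreasing_in_moderate_separation(self, i):
        # monotone in delta over the moderate-separation range; at strong
        # separation mid-lattice masses eventually drain toward AUC = 1
        probs = [tail_table(BinormalModel(delta=d), 5, 6, 5).probs[i]
                 for d in (0.0, 0.5, 1.0)]
        assert all(a <= b * (1 + 1e-9) for a, b in zip(probs, probs[1:]))

    def test_invalid_ranges_rejected(self, unit_model):
        with pytest.raises(ValueError):
            tail_table(unit_model, 3, 3, 10)
        with pytest.raises(ValueError):
            tail_table(unit_model, 0, 3, 1)


class TestTabulatedModel:
    def test_tabulated_binormal_matches_analytic(self, unit_model):
        grid = np.linspace(-9, 10, 3001)
        tab = TabulatedModel(grid, norm.pdf(grid, 1.0), norm.pdf(grid))
        t_tab = tail_table(tab, 3, 3, 4, grid=IntegrationGrid(grid))
        t_ana = tail_table(unit_model, 3, 3, 4, grid=IntegrationGrid(grid))
        assert t_tab.probs == pytest.approx(t_ana.probs, rel=1e-3)

    def test_unnormalised_density_rejected(self):
        grid = np.linspace(-5, 5, 101)
        with pytest.raises(ValueError, match="integrates"):
            TabulatedModel(grid, 2 * norm.pdf(grid), norm.pdf(grid))

    def test_population_auc(self):
        grid = np.linspace(-10, 11, 4001)
        tab = TabulatedModel(grid, norm.pdf(grid, 1.0), norm.pdf(grid))
        assert tab.population_auc == pytest.approx(
            norm.cdf(1 / math.sqrt(2)), rel=1e-6)
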