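"""Geometric bridge: special-case exactness, coefficient fit, assembly."""

import numpy as np
import pytest

from exactroc.counting import count_table, mann_whitney_null
from exactroc.exact_tail import TailTable, tail_table
from exactroc.interpolation import (BridgeCoefficient, assemble_distribution,
                                    fit_C, geometric_bridge,
                                    ratio_diagnostics)
from exactroc.models import BinormalModel
from exactroc.montecarlo import MCResult, simulate_auc


def exact_tail_from_null(n, m, i_max, model):
    """TailTable holding the exact combinatorial F = G null (no quadrature)."""
    probs = np.array(mann_whitney_null(n, m, i_max))
    return TailTable(n=n, m=m, model=model, probs=probs, method="exact")


def mc_from_exact_null(n, m, model):
    """MCResult whose empirical distribution equals the exact F = G null:
    each interleaving represented once."""
    counts = count_table(n, m)
    deficits = np.repeat(np.arange(n * m + 1), [int(k) for k in counts.counts])
    return MCResult(deficits=deficits, n=n, m=m, model=model, seed=0,
                    reps=len(deficits))


class TestGeometricBridge:
    def test_single_step_hand_arithmetic(self, equal_model):
        # x2 = x1 + C * dk2 * dx1 / dk1 with x = [0.5, 0.7], k = [1, 2, 4]
        tail = TailTable(n=2, m=3, model=equal_model,
                         probs=np.array([0.5, 0.7]), method="exact")
        counts = count_table(2, 3)  # k = 1, 1, 2, 2, 2, 1, 1
        # dk1 = 0, so anchor ratio undefined -> use a 3-entry tail instead
        tail = TailTable(n=2, m=3, model=equal_model,
                         probs=np.array([0.1, 0.2, 0.5]), method="exact")
        # k = [1,1,2]: dk2 = 1; bridge to i=3: dk3 = k3-k2 = 0 -> dx3 = 0
        out = geometric_bridge(tail, counts, BridgeCoefficient("constant", 2.0),
                               i_stop=3)
        assert out[3] == pytest.approx(0.5 + 2.0 * 0 * (0.3 / 1))
        # i=4: dk4 = 0 again; ratio carried forward
        out = geometric_bridge(tail, counts, BridgeCoefficient("constant", 2.0),
                               i_stop=4)
        assert out[4] == out[3]

    @pytest.mark.parametrize("n,m,trunc", [(6, 6, 5), (5, 7, 4)])
    def test_uniform_null_recovered_exactly_with_unit_coefficient(
            self, equal_model, n, m, trunc):
        """With F = G and C = 1 the recurrence reproduces k_i·n!m!/(n+m)!."""
        tail = exact_tail_from_null(n, m, trunc, equal_model)
        counts = count_table(n, m)
        out = geometric_bridge(tail, counts, BridgeCoefficient("constant", 1.0),
                               i_stop=n * m // 2)
        expected = mann_whitney_null(n, m, n * m // 2)
        assert out == pytest.approx(expected, rel=1e-12)

    def test_truncate_and_recover_binormal(self, unit_model):
        """Truncating a known full distribution at deficit 8 and bridging
        with the true-percentile-matched C recovers the tail within 10%."""
        full = tail_table(unit_model, 10, 10, 100)
        trunc = TailTable(n=10, m=10, model=unit_model,
                          probs=full.probs[:9].copy(), method="exact")
        counts = count_table(10, 10)
        # emulate an ideal MC body from the exact distribution
        reps_probs = full.probs / full.probs.sum()
        rng = np.random.default_rng(0)
        deficits = rng.choice(101, size=400_000, p=reps_probs)
        mc = MCResult(deficits=deficits, n=10, m=10, model=unit_model,
                      seed=0, reps=len(deficits))
        coeff = fit_C(trunc, counts, mc, match_alpha=0.9)
        stop = max(20, coeff.i_tail + 1)
        out = geometric_bridge(trunc, counts, coeff, i_stop=20)
        assert out[:21] == pytest.approx(full.probs[:21], rel=0.10)

    def test_bridged_upper_tail_strictly_increasing(self, unit_model):
        tail = tail_table(unit_model, 6, 6, 6)
        counts = count_table(6, 6)
        out = geometric_bridge(tail, counts,
                               BridgeCoefficient("constant", 0.8), i_stop=18)
        assert np.all(out > 0)
        assert np.all(np.diff(np.cumsum(out)) > 0)


class TestFitC:
    def test_uniform_inputs_recover_unit_coefficient(self, equal_model):
        n = m = 6
        tail = exact_tail_from_null(n, m, 5, equal_model)
        counts = count_table(n, m)
        mc = mc_from_exact_null(n, m, equal_model)
        coeff = fit_C(tail, counts, mc, match_alpha=0.9)
        assert coeff.form == "constant"
        assert coeff.C == pytest.approx(1.0, rel=1e-4)

    def test_match_point_reproduced_by_construction(self, unit_model):
        from exactroc.montecarlo import percentile_deficit

        tail = tail_table(unit_model, 10, 10, 5)
        counts = count_table(10, 10)
        mc = simulate_auc(unit_model, 10, 10, 100_000, seed=13)
        coeff = fit_C(tail, counts, mc, match_alpha=0.9)
        d_star = percentile_deficit(mc, 0.9)
        bridged = geometric_bridge(tail, counts, coeff, d_star)
        target = np.count_nonzero(mc.deficits <= d_star) / mc.reps
        assert np.sum(bridged) == pytest.approx(target, rel=1e-4)

    def test_rescaled_tail_still_matches_at_fixed_point(self, equal_model):
        """Perturbing the tail rescales the fitted C so that the bridged
        mass at the match percentile still equals the empirical target —
        the defining fixed-point property of the fit."""
        from exactroc.montecarlo import percentile_deficit

        n = m = 6
        tail = exact_tail_from_null(n, m, 5, equal_model)
        counts = count_table(n, m)
        mc = mc_from_exact_null(n, m, equal_model)
        scaled = TailTable(n=n, m=m, model=equal_model,
                           probs=tail.probs * 0.9, method="exact")
        coeff = fit_C(scaled, counts, mc, match_alpha=0.9)
        d_star = percentile_deficit(mc, 0.9)
        bridged = geometric_bridge(scaled, counts, coeff, d_star)
        target = np.count_nonzero(mc.deficits <= d_star) / mc.reps
        assert np.sum(bridged) == pytest.approx(target, rel=1e-4)

    def test_exponent_form_monotone_path(self, unit_model):
        tail = tail_table(unit_model, 10, 10, 5)
        counts = count_table(10, 10)
        mc = simulate_auc(unit_model, 10, 10, 100_000, seed=21)
        coeff = fit_C(tail, counts, mc, match_alpha=0.9, form="exponent")
        assert coeff.form == "exponent"
        path = coeff.path(np.arange(coeff.i_tail, coeff.i_med + 1))
        assert np.all(np.diff(path) >= -1e-12)
        assert path[-1] == pytest.approx(1.0, abs=1e-9)


class TestRatioDiagnostics:
    def test_uniform_null_ratios_identically_one(self, equal_model):
        n = m = 6
        tail = exact_tail_from_null(n, m, 8, equal_model)
        counts = count_table(n, m)
        ratios = ratio_diagnostics(tail, counts)
        finite = [r for _, r in ratios if np.isfinite(r)]
        assert finite == pytest.approx([1.0] * len(finite), rel=1e-9)

    def test_binormal_ratios_approximately_constant(self, unit_model):
        """The stabilising normalised ratio underpinning the constant-C
        bridge: coefficient of variation below 0.2 over mid-tail deficits."""
        tail = tail_table(unit_model, 12, 12, 30)
        counts = count_table(12, 12)
        ratios = [r for i, r in ratio_diagnostics(tail, counts)
                  if 10 <= i <= 30 and np.isfinite(r)]
        ratios = np.array(ratios)
        assert ratios.std() / ratios.mean() < 0.2

    def test_zero_difference_reported_not_computed(self, equal_model):
        tail = exact_tail_from_null(3, 3, 4, equal_model)
        counts = count_table(3, 3)  # k = 1,1,2,3,3,... dk vanishes at i=1, 4
        ratios = dict(ratio_diagnostics(tail, counts))
        assert np.isnan(ratios[2])  # dk_{i-1} = 0 at i = 2


class TestAssemble:
    def test_exact_only_distribution_identity(self, unit_model):
        tail = tail_table(unit_model, 10, 10, 100)
        dist = assemble_distribution(tail, None, None)
        assert dist.probs == pytest.approx(tail.probs)
        assert set(dist.source) == {"exact"}
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_total_variation_to_exact_null_small(self, equal_model):
        """exact (i<=5) + unit-C bridge + MC body vs the exact F = G null."""
        n = m = 8
        tail = exact_tail_from_null(n, m, 5, equal_model)
        counts = count_table(n, m)
        mc = simulate_auc(equal_model, n, m, 1_000_000, seed=17)
        coeff = fit_C(tail, counts, mc, match_alpha=0.99)
        from exactroc.montecarlo import percentile_deficit

        d_star = percentile_deficit(mc, 0.99)
        bridged = (geometric_bridge(tail, counts, coeff, d_star)
                   if d_star > 5 else None)
        dist = assemble_distribution(tail, bridged, mc)
        exact = np.array(mann_whitney_null(n, m))
        tv = 0.5 * np.abs(dist.probs - exact).sum()
        assert tv < 0.01

    def test_junction_mismatch_warns(self, equal_model):
        n = m = 4
        tail = exact_tail_from_null(n, m, 3, equal_model)
        bad = tail.probs.copy()
        bad_tail = TailTable(n=n, m=m, model=equal_model, probs=bad * 5.0,
                             method="exact")
        mc = simulate_auc(equal_model, n, m, 50_000, seed=19)
        with pytest.warns(RuntimeWarning, match="junction|mass"):
            assemble_distribution(bad_tail, None, mc)

    def test_source_blocks_contiguous(self, unit_model):
        tail = tail_table(unit_model, 6, 6, 2)
        counts = count_table(6, 6)
        mc = simulate_auc(unit_model, 6, 6, 100_000, seed=23)
        coeff = fit_C(tail, counts, mc, match_alpha=0.8)
        from exactroc.montecarlo import percentile_deficit

        d_star = percentile_deficit(mc, 0.8)
        bridged = geometric_bridge(tail, counts, coeff, d_star)
        dist = assemble_distribution(tail, bridged, mc)
        src = list(dist.source)
        blocks = [src[0]]
        for s in src[1:]:
            if s != blocks[-1]:
                blocks.append(s)
        assert blocks == ["exact", "interpolated", "monte_carlo"]
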