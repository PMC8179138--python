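"""Zwanzig windows, leg accumulation and thermodynamic-cycle closure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermoprof as tp
from thermoprof.constants import K_B
from thermoprof.fep import (
    LambdaLadder,
    PerturbationSeries,
    WindowEstimate,
    accumulate_leg,
    cycle_combine,
    pool_replicates,
    zwanzig_window,
)

from conftest import harmonic_delta_f_quadrature


def _series(du, lam=0.0, window=0, t=300.0):
    return PerturbationSeries(window_index=window, lam=lam, delta_u=np.asarray(du),
                              temperature=t)


class TestLambdaLadder:
    def test_evenly_spaced_has_windows_plus_one_states(self):
        ladder = LambdaLadder.evenly_spaced(84)
        assert ladder.n_windows == 84
        assert len(ladder.lambdas) == 85
        assert ladder.lambdas[0] == 0.0 and ladder.lambdas[-1] == 1.0

    @pytest.mark.parametrize(
        "lams", [(0.0,), (0.1, 1.0), (0.0, 0.9), (0.0, 0.5, 0.5, 1.0), (0.0, 0.7, 0.4, 1.0)]
    )
    def test_invalid_ladders_rejected(self, lams):
        with pytest.raises(ValueError):
            LambdaLadder(lams)

    def test_reversed_ladder(self):
        ladder = LambdaLadder((0.0, 0.3, 1.0))
        assert ladder.reversed().lambdas == (0.0, 0.7, 1.0)


class TestZwanzigWindow:
    def test_zero_differences_give_zero_free_energy(self):
        est = zwanzig_window(_series(np.zeros(100)))
        assert est.delta_f == 0.0
        assert est.sem == 0.0

    def test_constant_shift_is_exact(self):
        est = zwanzig_window(_series(np.full(50, 1.7)))
        assert est.delta_f == pytest.approx(1.7, abs=1e-12)
        assert est.sem == 0.0

    def test_frame_reordering_invariance(self):
        rng = np.random.default_rng(0)
        du = rng.normal(0.2, 0.5, size=400)
        perm = rng.permutation(400)
        a = zwanzig_window(_series(du))
        b = zwanzig_window(_series(du[perm]))
        assert a.delta_f == pytest.approx(b.delta_f, abs=1e-12)

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            _series(np.array([]))
        with pytest.raises(ValueError):
            _series(np.array([0.1, np.nan]))

    def test_few_frames_warns(self):
        with pytest.warns(UserWarning, match="retained frames"):
            zwanzig_window(_series(np.ones(5)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False, width=32), min_size=10, max_size=200)
    )
    def test_exponential_average_bounded_by_sample_extremes(self, du):
        # Jensen: min dU <= dF <= <dU>
        est = zwanzig_window(_series(np.array(du, dtype=float)))
        assert est.delta_f <= np.mean(du) + 1e-9
        assert est.delta_f >= np.min(du) - 1e-9


class TestLegAccumulation:
    def test_single_window(self):
        leg = accumulate_leg(
            [WindowEstimate(0, 0.0, 0.5, 0.0, 10, 0.0, 300.0)], "bound"
        )
        assert leg.leg_dg == pytest.approx(0.5)

    def test_window_sum(self):
        wins = [
            WindowEstimate(i, i / 3, dg, 0.0, 10, 0.0, 300.0)
            for i, dg in enumerate([0.1, -0.2, 0.3])
        ]
        leg = accumulate_leg(wins, "bound")
        assert leg.leg_dg == pytest.approx(0.2)
        assert leg.leg_dg == pytest.approx(leg.window_dgs.sum(), abs=1e-9)

    def test_ladder_count_mismatch_rejected(self):
        wins = [WindowEstimate(0, 0.0, 0.5, 0.0, 10, 0.0, 300.0)]
        with pytest.raises(ValueError, match="window count"):
            accumulate_leg(wins, "bound", LambdaLadder.evenly_spaced(3))

    def test_mixed_temperatures_rejected(self):
        wins = [
            WindowEstimate(0, 0.0, 0.5, 0.0, 10, 0.0, 300.0),
            WindowEstimate(1, 0.5, 0.5, 0.0, 10, 0.0, 310.0),
        ]
        with pytest.raises(ValueError, match="temperatures"):
            accumulate_leg(wins, "bound")


class TestCycleCombine:
    def test_bound_minus_unbound(self):
        b = tp.FreeEnergyResult("bound", [-8.0], -8.0, 0.1, 300.0)
        u = tp.FreeEnergyResult("unbound", [-2.0], -2.0, 0.1, 300.0)
        rel = cycle_combine(b, u)
        assert rel.ddg == pytest.approx(-6.0)
        assert rel.sem == pytest.approx(np.hypot(0.1, 0.1))

    def test_identical_legs_close_the_cycle(self):
        b = tp.FreeEnergyResult("bound", [1.0, 2.0], 3.0, 0.05, 300.0)
        u = tp.FreeEnergyResult("unbound", [1.0, 2.0], 3.0, 0.05, 300.0)
        assert cycle_combine(b, u).ddg == 0.0

    def test_temperature_mismatch_rejected(self):
        b = tp.FreeEnergyResult("bound", [0.0], 0.0, 0.0, 300.0)
        u = tp.FreeEnergyResult("unbound", [0.0], 0.0, 0.0, 310.0)
        with pytest.raises(ValueError, match="temperature mismatch"):
            cycle_combine(b, u)

    def test_replicate_statistics_match_direct_arithmetic(self):
        # oracle: mean and SEM of the per-replicate differences
        bvals = [-8.1, -7.9, -8.3]
        uvals = [-2.0, -2.2, -1.9]
        diffs = np.array(bvals) - np.array(uvals)
        b = tp.FreeEnergyResult("bound", [np.mean(bvals)], float(np.mean(bvals)),
                                0.1, 300.0, replicate_dgs=bvals)
        u = tp.FreeEnergyResult("unbound", [np.mean(uvals)], float(np.mean(uvals)),
                                0.1, 300.0, replicate_dgs=uvals)
        rel = cycle_combine(b, u)
        assert rel.ddg == pytest.approx(diffs.mean())
        assert rel.sem == pytest.approx(diffs.std(ddof=1) / np.sqrt(3))


class TestHarmonicBenchmark:
    def test_leg_matches_partition_function_quadrature(self, harmonic_spec):
        oracle = harmonic_delta_f_quadrature(1.0, 2.0, 300.0)
        assert oracle == pytest.approx(harmonic_spec.exact_delta_f(), abs=1e-9)
        run = tp.sample_alchemical_path(
            harmonic_spec, LambdaLadder.evenly_spaced(12), n_steps=30000, seed=7,
            store_frames=False,
        )
        leg = tp.estimate_leg(run.series, "bound")
        assert leg.leg_dg == pytest.approx(oracle, abs=3 * leg.leg_sem)

    def test_two_seeds_agree_within_combined_sem(self, harmonic_spec):
        ladder = LambdaLadder.evenly_spaced(12)
        legs = [
            tp.estimate_leg(
                tp.sample_alchemical_path(
                    harmonic_spec, ladder, n_steps=30000, seed=s, store_frames=False
                ).series,
                "bound",
            )
            for s in (21, 22)
        ]
        assert legs[0].leg_dg != legs[1].leg_dg  # different streams
        sem = np.hypot(legs[0].leg_sem, legs[1].leg_sem)
        assert abs(legs[0].leg_dg - legs[1].leg_dg) < 3 * sem

    def test_ladder_refinement_stable(self, harmonic_spec):
        legs = {}
        for n in (8, 16):
            run = tp.sample_alchemical_path(
                harmonic_spec, LambdaLadder.evenly_spaced(n), n_steps=30000,
                seed=31, store_frames=False,
            )
            legs[n] = tp.estimate_leg(run.series, "bound")
        sem = np.hypot(legs[8].leg_sem, legs[16].leg_sem)
        assert abs(legs[8].leg_dg - legs[16].leg_dg) < 3 * sem

    def test_free_energy_scales_linearly_with_temperature(self, harmonic_spec):
        # dH = 0 for the harmonic mutation, so dG(T)/T is constant
        ratios = []
        for t in (280.0, 315.0):
            spec = tp.HarmonicSpec(1.0, 2.0, temperature=t)
            run = tp.sample_alchemical_path(
                spec, LambdaLadder.evenly_spaced(8), n_steps=30000, seed=43,
                store_frames=False,
            )
            leg = tp.estimate_leg(run.series, "bound")
            ratios.append((leg.leg_dg / t, leg.leg_sem / t))
        gap = abs(ratios[0][0] - ratios[1][0])
        assert gap < 3 * np.hypot(ratios[0][1], ratios[1][1])
        assert ratios[0][0] == pytest.approx(0.5 * K_B * np.log(2), rel=0.02)


def test_pool_replicates_mean_and_sem():
    legs = [
        tp.FreeEnergyResult("bound", [x], x, 0.0, 300.0, replicate_dgs=[x])
        for x in (1.0, 1.2, 0.8)
    ]
    pooled = pool_replicates(legs)
    assert pooled.leg_dg == pytest.approx(1.0)
    assert pooled.leg_sem == pytest.approx(np.std([1.0, 1.2, 0.8], ddof=1) / np.sqrt(3))
    assert pooled.replicate_dgs == [1.0, 1.2, 0.8]
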