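"""Well-tempered metadynamics: hills, bias, FES, recrossing, barriers."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from pathmetad.metad import (
    BiasState,
    FESGrid,
    HillsLog,
    barrier_between,
    bias_value,
    deposit_hill,
    detect_recrossing,
    reconstruct_fes,
    run_wtmetad,
)
from pathmetad.systems import langevin_run, make_double_well_1d
from pathmetad.units import KB_KCAL


def _state(w0=0.1, gamma=8.0, T=300.0, widths=(0.1,), ranges=((-2.0, 2.0),)):
    return BiasState(ranges=ranges, widths=widths, w0=w0, bias_factor=gamma,
                     temperature=T)


class TestDepositHill:
    def test_first_hill_has_base_height(self):
        st = _state()
        h = st.deposit([0.0], time=0.0)
        assert h == pytest.approx(0.1)

    def test_second_hill_damped_by_closed_form(self):
        w0, gamma, T = 0.1, 8.0, 300.0
        st = _state(w0=w0, gamma=gamma, T=T)
        st.deposit([0.0], time=0.0)
        h2 = st.deposit([0.0], time=1.0)
        expected = w0 * math.exp(-w0 / ((gamma - 1) * KB_KCAL * T))
        assert h2 == pytest.approx(expected, rel=1e-6)

    def test_heights_trend_downward_in_a_well(self):
        """1000 hills dropped around one location: well-tempered damping
        makes deposited heights decrease (Spearman ρ < 0, p < 0.01)."""
        st = _state()
        rng = np.random.default_rng(0)
        heights = [st.deposit([float(rng.normal(scale=0.2))], t) for t in range(1000)]
        rho, p = spearmanr(np.arange(1000), heights)
        assert rho < 0
        assert p < 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="bias factor"):
            _state(gamma=1.0)
        with pytest.raises(ValueError, match="height"):
            _state(w0=0.0)
        with pytest.raises(ValueError, match="width"):
            _state(widths=(0.0,))

    def test_deposit_hill_functional_wrapper(self):
        st = deposit_hill(_state(), [0.5], time=0.0)
        assert len(st.to_hills_log()) == 1


class TestBiasValue:
    def test_empty_log_is_zero(self):
        hills = HillsLog(times=[], centers=np.empty((0, 1)), widths=[0.1],
                         heights=[], bias_factor=8.0)
        assert bias_value([0.3], hills) == 0.0

    def test_single_hill_at_center(self):
        hills = HillsLog(times=[0.0], centers=[[0.5]], widths=[0.1],
                         heights=[0.1], bias_factor=8.0)
        assert bias_value([0.5], hills) == pytest.approx(0.1)

    def test_matches_naive_summation(self, rng):
        """50 random 2D hills at a random point vs explicit python loop."""
        centers = rng.uniform(-1, 1, size=(50, 2))
        heights = rng.uniform(0.01, 0.2, size=50)
        widths = np.array([0.3, 0.15])
        hills = HillsLog(times=np.arange(50.0), centers=centers, widths=widths,
                         heights=heights, bias_factor=8.0)
        pt = rng.uniform(-1, 1, size=2)
        naive = 0.0
        for c, h in zip(centers, heights):
            naive += h * math.exp(
                -((pt[0] - c[0]) ** 2) / (2 * widths[0] ** 2)
                - ((pt[1] - c[1]) ** 2) / (2 * widths[1] ** 2)
            )
        assert bias_value(pt, hills) == pytest.approx(naive, abs=1e-12)

    def test_grid_accumulator_matches_exact_sum(self, rng):
        st = _state(widths=(0.15,), ranges=((-2, 2),))
        for t in range(40):
            st.deposit([float(rng.uniform(-1.5, 1.5))], t)
        hills = st.to_hills_log()
        for u in rng.uniform(-1.5, 1.5, size=10):
            # bilinear interpolation on a σ/6 grid is good to ~1%
            assert st.value([u]) == pytest.approx(
                bias_value([u], hills), rel=0.02, abs=2e-3
            )


class TestWellTemperedProperty:
    def test_sublinear_bias_growth_vs_standard(self):
        """Cumulative bias at a revisited point grows sublinearly compared
        with standard (infinite bias factor) metadynamics."""
        wt = _state(gamma=5.0)
        std = _state(gamma=math.inf)
        for t in range(400):
            wt.deposit([0.0], t)
            std.deposit([0.0], t)
        v_wt = wt.value([0.0])
        v_std = std.value([0.0])
        assert v_std == pytest.approx(400 * 0.1, rel=1e-6)
        assert v_wt < 0.5 * v_std


class TestRunWTMetad:
    def test_zero_height_reduces_to_unbiased(self):
        pot = make_double_well_1d(5.0)
        tr_b, hills = run_wtmetad(pot, n_steps=4000, start=(-1.0, 0.0), dt=0.01,
                                  friction=5.0, temperature=300.0, seed=3,
                                  w0=0.0, sigmas=(0.1,), save_stride=10)
        tr_u = langevin_run(pot, (-1.0, 0.0), n_steps=4000, dt=0.01, friction=5.0,
                            temperature=300.0, seed=3, save_stride=10)
        assert len(hills) == 0
        assert np.allclose(tr_b.cvs[:, 0], tr_u.positions[:, 0], atol=1e-12)

    def test_reproducible_under_seed(self):
        pot = make_double_well_1d(3.0)
        a, ha = run_wtmetad(pot, n_steps=3000, start=(-1.0, 0.0), dt=0.01, seed=4,
                            sigmas=(0.1,), pace=100)
        b, hb = run_wtmetad(pot, n_steps=3000, start=(-1.0, 0.0), dt=0.01, seed=4,
                            sigmas=(0.1,), pace=100)
        assert np.array_equal(a.cvs, b.cvs)
        assert np.array_equal(ha.heights, hb.heights)

    def test_bad_widths_rejected(self):
        pot = make_double_well_1d(3.0)
        with pytest.raises(ValueError, match="width"):
            run_wtmetad(pot, n_steps=100, start=(-1.0, 0.0), sigmas=(-0.1,))

    def test_mini_vft_full_transition_sampled(self, mini_vft, hinge_frameset):
        """Biasing (S, Z) drives the bead model across the whole path."""
        trace, hills = run_wtmetad(
            mini_vft, n_steps=60000, frameset=hinge_frameset, seed=2,
            sigmas=(0.5, 0.1), pace=50, save_stride=50,
        )
        n = hinge_frameset.n_frames
        assert trace.cvs[:, 0].min() < 1.5
        assert trace.cvs[:, 0].max() > n - 1.0
        assert len(hills) == 60000 // 50


class TestReconstructFES:
    def test_single_hill_closed_form(self):
        st = _state(w0=0.1, gamma=8.0, widths=(0.1,))
        st.deposit([0.0], 0.0)
        fes = reconstruct_fes(st.to_hills_log(), s_range=(-1, 1), n_s=201)
        # depth below the far field equals (γ/(γ−1))·w0 at the hill center
        depth = fes.free_energy.max() - fes.free_energy[100]
        assert depth == pytest.approx(8.0 / 7.0 * 0.1, rel=1e-3)
        assert fes.free_energy.min() == 0.0

    def test_standard_metad_limit(self):
        st = _state(gamma=math.inf, widths=(0.1,))
        st.deposit([0.2], 0.0)
        hills = st.to_hills_log()
        fes = reconstruct_fes(hills, s_range=(-1, 1), n_s=101)
        v = np.array([bias_value([u], hills) for u in fes.s_centers])
        assert np.allclose(fes.free_energy, -v - (-v).min(), atol=1e-12)

    def test_cutoff_before_first_hill_rejected(self):
        st = _state()
        st.deposit([0.0], 5.0)
        with pytest.raises(ValueError, match="cutoff"):
            reconstruct_fes(st.to_hills_log(), s_range=(-1, 1), time_cutoff=1.0)

    def test_empty_hills_rejected(self):
        hills = HillsLog(times=[], centers=np.empty((0, 1)), widths=[0.1],
                         heights=[], bias_factor=8.0)
        with pytest.raises(ValueError, match="empty"):
            reconstruct_fes(hills, s_range=(-1, 1))


class TestFESConvergence:
    def test_fes_error_non_increasing_in_time(self):
        """The (smoothed) RMS error of the reconstructed double-well FES
        does not increase as more hills arrive."""
        pot = make_double_well_1d(5.0)
        _, hills = run_wtmetad(pot, n_steps=150_000, start=(-1.0, 0.0), dt=0.01,
                               friction=8.0, seed=6, w0=0.1, sigmas=(0.1,),
                               bias_factor=8.0, pace=100, save_stride=50)
        t_end = hills.times[-1]
        errors = []
        for frac in np.linspace(0.2, 1.0, 8):
            fes = reconstruct_fes(hills, s_range=(-1.3, 1.3), n_s=201,
                                  time_cutoff=float(frac * t_end))
            u = fes.s_centers
            diff = fes.profile_along_s() - 5.0 * (u**2 - 1.0) ** 2
            diff -= diff.mean()
            errors.append(np.sqrt(np.mean(diff**2)))
        smoothed = np.convolve(errors, np.ones(3) / 3, mode="valid")
        assert np.all(np.diff(smoothed) < 0.1 * smoothed[0])
        assert smoothed[-1] < 0.5 * smoothed[0]


class TestDetectRecrossing:
    def test_one_way_trip_returns_none(self):
        s = np.concatenate([np.full(10, -1.0), np.full(10, 1.0)])
        t = np.arange(20.0)
        assert detect_recrossing(s, t, (-1.5, -0.5), (0.5, 1.5)) is None

    def test_square_wave_reentry_time(self):
        s = np.concatenate([np.full(5, -1.0), np.full(5, 1.0), np.full(5, -1.0)])
        t = np.arange(15.0)
        assert detect_recrossing(s, t, (-1.5, -0.5), (0.5, 1.5)) == 10.0

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            detect_recrossing([0.0], [0.0], (-1.0, 0.5), (0.0, 1.0))

    def test_matches_hand_rolled_state_machine_on_biased_trace(self):
        pot = make_double_well_1d(4.0)
        trace, _ = run_wtmetad(pot, n_steps=80000, start=(-1.0, 0.0), dt=0.01,
                               friction=8.0, seed=5, sigmas=(0.1,), pace=100,
                               save_stride=10)
        u, t = trace.cvs[:, 0], trace.times
        got = detect_recrossing(u, t, (-1.3, -0.7), (0.7, 1.3))
        # independent scan: explicit phase bookkeeping
        phase, expected = "seek_a", None
        for ui, ti in zip(u, t):
            if phase == "seek_a" and -1.3 <= ui <= -0.7:
                phase = "seek_b"
            elif phase == "seek_b" and 0.7 <= ui <= 1.3:
                phase = "seek_a_again"
            elif phase == "seek_a_again" and -1.3 <= ui <= -0.7:
                expected = ti
                break
        assert got == expected
        assert got is not None


class TestBarrierBetween:
    def _analytic_fes(self, barrier=5.0):
        s = np.linspace(-1.5, 1.5, 601)
        f = barrier * ((s**2) - 1.0) ** 2
        return FESGrid(s_centers=s, free_energy=f - f.min(), bias_factor=8.0)

    def test_recovers_constructed_barrier(self):
        fes = self._analytic_fes(5.0)
        b = barrier_between(fes, (-1.2, -0.8), (0.8, 1.2))
        assert b["barrier_ab"] == pytest.approx(5.0, abs=1e-6)

    def test_symmetric_well_equal_barriers(self):
        fes = self._analytic_fes(3.0)
        b = barrier_between(fes, (-1.2, -0.8), (0.8, 1.2))
        assert b["barrier_ab"] == pytest.approx(b["barrier_ba"], abs=1e-9)
        assert b["delta_f_ab"] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_landscape_rejected(self):
        s = np.linspace(0, 1, 100)
        f = s.copy()  # monotone, no interior maximum between basins
        fes = FESGrid(s_centers=s, free_energy=f - f.min(), bias_factor=8.0)
        with pytest.raises(ValueError, match="degenerate"):
            barrier_between(fes, (0.0, 0.2), (0.8, 1.0))
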