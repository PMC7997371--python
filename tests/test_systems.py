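"""Analytic potentials, the mini-VFT bead model and the Langevin integrator."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ttest_ind

from pathmetad.geometry import aligned_rmsd
from pathmetad.systems import (
    AnalyticPotential2D,
    IntegrationFailure,
    langevin_run,
    make_double_well_1d,
    make_mini_vft,
    make_wide_open_excursion,
    minimum_energy_barrier,
    wide_open_reference,
)
from pathmetad.units import KB_KCAL, kT_kcal


class TestDoubleWell:
    def test_barrier_and_minima_by_construction(self):
        pot = make_double_well_1d(5.0, minima_separation=2.0)
        assert pot.energy([0.0, 0.0]) - pot.energy([1.0, 0.0]) == pytest.approx(5.0, abs=1e-9)
        assert pot.energy([-1.0, 0.0]) == pytest.approx(pot.energy([1.0, 0.0]), abs=1e-12)

    def test_stationary_points_match_root_finder(self):
        """Stationary points of the quartic match the roots of U'."""
        B, a = 3.0, 1.5
        pot = make_double_well_1d(B, minima_separation=2 * a)
        # U'(u) = 4B u (u² - a²)/a⁴ → roots of u³ - a² u
        roots = np.sort(np.roots([1.0, 0.0, -(a**2), 0.0]))
        stats = np.sort([p[0] for p in pot.stationary_points])
        assert np.allclose(roots, stats, atol=1e-12)
        for u in roots:
            assert pot.gradient([u, 0.0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_barrier_rejected(self):
        with pytest.raises(ValueError, match="barrier"):
            make_double_well_1d(0.0)

    @pytest.mark.parametrize("seed", [3])
    def test_gradient_matches_finite_differences(self, seed):
        pot = make_double_well_1d(4.0, minima_separation=2.5)
        rng = np.random.default_rng(seed)
        for _ in range(100):
            x = rng.uniform(-2, 2, size=2)
            g = pot.gradient(x)
            eps = 1e-6
            for d in range(2):
                xp, xm = x.copy(), x.copy()
                xp[d] += eps
                xm[d] -= eps
                fd = (pot.energy(xp) - pot.energy(xm)) / (2 * eps)
                assert g[d] == pytest.approx(fd, abs=1e-5)


class TestMiniVFT:
    def test_references_are_exact_minima(self, mini_vft):
        for ref in (mini_vft.ref_closed, mini_vft.ref_open):
            ec, eo, _, _ = mini_vft.energy_components(ref.coords)
            assert min(ec, eo) == pytest.approx(0.0, abs=1e-20)
            g = mini_vft.gradient(ref.coords)
            assert np.abs(g).max() < 1e-8

    def test_zero_hinge_angle_gives_identical_references(self):
        m = make_mini_vft(hinge_angle_open=0.0, seed=3)
        assert aligned_rmsd(m.ref_closed, m.ref_open) == pytest.approx(0.0, abs=1e-12)

    def test_open_closed_separation_exceeds_2A(self, mini_vft):
        assert aligned_rmsd(mini_vft.ref_closed, mini_vft.ref_open) > 0.2

    def test_align_lobe_identical_across_references(self, mini_vft):
        idx = mini_vft.reference_lobe_indices
        assert np.array_equal(
            mini_vft.ref_closed.coords[idx], mini_vft.ref_open.coords[idx]
        )

    def test_deterministic_given_seed(self):
        a = make_mini_vft(seed=42)
        b = make_mini_vft(seed=42)
        assert np.array_equal(a.ref_closed.coords, b.ref_closed.coords)
        assert np.array_equal(a.ref_open.coords, b.ref_open.coords)
        assert np.array_equal(a.pairs, b.pairs)

    def test_midpoint_higher_than_basin(self, mini_vft):
        mid = 0.5 * (mini_vft.ref_closed.coords + mini_vft.ref_open.coords)
        assert mini_vft.energy(mini_vft.ref_closed.coords) < mini_vft.energy(mid)

    def test_steric_overlap_rejected(self):
        """Over-closing the jaw clashes the lobes and is refused."""
        with pytest.raises(ValueError, match="steric overlap"):
            make_mini_vft(hinge_angle_open=-30.0, seed=0)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            make_mini_vft(n_beads=3)

    def test_gradient_matches_finite_differences(self, mini_vft, rng):
        """Analytic double-basin forces vs central differences at 50
        thermally displaced configurations."""
        worst = 0.0
        for _ in range(50):
            x = mini_vft.ref_closed.coords + rng.normal(scale=0.05, size=(mini_vft.n_atoms, 3))
            g = mini_vft.gradient(x).ravel()
            flat = x.ravel()
            pick = rng.integers(0, flat.size, size=6)  # spot-check components
            eps = 1e-6
            for i in pick:
                xp, xm = flat.copy(), flat.copy()
                xp[i] += eps
                xm[i] -= eps
                fd = (mini_vft.energy(xp) - mini_vft.energy(xm)) / (2 * eps)
                worst = max(worst, abs(g[i] - fd))
        assert worst < 1e-4

    def test_string_barrier_in_design_band(self, mini_vft):
        """The default engineered barrier sits in the 6-8 kT band at 300 K."""
        B = minimum_energy_barrier(mini_vft, n_images=31, n_iter=200)
        assert 6.0 < B / kT_kcal(300.0) < 8.0


class TestLangevin:
    def test_harmonic_variance_matches_equipartition(self):
        k = 10.0  # kcal/mol/nm²
        pot = AnalyticPotential2D(
            lambda x: 0.5 * k * (x[0] ** 2 + x[1] ** 2),
            lambda x: k * np.asarray(x),
            ((-5, 5), (-5, 5)),
            mass=1.0,
        )
        tr = langevin_run(pot, (0.2, 0.0), n_steps=400_000, dt=0.01, friction=2.0,
                          temperature=300.0, seed=1, save_stride=5)
        expected = kT_kcal(300.0) / k
        assert tr.positions[:, 0].var() == pytest.approx(expected, rel=0.05)
        assert tr.positions[:, 1].var() == pytest.approx(expected, rel=0.05)

    def test_zero_temperature_stays_at_minimum(self):
        pot = make_double_well_1d(5.0)
        tr = langevin_run(pot, (1.0, 0.0), n_steps=2000, dt=0.005, friction=5.0,
                          temperature=0.0, seed=2, save_stride=10)
        assert np.allclose(tr.positions[:, 0], 1.0, atol=1e-6)

    def test_reproducible_under_seed(self, mini_vft):
        a = langevin_run(mini_vft, mini_vft.ref_closed, n_steps=500, seed=9)
        b = langevin_run(mini_vft, mini_vft.ref_closed, n_steps=500, seed=9)
        assert np.array_equal(a.frames[-1].coords, b.frames[-1].coords)

    def test_closed_start_never_commits_to_open(self, mini_vft):
        """At the default 6-8 kT barrier, a desk-scale unbiased run stays
        in its starting basin (the sampling problem the pipeline solves)."""
        traj = langevin_run(mini_vft, mini_vft.ref_closed, n_steps=30_000, seed=11, save_stride=30)
        for f in traj.frames:
            assert aligned_rmsd(f, mini_vft.ref_closed) < aligned_rmsd(f, mini_vft.ref_open)

    def test_integration_failure_names_step(self, mini_vft):
        with pytest.raises(IntegrationFailure, match="step"):
            langevin_run(mini_vft, mini_vft.ref_closed, n_steps=2000, dt=5.0, seed=1)

    def test_detailed_balance_well_populations(self):
        """Long unbiased sampling of a tilted double well reproduces the
        analytic Boltzmann population ratio within Monte-Carlo error (3σ)."""
        B, a, tilt, T = 1.2, 0.8, 0.5, 300.0
        pot = AnalyticPotential2D(
            lambda x: B * ((x[0] / a) ** 2 - 1) ** 2 + tilt * x[0],
            lambda x: np.array(
                [4 * B * x[0] * ((x[0] / a) ** 2 - 1) / a**2 + tilt]
                + [0.0] * (len(x) - 1)
            ),
            ((-3, 3), (-3, 3)),
            bias_dims=(0,),
            mass=1.0,
        )
        beta = 1.0 / (KB_KCAL * T)
        U = lambda u: B * ((u / a) ** 2 - 1) ** 2 + tilt * u
        zl, _ = quad(lambda u: np.exp(-beta * U(u)), -3, 0)
        zr, _ = quad(lambda u: np.exp(-beta * U(u)), 0, 3)
        p_left = zl / (zl + zr)
        tr = langevin_run(pot, (-a, 0.0), n_steps=600_000, dt=0.01, friction=2.0,
                          temperature=T, seed=4, save_stride=10)
        u = tr.positions[:, 0]
        frac = np.mean(u < 0)
        # effective samples limited by well-hopping correlation
        flips = np.sum(np.abs(np.diff((u > 0).astype(int))))
        sigma = np.sqrt(p_left * (1 - p_left) / max(flips, 1))
        assert abs(frac - p_left) < 3 * sigma + 0.02

    def test_seeds_statistically_indistinguishable(self, mini_vft):
        """Mean energies from different seeds agree (two-sample t-test)."""
        groups = []
        for seeds in ((21, 22, 23, 24, 25, 26, 27, 28, 29, 30),
                      (31, 32, 33, 34, 35, 36, 37, 38, 39, 40)):
            means = []
            for s in seeds:
                tr = langevin_run(mini_vft, mini_vft.ref_closed, n_steps=2000, seed=s,
                                  save_stride=20)
                means.append(np.mean([mini_vft.energy(f.coords) for f in tr.frames[20:]]))
            groups.append(means)
        _, p = ttest_ind(groups[0], groups[1])
        assert p > 0.01


class TestWideOpenExcursion:
    def test_zero_margin_ends_at_open_reference(self, mini_vft):
        exc = make_wide_open_excursion(mini_vft, seed=0, margin_deg=0.0, twist_deg=0.0,
                                       jitter=0.0)
        assert aligned_rmsd(exc.frames[-1], mini_vft.ref_open) == pytest.approx(0.0, abs=1e-12)

    def test_default_margin_exceeds_open_separation(self, mini_vft):
        exc = make_wide_open_excursion(mini_vft, seed=0)
        final = exc.frames[-1]
        assert aligned_rmsd(final, mini_vft.ref_open) > 0.05
        assert mini_vft.lobe_separation(final.coords) > mini_vft.lobe_separation(
            mini_vft.ref_open.coords
        )
        wide = wide_open_reference(mini_vft)
        assert mini_vft.lobe_separation(wide.coords) > mini_vft.lobe_separation(
            mini_vft.ref_open.coords
        )

    def test_deterministic_under_seed(self, mini_vft):
        a = make_wide_open_excursion(mini_vft, seed=5)
        b = make_wide_open_excursion(mini_vft, seed=5)
        assert np.array_equal(a.frames[-1].coords, b.frames[-1].coords)
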