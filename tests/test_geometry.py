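"""Superposition, aligned MSD/RMSD and fluctuation metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pathmetad.geometry import (
    DegenerateSuperpositionError,
    Structure,
    StructureCompatibilityError,
    aligned_msd,
    aligned_msd_many,
    aligned_msd_with_grad_many,
    aligned_rmsd,
    apply_transform,
    rmsd_to_references,
    rmsf,
    superpose,
)
from pathmetad.systems import langevin_run

from conftest import random_rigid_transform, random_structure


class TestSuperpose:
    def test_recovers_known_rigid_motion(self, rng):
        ref = random_structure(rng)
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        mobile = ref.with_coords(ref.coords @ R.T + t)
        tr = superpose(mobile, ref, subset="align")
        fitted = apply_transform(mobile, tr)
        assert np.allclose(fitted.coords, ref.coords, atol=1e-12)
        assert np.isclose(np.linalg.det(tr.rotation), 1.0)

    def test_identity_for_equal_structures(self, rng):
        s = random_structure(rng)
        tr = superpose(s, s)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(tr.translation, 0.0, atol=1e-10)

    def test_matches_brute_force_rotation_search(self, rng):
        """Fitted subset RMSD equals the best found by an independent
        search over rotation space (random restarts + local refinement)."""
        a = random_structure(rng, n_atoms=10, n_align=10)
        b = random_structure(rng, n_atoms=10, n_align=10)
        tr = superpose(a, b)
        fitted = apply_transform(a, tr)
        rmsd_fit = np.sqrt(np.mean(np.sum((fitted.coords - b.coords) ** 2, axis=1)))

        pa = a.coords - a.coords.mean(axis=0)
        pb = b.coords - b.coords.mean(axis=0)

        def cost(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.mean(np.sum((pa @ R.T - pb) ** 2, axis=1))

        best = np.inf
        for k in range(60):
            v = Rotation.random(random_state=k).as_rotvec()
            res = minimize(cost, v, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
            best = min(best, res.fun)
        assert np.sqrt(best) == pytest.approx(rmsd_fit, abs=1e-6)

    def test_too_few_and_collinear_subsets_rejected(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]])
        s2 = Structure(coords, subset_tags=("align", "align", "none", "measure"))
        with pytest.raises(DegenerateSuperpositionError, match=">= 3"):
            superpose(s2, s2)
        collinear = Structure(coords, subset_tags=("align", "align", "align", "measure"))
        with pytest.raises(DegenerateSuperpositionError, match="collinear"):
            superpose(collinear, collinear)


class TestAlignedMSD:
    def test_zero_for_identical_structures(self, rng):
        s = random_structure(rng)
        assert aligned_msd(s, s) == pytest.approx(0.0, abs=1e-18)

    def test_single_displaced_measure_atom(self, rng):
        """Displacing one of m measure atoms by d gives MSD = d²/m."""
        s = random_structure(rng, n_atoms=12, n_align=6)
        coords = s.coords.copy()
        d = 0.37
        coords[8] += d * np.array([0, 0, 1.0])
        moved = s.with_coords(coords)
        assert aligned_msd(moved, s) == pytest.approx(d**2 / 6, rel=1e-10)

    def test_rigid_motion_invariance(self, rng):
        """MSD is invariant when either input moves rigidly (to 1e-9 nm²)."""
        a = random_structure(rng)
        b = random_structure(rng)
        base = aligned_msd(a, b)
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            assert aligned_msd(a.with_coords(a.coords @ R.T + t), b) == pytest.approx(
                base, abs=1e-9
            )
            assert aligned_msd(a, b.with_coords(b.coords @ R.T + t)) == pytest.approx(
                base, abs=1e-9
            )

    def test_matches_quaternion_oracle_when_align_equals_measure(self, rng):
        """With align == measure the aligned MSD is the classic least-squares
        MSD; cross-check against MDAnalysis' QCP implementation."""
        qcp = pytest.importorskip("MDAnalysis.lib.qcprot")
        for _ in range(100):
            n = int(rng.integers(5, 20))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            sa = Structure(a)  # default tag "both": align == measure
            sb = Structure(b)
            ours = aligned_msd(sa, sb)
            ac = (a - a.mean(axis=0)).astype(np.float64)
            bc = (b - b.mean(axis=0)).astype(np.float64)
            rmsd_ref = qcp.CalcRMSDRotationalMatrix(ac, bc, n, None, None)
            assert ours == pytest.approx(rmsd_ref**2, rel=1e-8, abs=1e-12)

    def test_rmsd_symmetric_when_subsets_coincide(self, rng):
        a = Structure(rng.normal(size=(8, 3)))
        b = Structure(rng.normal(size=(8, 3)))
        assert aligned_rmsd(a, b) == pytest.approx(aligned_rmsd(b, a), rel=1e-10)

    def test_mismatched_atom_counts_rejected(self, rng):
        a = random_structure(rng, n_atoms=8)
        b = random_structure(rng, n_atoms=9, n_align=5)
        with pytest.raises(StructureCompatibilityError):
            aligned_msd(a, b)


class TestMSDGradient:
    def test_matches_finite_differences(self, rng):
        """Full analytic gradient (with alignment response) vs central
        differences, including deformed align subsets."""
        a = random_structure(rng, n_atoms=9, n_align=4)
        frames = [random_structure(rng, n_atoms=9, n_align=4) for _ in range(3)]
        # share tags so structures are compatible
        frames = [a.with_coords(f.coords) for f in frames]
        msd, grad = aligned_msd_with_grad_many(a, frames)
        eps = 1e-6
        for k in range(len(frames)):
            for i in range(a.n_atoms):
                for d in range(3):
                    cp = a.coords.copy()
                    cp[i, d] += eps
                    cm = a.coords.copy()
                    cm[i, d] -= eps
                    fd = (
                        aligned_msd(a.with_coords(cp), frames[k])
                        - aligned_msd(a.with_coords(cm), frames[k])
                    ) / (2 * eps)
                    assert grad[k, i, d] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_stationary_rotation_approximation_flagged(self, rng):
        """The quasi-static fast path is exact on measure atoms but differs
        on align atoms; the full gradient is the default."""
        a = random_structure(rng, n_atoms=9, n_align=4)
        f = a.with_coords(random_structure(rng, n_atoms=9, n_align=4).coords)
        _, g_full = aligned_msd_with_grad_many(a, [f])
        _, g_fast = aligned_msd_with_grad_many(a, [f], rotation_response=False)
        assert np.allclose(g_full[0, 4:], g_fast[0, 4:], atol=1e-12)
        assert not np.allclose(g_full[0, :4], g_fast[0, :4], atol=1e-3)


class TestRMSF:
    def test_identical_frames_give_zero(self, rng):
        s = random_structure(rng)
        assert np.allclose(rmsf([s.copy() for _ in range(5)], s), 0.0)

    def test_single_frame_warns(self, rng):
        s = random_structure(rng)
        with pytest.warns(UserWarning, match="single-frame"):
            out = rmsf([s], s)
        assert np.allclose(out, 0.0)

    def test_isotropic_jitter_gives_sigma_sqrt3(self, rng):
        """One atom jittered with isotropic Gaussian noise of std σ has
        RMSF ≈ σ√3 (Monte-Carlo check within 5%)."""
        base = random_structure(rng, n_atoms=10, n_align=6)
        sigma = 0.05
        frames = []
        for _ in range(10_000):
            c = base.coords.copy()
            c[9] += rng.normal(scale=sigma, size=3)
            frames.append(base.with_coords(c))
        fl = rmsf(frames, base, subset="align")
        assert fl[9] == pytest.approx(sigma * np.sqrt(3), rel=0.05)
        assert np.all(fl[:6] < 0.3 * sigma)

    def test_mobile_lobe_fluctuates_more(self, mini_vft):
        """Thermal motion of the hinged lobe exceeds that of the rigid
        reference lobe, as in the two-lobe construction."""
        traj = langevin_run(mini_vft, mini_vft.ref_closed, n_steps=6000, seed=7, save_stride=20)
        fl = rmsf(traj, mini_vft.ref_closed, subset="align")
        mob = fl[mini_vft.mobile_indices].mean()
        ref = fl[mini_vft.reference_lobe_indices].mean()
        assert mob > 2 * ref


class TestRMSDToReferences:
    def test_endpoint_frames(self, mini_vft):
        d_c, d_o = rmsd_to_references(
            [mini_vft.ref_closed], mini_vft.ref_closed, mini_vft.ref_open
        )
        sep = aligned_rmsd(mini_vft.ref_closed, mini_vft.ref_open)
        assert d_c[0] == pytest.approx(0.0, abs=1e-12)
        assert d_o[0] == pytest.approx(sep, rel=1e-12)
        d_c, d_o = rmsd_to_references(
            [mini_vft.ref_open], mini_vft.ref_closed, mini_vft.ref_open
        )
        assert d_c[0] == pytest.approx(sep, rel=1e-12)
        assert d_o[0] == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_lies_between(self, mini_vft):
        mid = mini_vft.ref_closed.with_coords(
            0.5 * (mini_vft.ref_closed.coords + mini_vft.ref_open.coords)
        )
        d_c, d_o = rmsd_to_references([mid], mini_vft.ref_closed, mini_vft.ref_open)
        sep = aligned_rmsd(mini_vft.ref_closed, mini_vft.ref_open)
        assert 0 < d_c[0] < sep
        assert 0 < d_o[0] < sep
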