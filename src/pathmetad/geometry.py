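"""Rigid-body superposition and displacement metrics on bead structures.

The central convention throughout the package is the separation of an
*alignment* subset from a *measurement* subset: structures are first
superposed by least squares on the alignment atoms (the rigid lobe), and
displacements are then measured on the measurement atoms (the mobile lobe).
All coordinates are in nm and all squared displacements in nm²; Å appears
only at file-format and report boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "RigidTransform",
    "DegenerateSuperpositionError",
    "StructureCompatibilityError",
    "superpose",
    "apply_transform",
    "aligned_msd",
    "aligned_msd_many",
    "aligned_rmsd",
    "rmsf",
    "rmsd_to_references",
]

VALID_TAGS = ("align", "measure", "both", "none")


class DegenerateSuperpositionError(ValueError):
    """Raised when a superposition subset is too small or collinear."""


class StructureCompatibilityError(ValueError):
    """Raised when two structures cannot be compared atom by atom."""


@dataclass
class Structure:
    """An ordered set of bead positions with subset tags.

    Parameters
    ----------
    coords : (n_atoms, 3) float array, nm
    atom_ids : ordered atom labels; defaults to "B0", "B1", ...
    subset_tags : per-atom tag from {"align", "measure", "both", "none"};
        defaults to "both" for every atom.
    """

    coords: np.ndarray
    atom_ids: tuple = None
    subset_tags: tuple = None
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        n = len(self.coords)
        if self.atom_ids is None:
            self.atom_ids = tuple(f"B{i}" for i in range(n))
        else:
            self.atom_ids = tuple(self.atom_ids)
        if self.subset_tags is None:
            self.subset_tags = ("both",) * n
        else:
            self.subset_tags = tuple(self.subset_tags)
            bad = set(self.subset_tags) - set(VALID_TAGS)
            if bad:
                raise ValueError(f"unknown subset tags: {sorted(bad)}")
        if len(self.atom_ids) != n or len(self.subset_tags) != n:
            raise ValueError("atom_ids/subset_tags length mismatch with coords")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def subset_indices(self, subset: str) -> np.ndarray:
        """Indices of atoms belonging to the given subset ('align'|'measure')."""
        if subset not in ("align", "measure"):
            raise ValueError(f"subset must be 'align' or 'measure', got {subset!r}")
        tags = np.asarray(self.subset_tags)
        return np.flatnonzero((tags == subset) | (tags == "both"))

    def with_coords(self, coords: np.ndarray, label: str = None) -> "Structure":
        return Structure(
            coords=np.asarray(coords, dtype=float),
            atom_ids=self.atom_ids,
            subset_tags=self.subset_tags,
            label=self.label if label is None else label,
        )

    def copy(self) -> "Structure":
        return self.with_coords(self.coords.copy())


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation (proper rotation, det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def _check_compatible(a: Structure, b: Structure) -> None:
    if a.n_atoms != b.n_atoms:
        raise StructureCompatibilityError(
            f"atom counts differ: {a.n_atoms} vs {b.n_atoms}"
        )
    if a.subset_tags != b.subset_tags:
        raise StructureCompatibilityError("subset tags differ between structures")


def _check_subset_wellposed(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise DegenerateSuperpositionError(
            f"superposition needs >= 3 subset atoms, got {len(pts)}"
        )
    centered = pts - pts.mean(axis=0)
    # rank < 2 means the subset is collinear (or a single point)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1e-30) or s[0] < 1e-12:
        raise DegenerateSuperpositionError(
            "superposition subset is collinear; rotation is ill-conditioned"
        )


def superpose(mobile: Structure, reference: Structure, subset: str = "align") -> RigidTransform:
    """Least-squares rigid transform taking `mobile` onto `reference`.

    The transform minimizes the squared deviation over the given subset and
    its rotation is always proper (reflections corrected). Kabsch problem
    solved through :func:`scipy.spatial.transform.Rotation.align_vectors`.
    """
    _check_compatible(mobile, reference)
    idx = mobile.subset_indices(subset)
    pm = mobile.coords[idx]
    pr = reference.coords[idx]
    _check_subset_wellposed(pm)
    cm = pm.mean(axis=0)
    cr = pr.mean(axis=0)
    rot, _ = Rotation.align_vectors(pr - cr, pm - cm)
    R = rot.as_matrix()
    return RigidTransform(rotation=R, translation=cr - R @ cm)


def apply_transform(structure: Structure, transform: RigidTransform) -> Structure:
    return structure.with_coords(transform.apply(structure.coords))


def _batch_kabsch(mobile_pts: np.ndarray, ref_pts: np.ndarray):
    """Proper rotations aligning each ref_pts[k] onto the common mobile_pts.

    mobile_pts : (m, 3) centered;  ref_pts : (K, m, 3) centered.
    Returns (K, 3, 3) rotations R_k such that ``x @ R_k.T ~ ref_k``.
    """
    H = np.einsum("kmi,mj->kij", ref_pts, mobile_pts)  # (K,3,3)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("kij,kjl->kil", U, Vt)))
    U = U.copy()
    U[:, :, 2] *= d[:, None]
    return np.einsum("kij,kjl->kil", U, Vt)


class FramePack:
    """Precomputed centered align/measure coordinate stacks for a frame list.

    Building the stacked arrays once makes repeated MSD/gradient evaluation
    against the same frames (the inner loop of path-CV dynamics) cheap.
    """

    def __init__(self, frames: Sequence[Structure], measure: str = "measure"):
        ref = frames[0]
        self.a_idx = ref.subset_indices("align")
        self.m_idx = (
            np.arange(ref.n_atoms) if measure == "all" else ref.subset_indices("measure")
        )
        if len(self.a_idx) < 3:
            raise DegenerateSuperpositionError(
                f"superposition needs >= 3 align atoms, got {len(self.a_idx)}"
            )
        self.n_atoms = ref.n_atoms
        fa = np.stack([f.coords[self.a_idx] for f in frames])  # (K, na, 3)
        self.cf = fa.mean(axis=1)
        self.qpts = fa - self.cf[:, None, :]
        fm = np.stack([f.coords[self.m_idx] for f in frames])
        self.fm = fm - self.cf[:, None, :]

    def __len__(self):
        return len(self.qpts)


def _pack_msd(coords: np.ndarray, pack: FramePack):
    """MSDs plus intermediates shared with the gradient path."""
    xa = coords[pack.a_idx]
    ca = xa.mean(axis=0)
    p = xa - ca
    S = np.einsum("ai,kaj->kij", p, pack.qpts)
    quat, R, evals, evecs = _quaternion_rotations(S)
    xm = coords[pack.m_idx] - ca
    diff = np.einsum("kij,mj->kmi", R, xm) - pack.fm
    msd = np.einsum("kmi,kmi->k", diff, diff) / len(pack.m_idx)
    return msd, (R, quat, evals, evecs, xm, diff)


def aligned_msd_many(
    x: Structure, frames: Sequence[Structure] = None, measure: str = "measure",
    pack: FramePack = None,
) -> np.ndarray:
    """MSD (nm²) of `x` against each frame: align on the align subset, measure
    on the measure subset (or every atom with ``measure='all'``). Vectorized
    over frames (shared Kabsch batch); pass a :class:`FramePack` to reuse
    precomputed frame arrays."""
    if pack is None:
        for f in frames:
            _check_compatible(x, f)
        pack = FramePack(frames, measure=measure)
        _check_subset_wellposed(x.coords[pack.a_idx])
    msd, _ = _pack_msd(x.coords, pack)
    return msd


def _quaternion_rotations(S: np.ndarray):
    """Optimal rotations from Horn's quaternion method, batched.

    S : (K, 3, 3) correlation matrices Σ_a p_a q_aᵀ between centered mobile
    points p and centered reference points q. Returns the unit quaternions
    (K, 4), rotation matrices (K, 3, 3) mapping p onto q, and the full
    eigensystem of the 4x4 Horn matrices (needed for gradients).
    """
    K = len(S)
    N = np.empty((K, 4, 4))
    S00, S01, S02 = S[:, 0, 0], S[:, 0, 1], S[:, 0, 2]
    S10, S11, S12 = S[:, 1, 0], S[:, 1, 1], S[:, 1, 2]
    S20, S21, S22 = S[:, 2, 0], S[:, 2, 1], S[:, 2, 2]
    N[:, 0, 0] = S00 + S11 + S22
    N[:, 0, 1] = N[:, 1, 0] = S12 - S21
    N[:, 0, 2] = N[:, 2, 0] = S20 - S02
    N[:, 0, 3] = N[:, 3, 0] = S01 - S10
    N[:, 1, 1] = S00 - S11 - S22
    N[:, 1, 2] = N[:, 2, 1] = S01 + S10
    N[:, 1, 3] = N[:, 3, 1] = S20 + S02
    N[:, 2, 2] = -S00 + S11 - S22
    N[:, 2, 3] = N[:, 3, 2] = S12 + S21
    N[:, 3, 3] = -S00 - S11 + S22
    evals, evecs = np.linalg.eigh(N)  # ascending
    q = evecs[:, :, 3]  # top eigenvector
    w, xq, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    R = np.empty((K, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (xq * y - w * z)
    R[:, 0, 2] = 2 * (xq * z + w * y)
    R[:, 1, 0] = 2 * (xq * y + w * z)
    R[:, 1, 1] = 1 - 2 * (xq * xq + z * z)
    R[:, 1, 2] = 2 * (y * z - w * xq)
    R[:, 2, 0] = 2 * (xq * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * xq)
    R[:, 2, 2] = 1 - 2 * (xq * xq + y * y)
    return q, R, evals, evecs


def _dR_dq(q: np.ndarray):
    """d(rotation matrix)/d(unit quaternion), batched: (K, 3, 3, 4)."""
    K = len(q)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    D = np.zeros((K, 3, 3, 4))
    zero = np.zeros(K)
    D[:, 0, 0] = np.stack([zero, zero, -4 * y, -4 * z], axis=1)
    D[:, 0, 1] = np.stack([-2 * z, 2 * y, 2 * x, -2 * w], axis=1)
    D[:, 0, 2] = np.stack([2 * y, 2 * z, 2 * w, 2 * x], axis=1)
    D[:, 1, 0] = np.stack([2 * z, 2 * y, 2 * x, 2 * w], axis=1)
    D[:, 1, 1] = np.stack([zero, -4 * x, zero, -4 * z], axis=1)
    D[:, 1, 2] = np.stack([-2 * x, -2 * w, 2 * z, 2 * y], axis=1)
    D[:, 2, 0] = np.stack([-2 * y, 2 * z, -2 * w, 2 * x], axis=1)
    D[:, 2, 1] = np.stack([2 * x, 2 * w, 2 * z, 2 * y], axis=1)
    D[:, 2, 2] = np.stack([zero, -4 * x, -4 * y, zero], axis=1)
    return D


def aligned_msd_with_grad_many(
    x: Structure,
    frames: Sequence[Structure] = None,
    rotation_response: bool = True,
    pack: FramePack = None,
):
    """MSDs (nm²) against each frame plus their gradients w.r.t. x's coords.

    The gradient is the full analytic derivative including the response of
    the optimal rotation to the alignment atoms, obtained by first-order
    perturbation of the Horn quaternion eigenproblem. With
    ``rotation_response=False`` the rotation is treated as quasi-static (a
    cheaper approximation, exact only when align == measure). Returns
    ``(msd (K,), grad (K, n_atoms, 3))``; pass a :class:`FramePack` to reuse
    precomputed frame arrays.
    """
    if pack is None:
        for f in frames:
            _check_compatible(x, f)
        pack = FramePack(frames)
        _check_subset_wellposed(x.coords[pack.a_idx])
    msd, (R, quat, evals, evecs, xm, diff) = _pack_msd(x.coords, pack)
    a_idx, m_idx, qpts = pack.a_idx, pack.m_idx, pack.qpts
    m = len(m_idx)
    K = len(pack)

    back = np.einsum("kji,kmj->kmi", R, diff)  # Rᵀ diff
    grad = np.zeros((K, pack.n_atoms, 3))
    grad[:, m_idx, :] += (2.0 / m) * back
    # alignment-centroid response: moving align atoms shifts the centroid
    grad[:, a_idx, :] -= (2.0 / (m * len(a_idx))) * back.sum(axis=1)[:, None, :]

    if rotation_response:
        # T = dMSD/dR, then chain through the quaternion eigenproblem to S
        T = (2.0 / m) * np.einsum("kmi,mj->kij", diff, xm)  # (K,3,3)
        D = _dR_dq(quat)  # (K,3,3,4)
        g_q = np.einsum("kij,kijl->kl", T, D)  # dMSD/dq
        # pseudo-inverse of (λ_max I - N) in the eigenbasis, excluding q itself
        lam_max = evals[:, 3]
        gaps = lam_max[:, None] - evals[:, :3]  # (K,3) positive gaps
        gaps = np.maximum(gaps, 1e-10)
        coef = np.einsum("kl,klr->kr", g_q, evecs[:, :, :3]) / gaps  # (K,3)
        M4 = np.einsum("kr,klr->kl", coef, evecs[:, :, :3])  # (λI−N)⁺ g_q
        W = np.einsum("kl,km->klm", M4, quat)
        Y = W + W.transpose(0, 2, 1)
        G3 = np.empty((K, 3, 3))
        G3[:, 0, 0] = W[:, 0, 0] + W[:, 1, 1] - W[:, 2, 2] - W[:, 3, 3]
        G3[:, 1, 1] = W[:, 0, 0] - W[:, 1, 1] + W[:, 2, 2] - W[:, 3, 3]
        G3[:, 2, 2] = W[:, 0, 0] - W[:, 1, 1] - W[:, 2, 2] + W[:, 3, 3]
        G3[:, 1, 2] = Y[:, 0, 1] + Y[:, 2, 3]
        G3[:, 2, 1] = -Y[:, 0, 1] + Y[:, 2, 3]
        G3[:, 2, 0] = Y[:, 0, 2] + Y[:, 1, 3]
        G3[:, 0, 2] = -Y[:, 0, 2] + Y[:, 1, 3]
        G3[:, 0, 1] = Y[:, 0, 3] + Y[:, 1, 2]
        G3[:, 1, 0] = -Y[:, 0, 3] + Y[:, 1, 2]
        # dS_ij/dx_a = δ q_a,j (centering term vanishes: Σ_a q_a = 0)
        grad[:, a_idx, :] += np.einsum("kij,kaj->kai", G3, qpts)
    return msd, grad


def aligned_msd(x: Structure, frame: Structure) -> float:
    """Mean squared displacement (nm²) of the measure subset after optimal
    superposition on the align subset."""
    return float(aligned_msd_many(x, [frame])[0])


def aligned_rmsd(x: Structure, frame: Structure) -> float:
    """RMSD (nm) over the measure subset after align-subset superposition."""
    return float(np.sqrt(aligned_msd(x, frame)))


def rmsf(traj, reference: Structure, subset: str = "align") -> np.ndarray:
    """Per-atom root-mean-square fluctuation (nm) about the mean structure.

    Every frame is first superposed on `reference` using the given subset;
    fluctuations are then taken about the per-atom mean over frames.
    """
    frames = list(traj.frames) if hasattr(traj, "frames") else list(traj)
    if not frames:
        raise ValueError("trajectory is empty")
    if len(frames) == 1:
        warnings.warn("single-frame trajectory: RMSF is identically zero")
        return np.zeros(frames[0].n_atoms)
    coords = np.empty((len(frames), frames[0].n_atoms, 3))
    for k, f in enumerate(frames):
        t = superpose(f, reference, subset=subset)
        coords[k] = t.apply(f.coords)
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsd_to_references(traj, ref_closed: Structure, ref_open: Structure):
    """Paired RMSD series (nm) of every frame against the two end states.

    Used for the 2D-RMSD projection that shows basins never interconverting
    in unbiased sampling.
    """
    frames = list(traj.frames) if hasattr(traj, "frames") else list(traj)
    d_closed = np.array([aligned_rmsd(f, ref_closed) for f in frames])
    d_open = np.array([aligned_rmsd(f, ref_open) for f in frames])
    return d_closed, d_open
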