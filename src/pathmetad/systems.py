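"""Synthetic systems: analytic benchmark potentials, the two-lobe "mini-VFT"
bead model, and a BAOAB Langevin integrator.

The mini-VFT emulates a bilobed clamshell domain: a rigid reference lobe
(the alignment subset) and a mobile lobe (the measurement subset) joined at
a hinge. Its energy is a double-basin mixture of two elastic networks, one
built around the closed reference and one around the open reference, so the
model has exactly two metastable conformations separated by a tunable
barrier. Unbiased Langevin trajectories started in either basin stay there
on any affordable timescale, which is precisely the sampling problem the
path-metadynamics pipeline is built to solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import logsumexp

from .geometry import Structure
from .units import KB_KJ, KCAL_TO_KJ

__all__ = [
    "AnalyticPotential2D",
    "MiniVFTModel",
    "Trajectory",
    "CVTrace",
    "IntegrationFailure",
    "make_double_well_1d",
    "make_mini_vft",
    "make_symmetric_mini_vft",
    "langevin_run",
    "make_wide_open_excursion",
    "minimum_energy_barrier",
]


class IntegrationFailure(RuntimeError):
    """Raised when the integrator produces non-finite coordinates."""


# ---------------------------------------------------------------------------
# Analytic potentials
# ---------------------------------------------------------------------------

@dataclass
class AnalyticPotential2D:
    """Analytic potential over (u, v) with gradient, in kcal/mol and nm.

    ``bias_dims`` lists which coordinates serve as collective variables when
    the potential is used to exercise the metadynamics engine; a double well
    that is flat in v is biased on u alone.
    """

    energy_fn: Callable[[np.ndarray], float]
    gradient_fn: Callable[[np.ndarray], np.ndarray]
    domain: tuple  # ((u_min, u_max), (v_min, v_max))
    stationary_points: tuple = ()
    bias_dims: tuple = (0, 1)
    mass: float = 1.0
    label: str = ""

    n_dof: int = 2

    def energy(self, x: np.ndarray) -> float:
        return float(self.energy_fn(np.asarray(x, dtype=float)))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.gradient_fn(np.asarray(x, dtype=float)), dtype=float)


def make_double_well_1d(barrier: float, minima_separation: float = 2.0) -> AnalyticPotential2D:
    """Symmetric quartic double well in u, flat in v.

    U(u) = barrier * ((u/a)^2 - 1)^2 with a = minima_separation / 2, so the
    two minima sit at u = ±a with U = 0 and the saddle at u = 0 has height
    exactly ``barrier`` (kcal/mol).
    """
    if barrier <= 0:
        raise ValueError(f"barrier must be positive, got {barrier}")
    if minima_separation <= 0:
        raise ValueError("minima_separation must be positive")
    a = minima_separation / 2.0
    B = float(barrier)

    def energy(x):
        u = x[0]
        return B * (u * u / (a * a) - 1.0) ** 2

    def gradient(x):
        u = x[0]
        g = np.zeros_like(np.asarray(x, dtype=float))
        g[0] = 4.0 * B * u * (u * u / (a * a) - 1.0) / (a * a)
        return g

    return AnalyticPotential2D(
        energy_fn=energy,
        gradient_fn=gradient,
        domain=((-2.0 * a, 2.0 * a), (-2.0 * a, 2.0 * a)),
        stationary_points=((-a, 0.0), (0.0, 0.0), (a, 0.0)),
        bias_dims=(0,),
        mass=10.0,  # heavy enough that barrier attempts are rare at 300 K
        label=f"double_well(barrier={B:g},sep={minima_separation:g})",
    )


# ---------------------------------------------------------------------------
# Mini-VFT bead model
# ---------------------------------------------------------------------------

def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


def _helix_lobe(n_beads: int, z_sign: float, phase: float, rng: np.random.Generator) -> np.ndarray:
    """Compact helical bead arrangement for one jaw lobe.

    The helix axis runs along +y away from the hinge (at the origin); the
    two lobes are offset by ±z0 in z so their faces meet across the z = 0
    cleft, like the two halves of a clamshell seen from the hinge.
    """
    radius, pitch, turn, y0, z0, squash = 0.45, 0.18, 2.2, 0.35, 0.45, 0.55
    j = np.arange(n_beads)
    pts = np.stack(
        [
            radius * np.cos(turn * j + phase),
            y0 + pitch * j,
            z_sign * z0 + squash * radius * np.sin(turn * j + phase),
        ],
        axis=1,
    )
    # small deterministic jitter breaks exact symmetries of the helix
    pts += rng.normal(scale=0.03, size=pts.shape)
    return pts


@dataclass
class MiniVFTModel:
    """Two-lobe bead model with a double-basin elastic-network energy.

    E(x) = -(1/beta_mix) ln( exp(-beta_mix E_closed(x)) + exp(-beta_mix E_open(x)) )

    where each basin energy is an elastic network (harmonic pair restraints
    to the reference distances) built around its own reference structure.
    The reference-lobe beads are identical in both references, so the
    alignment subset is genuinely rigid across the transition.
    """

    ref_closed: Structure
    ref_open: Structure
    pairs: np.ndarray  # (n_pairs, 2) int
    k_pair: np.ndarray  # (n_pairs,) kcal/mol/nm²
    d0_closed: np.ndarray  # (n_pairs,) nm
    d0_open: np.ndarray
    beta_mix: float  # 1/(kcal/mol)
    temperature: float = 300.0
    mass: float = 100.0  # g/mol per bead
    seed: int = 0
    hinge_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    hinge_angle_open: float = 25.0  # degrees

    @property
    def n_atoms(self) -> int:
        return self.ref_closed.n_atoms

    @property
    def n_dof(self) -> int:
        return 3 * self.n_atoms

    @property
    def mobile_indices(self) -> np.ndarray:
        return self.ref_closed.subset_indices("measure")

    @property
    def reference_lobe_indices(self) -> np.ndarray:
        return self.ref_closed.subset_indices("align")

    def _basin_energy_grad(self, coords: np.ndarray, d0: np.ndarray):
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        dv = coords[i] - coords[j]
        d = np.linalg.norm(dv, axis=1)
        delta = d - d0
        e = 0.5 * np.sum(self.k_pair * delta * delta)
        f = (self.k_pair * delta / np.maximum(d, 1e-12))[:, None] * dv
        grad = np.zeros_like(coords)
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)
        return e, grad

    def energy_components(self, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        ec, gc = self._basin_energy_grad(coords, self.d0_closed)
        eo, go = self._basin_energy_grad(coords, self.d0_open)
        return ec, eo, gc, go

    def energy(self, coords: np.ndarray) -> float:
        ec, eo, _, _ = self.energy_components(coords)
        b = self.beta_mix
        return float(-logsumexp([-b * ec, -b * eo]) / b)

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        shape = np.shape(coords)
        ec, eo, gc, go = self.energy_components(coords)
        if not (math.isfinite(ec) and math.isfinite(eo)):
            # overflow propagates to the integrator, which reports the step
            return np.full(shape, np.nan)
        b = self.beta_mix
        # softmin weights, computed stably
        m = min(ec, eo)
        wc = math.exp(-b * (ec - m))
        wo = math.exp(-b * (eo - m))
        tot = wc + wo
        g = (wc / tot) * gc + (wo / tot) * go
        return g.reshape(shape)

    def structure(self, coords: np.ndarray, label: str = "") -> Structure:
        return self.ref_closed.with_coords(
            np.asarray(coords, dtype=float).reshape(self.n_atoms, 3), label=label
        )

    def lobe_separation(self, coords: np.ndarray) -> float:
        """Distance between the centroids of the two lobes (nm)."""
        c = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return float(
            np.linalg.norm(
                c[self.mobile_indices].mean(axis=0)
                - c[self.reference_lobe_indices].mean(axis=0)
            )
        )

    def hinge_rotated(self, angle_deg: float, twist_deg: float = 0.0) -> Structure:
        """Rigidly rotate the mobile lobe about the hinge from the closed pose.

        ``angle_deg`` opens about the hinge axis (through the origin);
        ``twist_deg`` then spins the lobe about its own long axis (through
        its centroid), which leaves the lobe separation set by the opening
        angle but moves the beads off the pure hinge path — the wide-open
        excursion geometry.
        """
        coords = self.ref_closed.coords.copy()
        mob = self.mobile_indices
        R = _rotation_about(self.hinge_axis, math.radians(angle_deg))
        coords[mob] = coords[mob] @ R.T
        if twist_deg:
            cen = coords[mob].mean(axis=0)
            Rt = _rotation_about(cen, math.radians(twist_deg))  # axis hinge->centroid
            coords[mob] = (coords[mob] - cen) @ Rt.T + cen
        return self.ref_closed.with_coords(coords, label=f"hinge_{angle_deg:g}")

    def rigid_hinge_path(self, n_images: int = 61) -> list:
        """Rigid hinge interpolation from the closed to the open reference."""
        angles = np.linspace(0.0, self.hinge_angle_open, n_images)
        return [self.hinge_rotated(a) for a in angles]


def make_mini_vft(
    n_beads: int = 8,
    hinge_angle_open: float = 25.0,
    barrier_scale: float = 1.0,
    seed: int = 0,
    temperature: float = 300.0,
    beta_mix: float = 2.0,
    k_intra: float = 400.0,
    k_inter: float = 6.0,
    inter_cutoff: float = 1.4,
) -> MiniVFTModel:
    """Construct a mini-VFT model with ``n_beads`` beads per lobe.

    The closed reference has the mobile lobe folded against the reference
    lobe; the open reference rotates the mobile lobe by ``hinge_angle_open``
    degrees about the hinge axis. Intra-lobe elastic pairs (all pairs, stiff)
    keep each lobe rigid; inter-lobe pairs within ``inter_cutoff`` nm of the
    respective reference define the two basins. ``barrier_scale`` multiplies
    the inter-lobe spring constant and hence the transition barrier.

    Default parameters give a barrier of roughly 6-8 kT at 300 K on the
    minimum-energy path, low enough for well-tempered metadynamics to
    converge at small scale while still prohibitive for unbiased sampling.
    """
    if n_beads < 4:
        raise ValueError("need at least 4 beads per lobe")
    rng = np.random.default_rng(seed)
    lower = _helix_lobe(n_beads, z_sign=-1.0, phase=0.0, rng=rng)
    upper = _helix_lobe(n_beads, z_sign=+1.0, phase=0.7, rng=rng)
    coords_closed = np.vstack([lower, upper])
    tags = ("align",) * n_beads + ("measure",) * n_beads
    ref_closed = Structure(coords_closed, subset_tags=tags, label="closed")

    axis = np.array([1.0, 0.0, 0.0])
    R = _rotation_about(axis, math.radians(hinge_angle_open))
    coords_open = coords_closed.copy()
    coords_open[n_beads:] = coords_open[n_beads:] @ R.T
    ref_open = Structure(coords_open, subset_tags=tags, label="open")

    for name, c in (("closed", coords_closed), ("open", coords_open)):
        dmat = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < 0.2:
            raise ValueError(
                f"steric overlap in {name} reference: minimum bead distance "
                f"{dmat.min():.3f} nm < 0.2 nm (hinge angle {hinge_angle_open} deg)"
            )

    # pair list: all intra-lobe pairs, plus inter-lobe contacts present in
    # either reference within the cutoff
    pairs, ks = [], []
    for lobe in (range(n_beads), range(n_beads, 2 * n_beads)):
        lobe = list(lobe)
        for a in range(len(lobe)):
            for b in range(a + 1, len(lobe)):
                pairs.append((lobe[a], lobe[b]))
                ks.append(k_intra)
    dc = np.linalg.norm(
        coords_closed[:n_beads, None, :] - coords_closed[None, n_beads:, :], axis=2
    )
    do = np.linalg.norm(
        coords_open[:n_beads, None, :] - coords_open[None, n_beads:, :], axis=2
    )
    inter = np.argwhere((dc < inter_cutoff) | (do < inter_cutoff))
    if len(inter) < 3:
        raise ValueError("too few inter-lobe contacts; increase inter_cutoff")
    for a, b in inter:
        pairs.append((int(a), int(b) + n_beads))
        ks.append(k_inter * barrier_scale)

    pairs = np.array(pairs, dtype=int)
    ks = np.array(ks, dtype=float)
    i, j = pairs[:, 0], pairs[:, 1]
    d0c = np.linalg.norm(coords_closed[i] - coords_closed[j], axis=1)
    d0o = np.linalg.norm(coords_open[i] - coords_open[j], axis=1)

    return MiniVFTModel(
        ref_closed=ref_closed,
        ref_open=ref_open,
        pairs=pairs,
        k_pair=ks,
        d0_closed=d0c,
        d0_open=d0o,
        beta_mix=beta_mix,
        temperature=temperature,
        seed=seed,
        hinge_axis=axis,
        hinge_angle_open=hinge_angle_open,
    )


def _c2_cluster(
    n_beads: int, y_lo: float, y_hi: float, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Bead cluster exactly symmetric under the C2 rotation about the y axis.

    Beads come in partner pairs (x, y, z) / (−x, y, −z); bead i and bead
    i + n/2 are C2 images. n_beads must be even.
    """
    half = n_beads // 2
    y = np.linspace(y_lo, y_hi, half)
    phi = 2.4 * np.arange(half)
    gen = np.stack([radius * np.cos(phi), y, radius * np.sin(phi)], axis=1)
    gen += rng.normal(scale=0.03, size=gen.shape)
    partner = gen * np.array([-1.0, 1.0, -1.0])
    return np.vstack([gen, partner])


def make_symmetric_mini_vft(
    n_beads: int = 8,
    half_angle: float = 13.0,
    k_intra: float = 400.0,
    k_inter: float = 10.0,
    inter_cutoff: float = 1.6,
    temperature: float = 300.0,
    beta_mix: float = 2.0,
    seed: int = 0,
) -> MiniVFTModel:
    """Two-state hinge model whose basins are iso-energetic *by construction*.

    A fixed collar lobe and a mobile arm lobe sit end to end along the y
    axis, both built as exactly C2-symmetric bead clusters about that axis.
    The two reference states tilt the arm by ∓``half_angle`` degrees about
    the hinge (x axis). The C2 rotation about y (x → −x, z → −z, beads
    permuted to their partners) is an exact isometry of the energy that
    exchanges the two basins, so their free energies are equal to machine
    precision — the controlled setting for testing whether the sampling
    machinery recovers iso-energetic minima.

    ``n_beads`` per lobe must be even.
    """
    if n_beads < 4 or n_beads % 2:
        raise ValueError("need an even number of beads >= 4 per lobe")
    rng = np.random.default_rng(seed)
    collar = _c2_cluster(n_beads, 0.30, 1.00, 0.42, rng)
    arm_base = _c2_cluster(n_beads, 1.30, 2.10, 0.38, rng)

    R_minus = _rotation_about(np.array([1.0, 0.0, 0.0]), math.radians(-half_angle))
    R_plus = _rotation_about(np.array([1.0, 0.0, 0.0]), math.radians(half_angle))
    coords_closed = np.vstack([collar, arm_base @ R_minus.T])
    coords_open = np.vstack([collar, arm_base @ R_plus.T])
    tags = ("align",) * n_beads + ("measure",) * n_beads
    ref_closed = Structure(coords_closed, subset_tags=tags, label="closed")
    ref_open = Structure(coords_open, subset_tags=tags, label="open")

    for name, c in (("closed", coords_closed), ("open", coords_open)):
        dmat = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < 0.2:
            raise ValueError(
                f"steric overlap in {name} reference: minimum bead distance "
                f"{dmat.min():.3f} nm < 0.2 nm (half angle {half_angle} deg)"
            )

    pairs, ks = [], []
    for lobe in (range(n_beads), range(n_beads, 2 * n_beads)):
        lobe = list(lobe)
        for a in range(len(lobe)):
            for b in range(a + 1, len(lobe)):
                pairs.append((lobe[a], lobe[b]))
                ks.append(k_intra)
    dc = np.linalg.norm(
        coords_closed[:n_beads, None, :] - coords_closed[None, n_beads:, :], axis=2
    )
    do = np.linalg.norm(
        coords_open[:n_beads, None, :] - coords_open[None, n_beads:, :], axis=2
    )
    inter = np.argwhere((dc < inter_cutoff) | (do < inter_cutoff))
    if len(inter) < 3:
        raise ValueError("too few inter-lobe contacts; increase inter_cutoff")
    for a, b in inter:
        pairs.append((int(a), int(b) + n_beads))
        ks.append(k_inter)

    pairs = np.array(pairs, dtype=int)
    ks = np.array(ks, dtype=float)
    i, j = pairs[:, 0], pairs[:, 1]
    d0c = np.linalg.norm(coords_closed[i] - coords_closed[j], axis=1)
    d0o = np.linalg.norm(coords_open[i] - coords_open[j], axis=1)

    return MiniVFTModel(
        ref_closed=ref_closed,
        ref_open=ref_open,
        pairs=pairs,
        k_pair=ks,
        d0_closed=d0c,
        d0_open=d0o,
        beta_mix=beta_mix,
        temperature=temperature,
        seed=seed,
        hinge_axis=np.array([1.0, 0.0, 0.0]),
        hinge_angle_open=2.0 * half_angle,
    )


def c2_image(model: MiniVFTModel, coords: np.ndarray) -> np.ndarray:
    """The C2-symmetry image of a configuration of the symmetric model.

    Rotates by π about the y axis and permutes each bead onto its C2
    partner (i ↔ i + n/2 within each lobe). For a model built by
    :func:`make_symmetric_mini_vft`, the energy satisfies
    ``E_closed(c2_image(x)) == E_open(x)`` to machine precision.
    """
    n = model.n_atoms // 2
    half = n // 2
    c = np.asarray(coords, dtype=float).reshape(model.n_atoms, 3)
    rot = c * np.array([-1.0, 1.0, -1.0])
    perm = np.empty(model.n_atoms, dtype=int)
    for lobe0 in (0, n):
        perm[lobe0 : lobe0 + half] = np.arange(lobe0 + half, lobe0 + n)
        perm[lobe0 + half : lobe0 + n] = np.arange(lobe0, lobe0 + half)
    return rot[perm]


# ---------------------------------------------------------------------------
# Trajectories and the integrator
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered bead-model frames with sampling metadata."""

    frames: list
    timestep: float  # ps between saved frames
    temperature: float
    seed: Optional[int] = None
    label: str = ""

    def __post_init__(self):
        if self.frames and len({f.n_atoms for f in self.frames}) > 1:
            raise ValueError("frames are structurally incompatible")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    def __len__(self):
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.timestep

    def coords_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])


@dataclass
class CVTrace:
    """Saved low-dimensional state of a run on an analytic potential."""

    times: np.ndarray
    positions: np.ndarray  # (n_saved, n_dof)
    temperature: float
    seed: Optional[int] = None
    label: str = ""


def _baoab_run(
    energy_grad,
    x0: np.ndarray,
    masses: np.ndarray,
    n_steps: int,
    dt: float,
    friction: float,
    temperature: float,
    rng: np.random.Generator,
    bias_force=None,
    callback=None,
    save_stride: int = 10,
):
    """BAOAB Langevin splitting; returns saved positions (kcal/mol input units).

    ``energy_grad(x) -> grad`` in kcal/mol/nm on the flat coordinate vector;
    ``bias_force(step, x) -> force`` (kcal/mol/nm, added to the physical
    force); ``callback(step, x)`` runs after each full step.
    """
    x = np.array(x0, dtype=float).ravel().copy()
    n = x.size
    m = np.broadcast_to(np.asarray(masses, dtype=float), (n,)).copy()
    kT = KB_KJ * temperature  # kJ/mol
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sig = np.sqrt(kT / m)
    v = rng.normal(size=n) * sig  # Maxwell-Boltzmann start

    def total_force(step, xx):
        f = -energy_grad(xx) * KCAL_TO_KJ
        if bias_force is not None:
            fb = bias_force(step, xx)
            if fb is not None:
                f = f + np.asarray(fb, dtype=float).ravel() * KCAL_TO_KJ
        return f

    f = total_force(0, x)
    saved = []
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * sig * rng.normal(size=n)
        x += 0.5 * dt * v
        f = total_force(step, x)
        v += 0.5 * dt * f / m
        if not np.all(np.isfinite(x)):
            raise IntegrationFailure(
                f"non-finite coordinates at step {step}; reduce dt or check forces"
            )
        if callback is not None:
            callback(step, x)
        if step % save_stride == 0:
            saved.append(x.copy())
    return np.array(saved) if saved else np.empty((0, n))


def langevin_run(
    system,
    start,
    n_steps: int,
    dt: float = 0.005,
    friction: float = 5.0,
    temperature: Optional[float] = None,
    seed: int = 0,
    bias=None,
    save_stride: int = 10,
    label: str = "",
):
    """Unbiased (or externally biased) Langevin dynamics on a system.

    For a :class:`MiniVFTModel`, ``start`` is a Structure or coordinate array
    and a :class:`Trajectory` of Structures is returned. For an
    :class:`AnalyticPotential2D`, ``start`` is a point and a
    :class:`CVTrace` is returned. ``bias`` is an optional callable
    ``bias(step, x) -> force`` in kcal/mol/nm.

    Stability requires dt below ~2/omega_max for the stiffest mode; the
    mini-VFT defaults (k_intra = 400 kcal/mol/nm², bead mass 100 g/mol) are
    stable at dt = 0.005 ps.
    """
    rng = np.random.default_rng(seed)
    if isinstance(system, MiniVFTModel):
        if temperature is None:
            temperature = system.temperature
        x0 = start.coords if isinstance(start, Structure) else np.asarray(start)
        saved = _baoab_run(
            lambda xx: system.gradient(xx).ravel(),
            x0.ravel(),
            system.mass,
            n_steps,
            dt,
            friction,
            temperature,
            rng,
            bias_force=bias,
            save_stride=save_stride,
        )
        frames = [system.structure(s) for s in saved]
        return Trajectory(
            frames=frames,
            timestep=dt * save_stride,
            temperature=temperature,
            seed=seed,
            label=label,
        )
    # analytic potential
    if temperature is None:
        temperature = 300.0
    x0 = np.asarray(start, dtype=float).ravel()
    saved = _baoab_run(
        system.gradient,
        x0,
        getattr(system, "mass", 1.0),
        n_steps,
        dt,
        friction,
        temperature,
        rng,
        bias_force=bias,
        save_stride=save_stride,
    )
    times = np.arange(1, len(saved) + 1) * dt * save_stride
    return CVTrace(
        times=times, positions=saved, temperature=temperature, seed=seed, label=label
    )


def make_wide_open_excursion(
    model: MiniVFTModel,
    seed: int = 0,
    margin_deg: float = 15.0,
    twist_deg: float = 25.0,
    n_frames: int = 40,
    jitter: float = 0.01,
) -> Trajectory:
    """Short synthetic excursion from the open state into a "wide-open" pose.

    The wide-open end point opens ``margin_deg`` degrees beyond the open
    reference and adds a ``twist_deg`` out-of-plane twist, emulating an
    over-opened conformation seen only in simulation and used as the path's
    terminal frame. With margin and twist 0 the final frame coincides with
    the open reference (up to jitter).
    """
    rng = np.random.default_rng(seed)
    a0 = model.hinge_angle_open
    frames = []
    for t in np.linspace(0.0, 1.0, n_frames):
        s = model.hinge_rotated(a0 + t * margin_deg, twist_deg=t * twist_deg)
        c = s.coords + rng.normal(scale=jitter, size=s.coords.shape)
        frames.append(s.with_coords(c, label=f"wide_open_t{t:.2f}"))
    return Trajectory(
        frames=frames,
        timestep=1.0,
        temperature=model.temperature,
        seed=seed,
        label="wide_open_excursion",
    )


def wide_open_reference(
    model: MiniVFTModel, margin_deg: float = 15.0, twist_deg: float = 25.0
) -> Structure:
    """The wide-open end-point structure itself (no jitter)."""
    s = model.hinge_rotated(model.hinge_angle_open + margin_deg, twist_deg=twist_deg)
    return s.with_coords(s.coords, label="wide_open")


def minimum_energy_barrier(
    model: MiniVFTModel,
    n_images: int = 41,
    n_iter: int = 400,
    step: float = 2e-4,
) -> float:
    """Engineered barrier (kcal/mol): zero-temperature string estimate.

    Starts from the rigid hinge interpolation closed -> open, relaxes the
    images by gradient descent with endpoints fixed, and reparametrizes to
    equal arc length each sweep. Returns max(E) - E(closed) along the
    converged string. Deterministic; serves as the independent reference for
    barrier-recovery checks.
    """
    path = np.stack([s.coords for s in model.rigid_hinge_path(n_images)])
    shape = path.shape
    for _ in range(n_iter):
        for k in range(1, n_images - 1):
            path[k] -= step * model.gradient(path[k]).reshape(shape[1:])
        # reparametrize by cumulative Cartesian arc length
        flat = path.reshape(n_images, -1)
        seg = np.linalg.norm(np.diff(flat, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, arc[-1], n_images)
        new = np.empty_like(flat)
        for d in range(flat.shape[1]):
            new[:, d] = np.interp(targets, arc, flat[:, d])
        path = new.reshape(shape)
    energies = np.array([model.energy(p) for p in path])
    return float(energies.max() - energies[0])
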