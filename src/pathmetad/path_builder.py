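"""Transition-path construction and refinement.

A transition path is discretized as a *frame set*: an ordered ensemble of
reference structures i = 1..N with a smoothness parameter λ. Paths are built
by restrained morphing between structures (the restraint energy is applied
linearly in the distance deviation toward the target, each step followed by
energy minimization), bridged through cluster centroids, and resampled to
equispaced frames; λ is then adapted to the mean squared interframe
displacement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    Structure,
    aligned_msd,
    aligned_msd_with_grad_many,
    aligned_rmsd,
)

__all__ = [
    "FrameSet",
    "MorphError",
    "morph",
    "bridge_and_concatenate",
    "extract_equispaced",
    "tune_lambda",
]


class MorphError(RuntimeError):
    """Restrained morphing failed to reach its target."""


@dataclass
class FrameSet:
    """Ordered path of reference structures with smoothness parameter λ.

    Frame indices run 1..N in the path-CV convention. ``lam`` is λ in nm⁻².
    """

    frames: list
    lam: float
    name: str = ""

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("a frame set needs at least 2 frames")
        if not (self.lam > 0):
            raise ValueError(f"lambda must be positive, got {self.lam}")
        msds = self.interframe_msds()
        if np.any(msds <= 1e-16):
            raise ValueError("adjacent frames are identical; degenerate frame set")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def interframe_msds(self) -> np.ndarray:
        """Adjacent-frame aligned MSDs (nm²) over the measure subset."""
        return np.array(
            [aligned_msd(a, b) for a, b in zip(self.frames[:-1], self.frames[1:])]
        )

    def interframe_distances(self) -> np.ndarray:
        """Adjacent-frame aligned RMSDs (nm)."""
        return np.sqrt(self.interframe_msds())


def tune_lambda(frameset) -> float:
    """Adapt λ (nm⁻²) to the mean squared displacement between adjacent frames.

    λ = ln(10) / ⟨|x_i − x_{i+1}|²⟩ with the MSD in nm², so that the weight
    of a frame decays by one decade per mean interframe MSD: adjacent frames
    stay distinguishable while the S, Z mapping remains smooth. With a mean
    interframe distance of 0.86 Å this gives λ ≈ 312 nm⁻², and 1.1 Å gives
    λ ≈ 193 nm⁻².
    """
    if isinstance(frameset, FrameSet):
        msds = frameset.interframe_msds()
    else:
        frames = list(frameset)
        if len(frames) < 2:
            raise ValueError("need at least 2 frames to tune lambda")
        msds = np.array([aligned_msd(a, b) for a, b in zip(frames[:-1], frames[1:])])
    mean_msd = float(np.mean(msds))
    if mean_msd <= 0:
        raise ValueError("zero mean interframe MSD (duplicate frames)")
    return math.log(10.0) / mean_msd


def morph(
    start: Structure,
    end: Structure,
    energy_model,
    min_intermediates: int = 150,
    k_restraint: float = 1000.0,
    k_step: float = 300.0,
    gtol: float = 1e-4,
    end_tolerance: float = 0.02,
    max_opt_iter: int = 200,
) -> list:
    """Restrained morph from ``start`` to ``end`` under an energy model.

    Rather than interpolating coordinates, the morph ramps a harmonic
    restraint on the aligned measure-subset RMSD to the target linearly to
    zero deviation over ``min_intermediates`` stages, minimizing

        E(x) + k_restraint/2 (d(x, end) − d_target)² + k_step/2 MSD(x, x_prev)

    at each stage. The last (proximal) term tethers each intermediate to its
    predecessor so the chain cannot teleport across a barrier at constant
    distance-to-target; the energy term lets it relax around high-energy
    regions instead of cutting through them. Returns
    ``[start, intermediate_1, ..., intermediate_M]`` with the last
    intermediate within ``end_tolerance`` (nm) of ``end``.
    """
    d0 = aligned_rmsd(start, end)
    if d0 < 1e-8:
        raise ValueError("start and end coincide; nothing to morph")
    if min_intermediates < 1:
        raise ValueError("min_intermediates must be >= 1")

    n_atoms = start.n_atoms
    targets = d0 * (1.0 - np.arange(1, min_intermediates + 1) / min_intermediates)
    chain = [start]
    x = start.coords.copy()

    def objective(flat, d_target, prev):
        coords = flat.reshape(n_atoms, 3)
        s = start.with_coords(coords)
        e = energy_model.energy(coords)
        ge = np.asarray(energy_model.gradient(coords)).reshape(n_atoms, 3)
        msd, gmsd = aligned_msd_with_grad_many(s, [end, prev])
        d = math.sqrt(max(msd[0], 1e-30))
        dd = d - d_target
        val = e + 0.5 * k_restraint * dd * dd + 0.5 * k_step * msd[1]
        grad = ge + k_restraint * dd * gmsd[0] / (2.0 * d) + 0.5 * k_step * gmsd[1]
        return val, grad.ravel()

    step_cap = 2.0 * d0 / min_intermediates

    def _tethered(flat, d_target, anchor_coords, k_anchor):
        coords = flat.reshape(n_atoms, 3)
        s = start.with_coords(coords)
        e = energy_model.energy(coords)
        ge = np.asarray(energy_model.gradient(coords)).reshape(n_atoms, 3)
        anchor = start.with_coords(anchor_coords)
        msd, gmsd = aligned_msd_with_grad_many(s, [end, anchor])
        d = math.sqrt(max(msd[0], 1e-30))
        dd = d - d_target
        val = e + 0.5 * k_restraint * dd * dd + 0.5 * k_anchor * msd[1]
        grad = ge + k_restraint * dd * gmsd[0] / (2.0 * d) + 0.5 * k_anchor * gmsd[1]
        return val, grad.ravel()

    for d_target in targets:
        prev = chain[-1]
        res = minimize(
            objective,
            x.ravel(),
            args=(d_target, prev),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_opt_iter, "gtol": gtol},
        )
        candidate = res.x.reshape(n_atoms, 3)
        step_len = aligned_rmsd(prev, start.with_coords(candidate))
        if step_len > step_cap:
            # a basin switch concentrates motion in one stage: subdivide it
            # into strongly tethered relaxed sub-steps so no frame pair jumps
            n_sub = int(math.ceil(step_len / step_cap))
            for t in np.linspace(1.0 / n_sub, 1.0, n_sub)[:-1]:
                anchor = (1.0 - t) * prev.coords + t * candidate
                sub = minimize(
                    _tethered,
                    anchor.ravel(),
                    args=(d_target, anchor, 20.0 * k_step),
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": max_opt_iter, "gtol": gtol},
                )
                chain.append(start.with_coords(sub.x.reshape(n_atoms, 3)))
        x = candidate
        chain.append(start.with_coords(x.copy()))

    # when the target is not a minimum of the energy model the last stage
    # equilibrates short of it; tighten the restraint until within tolerance
    final_d = aligned_rmsd(chain[-1], end)
    k_tight = k_restraint
    for _ in range(6):
        if final_d <= end_tolerance:
            break
        k_tight *= 5.0
        res = minimize(
            lambda flat: _restrained(flat, energy_model, start, end, k_tight),
            x.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_opt_iter, "gtol": gtol},
        )
        x = res.x.reshape(n_atoms, 3)
        chain.append(start.with_coords(x.copy()))
        final_d = aligned_rmsd(chain[-1], end)
    if final_d > end_tolerance:
        raise MorphError(
            f"morph did not reach target: final distance {final_d:.4f} nm "
            f"> tolerance {end_tolerance} nm"
        )
    return chain


def _restrained(flat, energy_model, template: Structure, end: Structure, k: float):
    """Energy plus a harmonic pull of the aligned distance-to-end to zero."""
    n_atoms = template.n_atoms
    coords = flat.reshape(n_atoms, 3)
    s = template.with_coords(coords)
    e = energy_model.energy(coords)
    ge = np.asarray(energy_model.gradient(coords)).reshape(n_atoms, 3)
    msd, gmsd = aligned_msd_with_grad_many(s, [end])
    d = math.sqrt(max(msd[0], 1e-30))
    grad = ge + k * gmsd[0] / 2.0
    return e + 0.5 * k * d * d, grad.ravel()


def bridge_and_concatenate(
    ordered_structures: Sequence[Structure], energy_model, **morph_kwargs
) -> list:
    """Morph between consecutive structures and concatenate the partial paths.

    Junction structures appear exactly once: each segment contributes its
    chain without its (approximate) final frame, and the exact next waypoint
    opens the following segment; the last waypoint closes the chain.
    """
    structures = list(ordered_structures)
    if len(structures) < 2:
        raise ValueError("need at least 2 structures to bridge")
    full = []
    for seg, (a, b) in enumerate(zip(structures[:-1], structures[1:])):
        try:
            chain = morph(a, b, energy_model, **morph_kwargs)
        except MorphError as err:
            raise MorphError(f"segment {seg} ({seg}->{seg + 1}) failed: {err}") from err
        full.extend(chain[:-1])
    full.append(structures[-1])
    return full


def extract_equispaced(chain: Sequence[Structure], N: int, name: str = "") -> FrameSet:
    """Select N frames from a chain at near-uniform aligned-RMSD arc length.

    The first and last chain structures are always included. λ is adapted to
    the resulting mean interframe MSD. Spacing uniformity (coefficient of
    variation of interframe distances) is expected below 0.15 for reasonably
    dense chains; a warning is emitted otherwise.
    """
    chain = list(chain)
    if N < 2:
        raise ValueError("N must be >= 2")
    if N > len(chain):
        raise ValueError(f"N = {N} exceeds chain length {len(chain)}")
    seg = np.array(
        [aligned_rmsd(a, b) for a, b in zip(chain[:-1], chain[1:])]
    )
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], N)
    idx = [0]
    for t in targets[1:-1]:
        k = int(np.argmin(np.abs(arc - t)))
        k = max(k, idx[-1] + 1)  # keep strictly increasing
        k = min(k, len(chain) - (N - len(idx)))
        idx.append(k)
    idx.append(len(chain) - 1)
    frames = [chain[k] for k in idx]
    fs = FrameSet(frames=frames, lam=tune_lambda(frames), name=name)
    cv = fs.interframe_distances()
    cov = float(np.std(cv) / np.mean(cv))
    if cov > 0.15:
        warnings.warn(
            f"interframe spacing CV {cov:.3f} exceeds 0.15; chain may be too sparse"
        )
    return fs
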