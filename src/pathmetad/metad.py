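"""Well-tempered metadynamics engine, hills bookkeeping, free-energy-surface
reconstruction, recrossing detection, and barrier measurement.

The engine biases either the coordinates of an analytic benchmark potential
or the path collective variables (S, Z) of a bead model. Gaussian hills of
base height w₀ are deposited at a fixed pace; in the well-tempered scheme
each deposited height is damped by exp(−V/( (γ−1) k_B T )) where V is the
accumulated bias at the deposition point, so the bias converges to
−(1−1/γ)·F and the free energy is recovered as F = −γ/(γ−1)·V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .units import KB_KCAL
from .systems import AnalyticPotential2D, MiniVFTModel, _baoab_run
from .pathcv import cv_gradient

__all__ = [
    "HillsLog",
    "BiasState",
    "FESGrid",
    "MetadTrace",
    "deposit_hill",
    "bias_value",
    "run_wtmetad",
    "reconstruct_fes",
    "reconstruct_fes_averaged",
    "detect_recrossing",
    "barrier_between",
]


@dataclass
class HillsLog:
    """Deposited Gaussian hills (times in ps, heights in kcal/mol)."""

    times: np.ndarray  # (n,)
    centers: np.ndarray  # (n, d)
    widths: np.ndarray  # (d,) shared by all hills
    heights: np.ndarray  # (n,) deposited (already damped) heights
    bias_factor: float
    temperature: float = 300.0
    cv_names: tuple = ("s", "z")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float).ravel()
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValueError("hill times must be non-decreasing")
        if np.any(self.heights < 0):
            raise ValueError("hill heights must be positive")
        if not (self.bias_factor > 1):
            raise ValueError("bias factor must exceed 1 (use inf for standard MetaD)")

    def __len__(self):
        return len(self.times)

    @property
    def n_dims(self) -> int:
        return self.centers.shape[1]

    def up_to(self, time_cutoff: float) -> "HillsLog":
        keep = self.times <= time_cutoff
        return HillsLog(
            times=self.times[keep],
            centers=self.centers[keep],
            widths=self.widths,
            heights=self.heights[keep],
            bias_factor=self.bias_factor,
            temperature=self.temperature,
            cv_names=self.cv_names,
        )


def bias_value(point, hills: HillsLog) -> float:
    """Accumulated bias (kcal/mol) at a CV-space point: Σ_k w_k Π_d
    exp(−Δ_d²/2σ_d²). Exact hill summation (no grid)."""
    if len(hills) == 0:
        return 0.0
    pt = np.atleast_1d(np.asarray(point, dtype=float))[: hills.n_dims]
    d2 = ((hills.centers - pt) / hills.widths) ** 2
    return float(np.sum(hills.heights * np.exp(-0.5 * d2.sum(axis=1))))


class BiasState:
    """Mutable bias bookkeeping: hill list plus a gridded accumulator.

    The grid stores the bias and its analytic gradient so that per-step
    force evaluation is an interpolation instead of a sum over all hills;
    grid spacing is a fraction of the hill width, and the grid agrees with
    exact hill summation to the interpolation error.
    """

    def __init__(
        self,
        ranges: Sequence[tuple],
        widths: Sequence[float],
        w0: float,
        bias_factor: float,
        temperature: float,
        points_per_sigma: int = 6,
        cv_names: tuple = ("s", "z"),
    ):
        if w0 <= 0:
            raise ValueError("base hill height must be positive")
        if not (bias_factor > 1):
            raise ValueError("bias factor must exceed 1 (use inf for standard MetaD)")
        if np.any(np.asarray(widths, dtype=float) <= 0):
            raise ValueError("hill widths must be positive")
        self.ndim = len(ranges)
        self.widths = np.asarray(widths, dtype=float)[: self.ndim]
        self.w0 = float(w0)
        self.bias_factor = float(bias_factor)
        self.temperature = float(temperature)
        self.cv_names = cv_names[: self.ndim]
        self.axes = []
        for (lo, hi), sig in zip(ranges, self.widths):
            n = max(int(np.ceil((hi - lo) / sig * points_per_sigma)), 8) + 1
            self.axes.append(np.linspace(lo, hi, n))
        shape = tuple(len(a) for a in self.axes)
        self.V = np.zeros(shape)
        self.dV = [np.zeros(shape) for _ in range(self.ndim)]
        self._times, self._centers, self._heights = [], [], []

    # -- interpolation ----------------------------------------------------
    def _locate(self, point):
        idx, frac = [], []
        for x, ax in zip(point, self.axes):
            xc = min(max(x, ax[0]), ax[-1])
            i = min(int(np.searchsorted(ax, xc) - 1), len(ax) - 2)
            i = max(i, 0)
            idx.append(i)
            frac.append((xc - ax[i]) / (ax[i + 1] - ax[i]))
        return idx, frac

    def _interp(self, grid, idx, frac):
        if self.ndim == 1:
            i, t = idx[0], frac[0]
            return (1 - t) * grid[i] + t * grid[i + 1]
        i, j = idx
        t, u = frac
        return (
            (1 - t) * (1 - u) * grid[i, j]
            + t * (1 - u) * grid[i + 1, j]
            + (1 - t) * u * grid[i, j + 1]
            + t * u * grid[i + 1, j + 1]
        )

    def value(self, point) -> float:
        idx, frac = self._locate(np.atleast_1d(point))
        return float(self._interp(self.V, idx, frac))

    def gradient(self, point) -> np.ndarray:
        idx, frac = self._locate(np.atleast_1d(point))
        return np.array([float(self._interp(g, idx, frac)) for g in self.dV])

    # -- deposition -------------------------------------------------------
    def next_height(self, point) -> float:
        """Well-tempered damped height for a hill at this point."""
        if math.isinf(self.bias_factor):
            return self.w0
        v = self.value(point)
        return self.w0 * math.exp(
            -v / ((self.bias_factor - 1.0) * KB_KCAL * self.temperature)
        )

    def deposit(self, point, time: float) -> float:
        point = np.atleast_1d(np.asarray(point, dtype=float))[: self.ndim]
        h = self.next_height(point)
        gaussians = []
        for ax, x0, sig in zip(self.axes, point, self.widths):
            u = (ax - x0) / sig
            gaussians.append((np.exp(-0.5 * u * u), -u / sig))
        if self.ndim == 1:
            g, gp = gaussians[0]
            self.V += h * g
            self.dV[0] += h * g * gp
        else:
            gu, dgu = gaussians[0]
            gv, dgv = gaussians[1]
            outer = np.outer(gu, gv)
            self.V += h * outer
            self.dV[0] += h * np.outer(gu * dgu, gv)
            self.dV[1] += h * np.outer(gu, gv * dgv)
        self._times.append(float(time))
        self._centers.append(point.copy())
        self._heights.append(h)
        return h

    def to_hills_log(self) -> HillsLog:
        return HillsLog(
            times=np.array(self._times),
            centers=np.array(self._centers).reshape(-1, self.ndim),
            widths=self.widths,
            heights=np.array(self._heights),
            bias_factor=self.bias_factor,
            temperature=self.temperature,
            cv_names=self.cv_names,
        )


def deposit_hill(state: BiasState, point, time: float = 0.0) -> BiasState:
    """Deposit one well-tempered hill at ``point``; returns the state."""
    state.deposit(point, time)
    return state


@dataclass
class MetadTrace:
    """Saved CV trace (and optionally coordinates) of a biased run."""

    times: np.ndarray  # ps
    cvs: np.ndarray  # (n_saved, d)
    coords: Optional[np.ndarray] = None  # (n_saved, n_dof)
    temperature: float = 300.0
    seed: Optional[int] = None
    label: str = ""

    def __len__(self):
        return len(self.times)


@dataclass
class FESGrid:
    """Free-energy estimate over the biased CVs, min-shifted to zero."""

    s_centers: np.ndarray
    free_energy: np.ndarray  # (n_s,) or (n_s, n_z), kcal/mol
    z_centers: Optional[np.ndarray] = None
    bias_factor: float = 8.0
    temperature: float = 300.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.free_energy)):
            raise ValueError("free energy must be finite on the grid")
        if abs(float(self.free_energy.min())) > 1e-9:
            raise ValueError("free energy must be min-shifted to zero")

    @property
    def is_2d(self) -> bool:
        return self.z_centers is not None

    def profile_along_s(self) -> np.ndarray:
        """1D free-energy profile F(S) = −kT ln ∫ exp(−F(S,Z)/kT) dZ."""
        if not self.is_2d:
            return self.free_energy - self.free_energy.min()
        kT = KB_KCAL * self.temperature
        dz = float(self.z_centers[1] - self.z_centers[0]) if len(self.z_centers) > 1 else 1.0
        # stable logsumexp over Z
        a = -self.free_energy / kT
        amax = a.max(axis=1, keepdims=True)
        prof = -kT * (np.log(np.exp(a - amax).sum(axis=1) * dz) + amax[:, 0])
        return prof - prof.min()


def run_wtmetad(
    system,
    n_steps: int,
    frameset=None,
    start=None,
    dt: float = 0.005,
    friction: float = 5.0,
    temperature: Optional[float] = None,
    seed: int = 0,
    w0: float = 0.1,
    sigmas: Sequence[float] = (0.2, 0.2),
    bias_factor: float = 8.0,
    pace: int = 200,
    save_stride: int = 20,
    cv_ranges: Optional[Sequence[tuple]] = None,
    save_coords: bool = True,
    label: str = "",
):
    """Well-tempered metadynamics on an analytic potential or a bead model.

    For an :class:`AnalyticPotential2D` the biased CVs are the coordinates
    listed in ``system.bias_dims``. For a :class:`MiniVFTModel` a
    ``frameset`` must be given and the CVs are (S, Z); bias forces reach the
    beads through the analytic chain rule of the path variables. Hills are
    deposited every ``pace`` integrator steps. Returns ``(trace, hills)``.
    """
    if isinstance(system, MiniVFTModel):
        if frameset is None:
            raise ValueError("biasing a bead model requires a frameset")
        if temperature is None:
            temperature = system.temperature
        if start is None:
            start = system.ref_closed
        x0 = start.coords if hasattr(start, "coords") else np.asarray(start)
        x0 = x0.ravel()
        masses = system.mass
        ndim_cv = 2
        if cv_ranges is None:
            N = frameset.n_frames
            cv_ranges = [(0.5, N + 0.5), (-0.1, 1.0)]
        cv_names = ("s", "z")

        def cv_and_jac(x):
            st = system.structure(x)
            s, z, gs, gz = cv_gradient(st, frameset)
            return np.array([s, z]), np.stack([gs.ravel(), gz.ravel()])

    elif isinstance(system, AnalyticPotential2D):
        if temperature is None:
            temperature = 300.0
        if start is None:
            start = [p for p in system.stationary_points[:1]] or [0.0, 0.0]
            start = np.asarray(start).ravel()
        x0 = np.asarray(start, dtype=float).ravel()
        masses = system.mass
        dims = list(system.bias_dims)
        ndim_cv = len(dims)
        if cv_ranges is None:
            cv_ranges = [system.domain[d] for d in dims]
        cv_names = tuple("uv"[d] for d in dims)

        def cv_and_jac(x):
            jac = np.zeros((ndim_cv, x.size))
            for r, d in enumerate(dims):
                jac[r, d] = 1.0
            return x[dims], jac

    else:
        raise TypeError(f"unsupported system type {type(system)!r}")

    null_bias = w0 == 0.0  # null-bias control: plain dynamics, empty hills
    state = BiasState(
        ranges=cv_ranges,
        widths=np.asarray(sigmas, dtype=float)[:ndim_cv],
        w0=w0 if not null_bias else 1.0,
        bias_factor=bias_factor,
        temperature=temperature,
        cv_names=cv_names,
    )

    rng = np.random.default_rng(seed)
    cache = {"cv": None, "jac": None, "step": -1}

    def bias_force(step, x):
        cv, jac = cv_and_jac(x)
        cache["cv"], cache["jac"], cache["step"] = cv, jac, step
        if null_bias:
            return None
        gv = state.gradient(cv)
        return -(gv @ jac)

    saved_cv, saved_t = [], []

    def callback(step, x):
        if step % pace == 0 and not null_bias:
            # cv cached from the force evaluation at this step
            state.deposit(cache["cv"], time=step * dt)
        if step % save_stride == 0:
            saved_cv.append(cache["cv"].copy())
            saved_t.append(step * dt)

    if isinstance(system, MiniVFTModel):
        grad_fn = lambda xx: system.gradient(xx).ravel()
    else:
        grad_fn = system.gradient

    saved_x = _baoab_run(
        grad_fn,
        x0,
        masses,
        n_steps,
        dt,
        friction,
        temperature,
        rng,
        bias_force=bias_force,
        callback=callback,
        save_stride=save_stride,
    )
    trace = MetadTrace(
        times=np.array(saved_t),
        cvs=np.array(saved_cv).reshape(-1, ndim_cv),
        coords=saved_x if save_coords else None,
        temperature=temperature,
        seed=seed,
        label=label,
    )
    return trace, state.to_hills_log()


def reconstruct_fes(
    hills: HillsLog,
    s_range: tuple,
    n_s: int = 200,
    z_range: Optional[tuple] = None,
    n_z: int = 100,
    time_cutoff: Optional[float] = None,
) -> FESGrid:
    """Reconstruct the FES from the hills: F = −γ/(γ−1) · V_bias(·, t ≤ cutoff).

    The prefactor is 1 in the standard-metadynamics limit γ → ∞. The result
    is min-shifted to zero (the reconstruction carries no absolute
    reference).
    """
    if len(hills) == 0:
        raise ValueError("empty hills log")
    if time_cutoff is not None:
        if time_cutoff < hills.times[0]:
            raise ValueError(
                f"time cutoff {time_cutoff} precedes the first hill at {hills.times[0]}"
            )
        hills = hills.up_to(time_cutoff)
    g = hills.bias_factor
    pref = 1.0 if math.isinf(g) else g / (g - 1.0)
    s = np.linspace(*s_range, n_s)
    if hills.n_dims == 1:
        du = (s[:, None] - hills.centers[None, :, 0]) / hills.widths[0]
        V = np.sum(hills.heights[None, :] * np.exp(-0.5 * du * du), axis=1)
        F = -pref * V
        return FESGrid(
            s_centers=s,
            free_energy=F - F.min(),
            z_centers=None,
            bias_factor=g,
            temperature=hills.temperature,
            provenance={"n_hills": len(hills), "time_cutoff": time_cutoff},
        )
    if z_range is None:
        raise ValueError("z_range required for 2D hills")
    z = np.linspace(*z_range, n_z)
    du = (s[:, None] - hills.centers[None, :, 0]) / hills.widths[0]
    dv = (z[:, None] - hills.centers[None, :, 1]) / hills.widths[1]
    eu = np.exp(-0.5 * du * du)  # (n_s, n_hills)
    ev = np.exp(-0.5 * dv * dv)  # (n_z, n_hills)
    V = np.einsum("sk,k,zk->sz", eu, hills.heights, ev)
    F = -pref * V
    return FESGrid(
        s_centers=s,
        free_energy=F - F.min(),
        z_centers=z,
        bias_factor=g,
        temperature=hills.temperature,
        provenance={"n_hills": len(hills), "time_cutoff": time_cutoff},
    )


def reconstruct_fes_averaged(
    hills: HillsLog,
    s_range: tuple,
    n_s: int = 200,
    z_range: Optional[tuple] = None,
    n_z: int = 100,
    n_snapshots: int = 5,
    first_fraction: float = 0.5,
) -> FESGrid:
    """Time-averaged FES estimate over the tail of a well-tempered run.

    The instantaneous estimate −γ/(γ−1)·V(t) oscillates around the true
    surface as hills keep arriving; averaging min-shifted snapshots taken at
    evenly spaced cutoffs over the last part of the run (from
    ``first_fraction`` of the total time onward) damps the oscillation.
    """
    if len(hills) == 0:
        raise ValueError("empty hills log")
    t_end = hills.times[-1]
    cuts = np.linspace(first_fraction * t_end, t_end, n_snapshots)
    acc = None
    for c in cuts:
        fes = reconstruct_fes(
            hills, s_range, n_s=n_s, z_range=z_range, n_z=n_z, time_cutoff=float(c)
        )
        acc = fes.free_energy if acc is None else acc + fes.free_energy
    F = acc / n_snapshots
    return FESGrid(
        s_centers=fes.s_centers,
        free_energy=F - F.min(),
        z_centers=fes.z_centers,
        bias_factor=hills.bias_factor,
        temperature=hills.temperature,
        provenance={"n_hills": len(hills), "averaged_snapshots": n_snapshots},
    )


def _window_bounds(window) -> tuple:
    """(lo, hi) S-interval from a tuple or a StateWindow-like object."""
    if hasattr(window, "s_interval"):
        return window.s_interval()
    lo, hi = window
    return float(lo), float(hi)


def detect_recrossing(s_trace, times, window_a, window_b):
    """Time of the first completed A→B→A traversal of the S trace, or None.

    Windows are S intervals (lo, hi) or StateWindow objects; they must not
    overlap. Used as the FES-reconstruction stopping point: after the system
    recrosses into the initial basin, further hills only overfill it.
    """
    a_lo, a_hi = _window_bounds(window_a)
    b_lo, b_hi = _window_bounds(window_b)
    if max(a_lo, b_lo) < min(a_hi, b_hi):
        raise ValueError("state windows overlap in S")
    s = np.asarray(s_trace, dtype=float)
    t = np.asarray(times, dtype=float)
    stage = 0  # 0: await A, 1: await B, 2: await A again
    for si, ti in zip(s, t):
        in_a = a_lo <= si <= a_hi
        in_b = b_lo <= si <= b_hi
        if stage == 0 and in_a:
            stage = 1
        elif stage == 1 and in_b:
            stage = 2
        elif stage == 2 and in_a:
            return float(ti)
    return None


def barrier_between(fes: FESGrid, window_a, window_b) -> dict:
    """Free-energy barriers (kcal/mol) between two basins on the S profile.

    Works on the 1D profile F(S) (Z integrated out at the grid temperature
    for 2D surfaces). Returns the basin minima, the barrier top between
    them, and the forward (A→B) and reverse (B→A) barrier heights.
    """
    prof = fes.profile_along_s()
    s = fes.s_centers
    a_lo, a_hi = _window_bounds(window_a)
    b_lo, b_hi = _window_bounds(window_b)
    in_a = (s >= a_lo) & (s <= a_hi)
    in_b = (s >= b_lo) & (s <= b_hi)
    if not in_a.any() or not in_b.any():
        raise ValueError("a basin window contains no grid points")
    ia = np.flatnonzero(in_a)[np.argmin(prof[in_a])]
    ib = np.flatnonzero(in_b)[np.argmin(prof[in_b])]
    lo, hi = sorted((ia, ib))
    if hi - lo < 2:
        raise ValueError("degenerate landscape: basins are adjacent on the grid")
    between = prof[lo + 1 : hi]
    itop = lo + 1 + int(np.argmax(between))
    top = prof[itop]
    if top <= max(prof[ia], prof[ib]) + 1e-12:
        raise ValueError("degenerate landscape: no interior barrier between basins")
    return {
        "f_min_a": float(prof[ia]),
        "f_min_b": float(prof[ib]),
        "s_min_a": float(s[ia]),
        "s_min_b": float(s[ib]),
        "f_top": float(top),
        "s_top": float(s[itop]),
        "barrier_ab": float(top - prof[ia]),
        "barrier_ba": float(top - prof[ib]),
        "delta_f_ab": float(prof[ib] - prof[ia]),
    }
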