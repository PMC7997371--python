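"""Committor analysis: unbiased shooting runs from a chosen configuration.

The committor p_B of a configuration is the probability that unbiased
dynamics started there (with fresh Maxwell-Boltzmann velocities) reaches
basin B before basin A. Configurations with p_B ≈ 0.5 form the
transition-state ensemble; measuring p_B near a putative saddle of the FES
is the standard validation of a metadynamics-derived mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad
from statsmodels.stats.proportion import proportion_confint

from .systems import AnalyticPotential2D, MiniVFTModel, _baoab_run
from .pathcv import path_s_z
from .units import KB_KCAL

__all__ = [
    "StateWindow",
    "CommittorResult",
    "run_committor",
    "select_start_configuration",
    "overdamped_splitting_probability",
]


@dataclass(frozen=True)
class StateWindow:
    """A metastable-state definition in (S, Z) space.

    ``s_op`` is "le" (S ≤ s_value) or "ge" (S ≥ s_value); ``z_max`` bounds
    Z from above (nm²), or is None for analytic systems without a Z.
    """

    label: str
    s_op: str
    s_value: float
    z_max: Optional[float] = None

    def __post_init__(self):
        if self.s_op not in ("le", "ge"):
            raise ValueError("s_op must be 'le' or 'ge'")

    def contains(self, s: float, z: Optional[float] = None) -> bool:
        ok = s <= self.s_value if self.s_op == "le" else s >= self.s_value
        if ok and self.z_max is not None and z is not None:
            ok = z <= self.z_max
        return bool(ok)

    def s_interval(self) -> tuple:
        """S interval for recrossing bookkeeping (half-open side clipped)."""
        if self.s_op == "le":
            return (-math.inf, self.s_value)
        return (self.s_value, math.inf)


def _check_disjoint(a: StateWindow, b: StateWindow) -> None:
    alo, ahi = a.s_interval()
    blo, bhi = b.s_interval()
    if max(alo, blo) < min(ahi, bhi):
        raise ValueError("state windows A and B overlap in S")


@dataclass
class CommittorResult:
    """Per-run outcomes and the committor estimate with its binomial CI."""

    outcomes: list  # per-run "A" | "B" | "timeout"
    p_b: float
    ci_low: float
    ci_high: float
    start_cv: tuple
    seeds: list
    n_timeout: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_b <= 1.0):
            raise ValueError("p_B must lie in [0, 1]")

    @property
    def n_runs(self) -> int:
        return len(self.outcomes)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "n_a": self.outcomes.count("A"),
            "n_b": self.outcomes.count("B"),
            "n_timeout": self.n_timeout,
            "p_b": self.p_b,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "start_cv": list(self.start_cv),
        }


def select_start_configuration(
    coords_pool: np.ndarray,
    cvs_pool: np.ndarray,
    target_s: float,
    target_z: float,
    n_frames: int,
    z_scale: float = 0.05,
):
    """Pick the stored configuration nearest the (S, Z) target.

    Distance is Euclidean in normalized (S/N, Z/z_scale) space. Returns
    ``(coords, (S, Z), index)``; raises if the pool is empty.
    """
    if len(coords_pool) == 0:
        raise ValueError(
            "no stored configurations to start from; run sampling (e.g. "
            "metadynamics with save_coords=True) first"
        )
    d = np.hypot(
        (cvs_pool[:, 0] - target_s) / n_frames,
        (cvs_pool[:, 1] - target_z) / z_scale,
    )
    k = int(np.argmin(d))
    return coords_pool[k], tuple(cvs_pool[k]), k


def run_committor(
    system,
    start,
    window_a: StateWindow,
    window_b: StateWindow,
    n_runs: int = 100,
    max_steps: int = 1_000_000,
    frameset=None,
    dt: float = 0.005,
    friction: float = 5.0,
    temperature: Optional[float] = None,
    seed: int = 0,
    cv_every: int = 10,
) -> CommittorResult:
    """Estimate p_B by unbiased shooting from a fixed configuration.

    Each run draws fresh Maxwell-Boltzmann velocities from its own seed and
    integrates until its CV projection enters A or B (checked every
    ``cv_every`` steps) or ``max_steps`` elapse. p_B = #B / (#A + #B);
    timeouts are reported separately, never silently dropped.
    """
    _check_disjoint(window_a, window_b)
    if isinstance(system, MiniVFTModel):
        if frameset is None:
            raise ValueError("committor on a bead model requires a frameset")
        if temperature is None:
            temperature = system.temperature
        x0 = (start.coords if hasattr(start, "coords") else np.asarray(start)).ravel()
        masses = system.mass
        grad_fn = lambda xx: system.gradient(xx).ravel()

        def cv_of(x):
            return path_s_z(system.structure(x), frameset)

    elif isinstance(system, AnalyticPotential2D):
        if temperature is None:
            temperature = 300.0
        x0 = np.asarray(start, dtype=float).ravel()
        masses = system.mass
        grad_fn = system.gradient
        dims = list(system.bias_dims)

        def cv_of(x):
            s = float(x[dims[0]])
            z = float(x[dims[1]]) if len(dims) > 1 else None
            return s, z

    else:
        raise TypeError(f"unsupported system type {type(system)!r}")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
    outcomes = []

    class _Committed(Exception):
        pass

    for run_seed in child_seeds:
        rng = np.random.default_rng(run_seed)
        result = {"state": "timeout"}

        def check(step, x):
            if step % cv_every == 0:
                s, z = cv_of(x)
                if window_a.contains(s, z):
                    result["state"] = "A"
                    raise _Committed
                if window_b.contains(s, z):
                    result["state"] = "B"
                    raise _Committed

        try:
            _baoab_run(
                grad_fn,
                x0,
                masses,
                max_steps,
                dt,
                friction,
                temperature,
                rng,
                callback=check,
                save_stride=max_steps + 1,  # nothing to save
            )
        except _Committed:
            pass
        outcomes.append(result["state"])

    n_a = outcomes.count("A")
    n_b = outcomes.count("B")
    n_timeout = outcomes.count("timeout")
    if n_a + n_b == 0:
        raise RuntimeError(
            f"all {n_runs} runs timed out after {max_steps} steps; "
            "cannot estimate the committor"
        )
    p_b = n_b / (n_a + n_b)
    lo, hi = proportion_confint(n_b, n_a + n_b, alpha=0.05, method="wilson")
    s0, z0 = cv_of(x0)
    return CommittorResult(
        outcomes=outcomes,
        p_b=float(p_b),
        ci_low=float(lo),
        ci_high=float(hi),
        start_cv=(s0, 0.0 if z0 is None else z0),
        seeds=child_seeds,
        n_timeout=n_timeout,
    )


def overdamped_splitting_probability(
    potential, x_a: float, x_b: float, x0: float, temperature: float = 300.0
) -> float:
    """Closed-form committor of 1D overdamped diffusion in a potential.

    p_B(x0) = ∫_{x_a}^{x0} exp(βU) dx / ∫_{x_a}^{x_b} exp(βU) dx, the exact
    splitting probability between absorbing boundaries at x_a and x_b.
    ``potential`` maps x to U(x) in kcal/mol. Serves as the independent
    oracle for shooting-run estimates in the high-friction regime.
    """
    beta = 1.0 / (KB_KCAL * temperature)
    num, _ = quad(lambda x: math.exp(beta * potential(x)), x_a, x0)
    den, _ = quad(lambda x: math.exp(beta * potential(x)), x_a, x_b)
    return num / den
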