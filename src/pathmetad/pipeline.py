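"""End-to-end pipeline stages over the mini-VFT system.

Each stage is a plain function taking a :class:`PipelineConfig` and a
working directory; stages communicate through files, so any stage can be
re-run from its on-disk inputs alone. The `demo` stage chains everything:
unbiased sampling from both end states → guess path by endpoint morphing →
clustering → refined path through centroids → projection validation →
well-tempered metadynamics → FES with recrossing cutoff → committor runs
near the FES saddle.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as pio
from .clustering import gromos_cluster, select_top_centroids
from .committor import StateWindow, run_committor, select_start_configuration
from .geometry import rmsd_to_references, rmsf
from .metad import (
    barrier_between,
    detect_recrossing,
    reconstruct_fes,
    run_wtmetad,
)
from .path_builder import bridge_and_concatenate, extract_equispaced, morph
from .pathcv import path_quality, project_trajectory
from .systems import (
    Trajectory,
    langevin_run,
    make_mini_vft,
    make_wide_open_excursion,
    wide_open_reference,
)

log = logging.getLogger("pathmetad")

__all__ = [
    "build_model",
    "stage_simulate",
    "stage_build_guess_path",
    "stage_cluster",
    "stage_refine_path",
    "stage_project",
    "stage_metad",
    "stage_fes",
    "stage_committor",
    "run_demo",
    "demo_config",
]


def demo_config(seed: int = 0) -> pio.PipelineConfig:
    """Desk-scale configuration for the full pipeline demo.

    Relative to the full-scale defaults this shortens runs and
    uses a coarser refined path (N = 12) so the whole study completes in
    minutes; physical parameters (300 K, hill height 0.1 kcal/mol, bias
    factor 8, 1.5 Å cluster cutoff) are unchanged.
    """
    cfg = pio.PipelineConfig(seed=seed)
    cfg.sampling.n_steps = 30000
    cfg.sampling.save_stride = 60
    cfg.path.n_frames_guess = 10
    cfg.path.n_frames_refined = 12
    cfg.path.min_intermediates = 60
    cfg.path.k_centroids = 6
    cfg.path.max_cluster_pool = 300
    cfg.metad.n_steps = 240000
    cfg.metad.pace_ps = 0.5
    cfg.metad.sigma_s = 0.5
    cfg.metad.sigma_z = 0.1
    cfg.committor.n_runs = 40
    cfg.committor.max_steps = 60000
    return cfg


def _seeds(cfg: pio.PipelineConfig, stage: str, n: int = 1):
    """Deterministic per-stage seeds derived from the master seed."""
    base = {"simulate": 1, "metad": 2, "committor": 3, "excursion": 4}[stage]
    ss = np.random.SeedSequence([cfg.seed, base])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def build_model(cfg: pio.PipelineConfig):
    return make_mini_vft(
        n_beads=cfg.system.n_beads,
        hinge_angle_open=cfg.system.hinge_angle,
        barrier_scale=cfg.system.barrier_scale,
        seed=cfg.seed,
        temperature=cfg.system.temperature,
    )


def _load_trajectories(workdir: Path, model, cfg) -> list:
    trajs = []
    for p in sorted(workdir.glob("traj_*.xyz")):
        coords = pio.read_xyz(p)
        frames = [model.structure(c) for c in coords]
        trajs.append(
            Trajectory(
                frames=frames,
                timestep=cfg.sampling.dt * cfg.sampling.save_stride,
                temperature=cfg.system.temperature,
                label=p.stem,
            )
        )
    if not trajs:
        raise FileNotFoundError(
            f"no traj_*.xyz under {workdir}; run the simulate stage first"
        )
    return trajs


def stage_simulate(cfg: pio.PipelineConfig, workdir) -> dict:
    """Unbiased runs from both end states plus the wide-open excursion.

    Half the trajectories start from the closed reference and half from the
    open one; none is expected to cross between basins. Writes the
    references (PDB), the trajectories (XYZ) and basic RMSD/RMSF
    diagnostics.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    model = build_model(cfg)
    pio.write_pdb([model.ref_closed, model.ref_open], workdir / "references.pdb")

    n = cfg.sampling.n_trajectories
    seeds = _seeds(cfg, "simulate", n)
    trajs = []
    for k, seed in enumerate(seeds):
        start = model.ref_closed if k % 2 == 0 else model.ref_open
        traj = langevin_run(
            model,
            start,
            n_steps=cfg.sampling.n_steps,
            dt=cfg.sampling.dt,
            friction=cfg.sampling.friction,
            seed=seed,
            save_stride=cfg.sampling.save_stride,
            label=f"traj_{k}_{start.label}",
        )
        pio.write_xyz(traj.frames, workdir / f"traj_{k}.xyz", comment=traj.label)
        trajs.append(traj)

    exc = make_wide_open_excursion(
        model,
        seed=_seeds(cfg, "excursion")[0],
        margin_deg=cfg.system.wide_open_margin,
        twist_deg=cfg.system.wide_open_twist,
    )
    pio.write_xyz(exc.frames, workdir / "wide_open_excursion.xyz")

    # diagnostics: 2D-RMSD projection and per-atom RMSF of the pooled runs
    rows = []
    for traj in trajs:
        d_c, d_o = rmsd_to_references(traj, model.ref_closed, model.ref_open)
        for t, a, b in zip(traj.times, d_c, d_o):
            rows.append((traj.label, t, a, b))
    import pandas as pd

    pd.DataFrame(rows, columns=["traj", "time", "rmsd_closed", "rmsd_open"]).to_csv(
        workdir / "rmsd2d.tsv", sep="\t", index=False, float_format="%.5f"
    )
    pooled = Trajectory(
        frames=[f for tr in trajs for f in tr.frames],
        timestep=trajs[0].timestep,
        temperature=cfg.system.temperature,
    )
    fl = rmsf(pooled, model.ref_closed, subset="align")
    np.savetxt(workdir / "rmsf_nm.tsv", fl, fmt="%.5f")
    summary = {
        "n_trajectories": n,
        "n_frames_each": len(trajs[0]),
        "seeds": seeds,
        "mean_rmsf_mobile_nm": float(
            fl[model.ref_closed.subset_indices("measure")].mean()
        ),
        "mean_rmsf_reference_nm": float(
            fl[model.ref_closed.subset_indices("align")].mean()
        ),
    }
    (workdir / "simulate_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("simulate: %d trajectories of %d frames", n, len(trajs[0]))
    return summary


def stage_build_guess_path(cfg: pio.PipelineConfig, workdir) -> dict:
    """Initial guess path: endpoint-only morph closed → wide-open."""
    workdir = Path(workdir)
    model = build_model(cfg)
    wide = wide_open_reference(
        model, margin_deg=cfg.system.wide_open_margin, twist_deg=cfg.system.wide_open_twist
    )
    chain = morph(
        model.ref_closed,
        wide,
        model,
        min_intermediates=cfg.path.min_intermediates,
    )
    fs = extract_equispaced(chain, cfg.path.n_frames_guess, name="guess")
    pio.write_frameset(fs, workdir / "path_guess.pdb")
    out = {
        "n_frames": fs.n_frames,
        "lambda_nm2": fs.lam,
        "mean_interframe_A": float(fs.interframe_distances().mean() * 10),
        "chain_length": len(chain),
    }
    (workdir / "guess_path_summary.json").write_text(json.dumps(out, indent=2))
    log.info("guess path: N=%d lambda=%.1f nm^-2", fs.n_frames, fs.lam)
    return out


def stage_cluster(cfg: pio.PipelineConfig, workdir) -> dict:
    """GROMOS clustering of the pooled unbiased trajectories."""
    workdir = Path(workdir)
    model = build_model(cfg)
    trajs = _load_trajectories(workdir, model, cfg)
    guess = pio.read_frameset(workdir / "path_guess.yaml")
    pool = [f for tr in trajs for f in tr.frames]
    if len(pool) > cfg.path.max_cluster_pool:
        stride = int(np.ceil(len(pool) / cfg.path.max_cluster_pool))
        pool = pool[::stride]
    table = gromos_cluster(pool, cutoff=cfg.path.cluster_cutoff, frameset=guess)
    pio.write_cluster_tsv(table, workdir / "clusters.tsv")
    pio.write_pdb([c.centroid for c in table.clusters], workdir / "centroids.pdb")
    out = {
        "n_clusters": len(table),
        "n_frames_pooled": table.n_frames,
        "top_populations": [int(c.population) for c in table.clusters[:10]],
    }
    (workdir / "cluster_summary.json").write_text(json.dumps(out, indent=2))
    log.info("clustering: %d clusters from %d frames", len(table), table.n_frames)
    return out


def stage_refine_path(cfg: pio.PipelineConfig, workdir) -> dict:
    """Refined path: bridge the top cluster centroids, then resample.

    The centroids of the most populated clusters are ordered by their S
    value on the guess path, bracketed by the closed reference and the
    wide-open end point, morph-bridged, and the concatenated chain is
    resampled into an equispaced frame set with λ adapted to the result.
    """
    workdir = Path(workdir)
    model = build_model(cfg)
    guess = pio.read_frameset(workdir / "path_guess.yaml")
    trajs = _load_trajectories(workdir, model, cfg)
    pool = [f for tr in trajs for f in tr.frames]
    if len(pool) > cfg.path.max_cluster_pool:
        stride = int(np.ceil(len(pool) / cfg.path.max_cluster_pool))
        pool = pool[::stride]
    table = gromos_cluster(pool, cutoff=cfg.path.cluster_cutoff, frameset=guess)
    k = min(cfg.path.k_centroids, len(table))
    centroids = select_top_centroids(table, k)
    wide = wide_open_reference(
        model, margin_deg=cfg.system.wide_open_margin, twist_deg=cfg.system.wide_open_twist
    )
    waypoints = [model.ref_closed] + centroids + [wide]
    # drop consecutive duplicates (a centroid may coincide with an endpoint)
    from .geometry import aligned_rmsd

    cleaned = [waypoints[0]]
    for w in waypoints[1:]:
        if aligned_rmsd(cleaned[-1], w) > 0.02:
            cleaned.append(w)
    chain = bridge_and_concatenate(
        cleaned, model, min_intermediates=cfg.path.min_intermediates
    )
    fs = extract_equispaced(chain, cfg.path.n_frames_refined, name="refined")
    pio.write_frameset(fs, workdir / "path_refined.pdb")
    out = {
        "n_frames": fs.n_frames,
        "lambda_nm2": fs.lam,
        "mean_interframe_A": float(fs.interframe_distances().mean() * 10),
        "n_waypoints": len(cleaned),
        "chain_length": len(chain),
    }
    (workdir / "refined_path_summary.json").write_text(json.dumps(out, indent=2))
    log.info("refined path: N=%d lambda=%.1f nm^-2", fs.n_frames, fs.lam)
    return out


def stage_project(cfg: pio.PipelineConfig, workdir) -> dict:
    """Project the unbiased trajectories onto the guess and refined paths."""
    workdir = Path(workdir)
    model = build_model(cfg)
    trajs = _load_trajectories(workdir, model, cfg)
    out = {}
    for name in ("guess", "refined"):
        sidecar = workdir / f"path_{name}.yaml"
        if not sidecar.exists():
            continue
        fs = pio.read_frameset(sidecar)
        fracs = []
        for traj in trajs:
            proj = project_trajectory(traj, fs)
            pio.write_projection_tsv(
                proj, workdir / f"projection_{name}_{traj.label}.tsv"
            )
            fracs.append(path_quality(proj)["fraction_low_z"])
        out[name] = {
            "fraction_low_z_per_traj": fracs,
            "fraction_low_z": float(np.mean(fracs)),
        }
    (workdir / "projection_summary.json").write_text(json.dumps(out, indent=2))
    for name, d in out.items():
        log.info("projection on %s path: low-Z fraction %.3f", name, d["fraction_low_z"])
    return out


def stage_metad(cfg: pio.PipelineConfig, workdir) -> dict:
    """Well-tempered metadynamics along the refined path CVs."""
    workdir = Path(workdir)
    model = build_model(cfg)
    fs = pio.read_frameset(workdir / "path_refined.yaml")
    pace = max(int(round(cfg.metad.pace_ps / cfg.metad.dt)), 1)
    trace, hills = run_wtmetad(
        model,
        n_steps=cfg.metad.n_steps,
        frameset=fs,
        dt=cfg.metad.dt,
        friction=cfg.metad.friction,
        seed=_seeds(cfg, "metad")[0],
        w0=cfg.metad.hill_height,
        sigmas=(cfg.metad.sigma_s, cfg.metad.sigma_z),
        bias_factor=cfg.metad.bias_factor,
        pace=pace,
        save_stride=cfg.metad.save_stride,
    )
    pio.write_hills(hills, workdir / "HILLS")
    np.savez_compressed(
        workdir / "metad_trace.npz",
        times=trace.times,
        cvs=trace.cvs,
        coords=trace.coords,
    )
    win_a, win_b = _state_windows(cfg, fs.n_frames)
    out = {
        "n_hills": len(hills),
        "final_time_ps": float(trace.times[-1]),
        "s_min": float(trace.cvs[:, 0].min()),
        "s_max": float(trace.cvs[:, 0].max()),
        "transition_sampled": bool(
            trace.cvs[:, 0].min() <= win_a.s_value
            and trace.cvs[:, 0].max() >= win_b.s_value
        ),
    }
    (workdir / "metad_summary.json").write_text(json.dumps(out, indent=2))
    log.info("metad: %d hills, S in [%.1f, %.1f]", len(hills), out["s_min"], out["s_max"])
    return out


def _state_windows(cfg: pio.PipelineConfig, n_frames: int):
    a = StateWindow(
        "A", "le", 1.0 + cfg.committor.window_a_sfrac * (n_frames - 1), cfg.committor.z_max
    )
    b = StateWindow(
        "B", "ge", 1.0 + cfg.committor.window_b_sfrac * (n_frames - 1), cfg.committor.z_max
    )
    return a, b


def stage_fes(cfg: pio.PipelineConfig, workdir) -> dict:
    """FES reconstruction with the recrossing stopping rule.

    The free energy is reconstructed from the hills deposited up to the
    first completed A→B→A recrossing of the S trace (to avoid overfilling
    the initial basin afterwards); if no recrossing occurred the full hills
    log is used and a warning is logged.
    """
    workdir = Path(workdir)
    hills = pio.read_hills(workdir / "HILLS")
    fs = pio.read_frameset(workdir / "path_refined.yaml")
    data = np.load(workdir / "metad_trace.npz")
    win_a, win_b = _state_windows(cfg, fs.n_frames)
    cutoff = None
    if cfg.metad.time_cutoff_policy == "at-recrossing":
        cutoff = detect_recrossing(
            data["cvs"][:, 0], data["times"], win_a, win_b
        )
        if cutoff is None:
            log.warning("no recrossing detected; falling back to the full hills log")
    n = fs.n_frames

    def _fes_at(cut):
        return reconstruct_fes(
            hills,
            s_range=(1.0, float(n)),
            n_s=160,
            z_range=(-0.05, 0.9),
            n_z=80,
            time_cutoff=cut,
        )

    fes = _fes_at(cutoff)
    bar = None
    try:
        bar = barrier_between(fes, win_a, win_b)
    except ValueError:
        # an early recrossing can leave the far basin unfilled; fall back to
        # the full hills log for the barrier estimate
        if cutoff is not None:
            log.warning(
                "FES at the recrossing cutoff has no resolved interior barrier; "
                "using the full hills log"
            )
            cutoff = None
            fes = _fes_at(None)
        try:
            bar = barrier_between(fes, win_a, win_b)
        except ValueError:
            log.warning(
                "FES has no resolved interior barrier between the state "
                "windows; run longer metadynamics for a barrier estimate"
            )
    pio.write_fes_tsv(fes, workdir / "fes.tsv")
    out = {
        "recrossing_time_ps": cutoff,
        "n_hills_used": int(fes.provenance["n_hills"]),
        **(
            {k: float(v) for k, v in bar.items()}
            if bar is not None
            else {"barrier_ab": None, "barrier_ba": None, "delta_f_ab": None}
        ),
    }
    (workdir / "fes_summary.json").write_text(json.dumps(out, indent=2))
    if bar is not None:
        log.info(
            "fes: barrier A->B %.2f kcal/mol, dF %.2f kcal/mol (recross=%s)",
            bar["barrier_ab"],
            bar["delta_f_ab"],
            cutoff,
        )
    return out


def stage_committor(
    cfg: pio.PipelineConfig,
    workdir,
    start_s: float = None,
    start_z: float = None,
    n_runs: int = None,
) -> dict:
    """Shooting runs from a stored configuration near the FES saddle.

    The (S, Z) target defaults to the measured FES saddle (or the
    configured path fraction if none is available); explicit ``start_s`` /
    ``start_z`` override both.
    """
    workdir = Path(workdir)
    model = build_model(cfg)
    fs = pio.read_frameset(workdir / "path_refined.yaml")
    data = np.load(workdir / "metad_trace.npz")
    n = fs.n_frames
    target_s = 1.0 + cfg.committor.start_sfrac * (n - 1)
    fes_summary = workdir / "fes_summary.json"
    if fes_summary.exists():  # prefer the measured saddle location, if any
        s_top = json.loads(fes_summary.read_text()).get("s_top")
        if s_top is not None:
            target_s = float(s_top)
        else:
            log.info("no FES saddle available; using the configured S target")
    if start_s is not None:
        target_s = float(start_s)
    target_z = cfg.committor.start_z if start_z is None else float(start_z)
    if n_runs is None:
        n_runs = cfg.committor.n_runs
    coords, cv0, _ = select_start_configuration(
        data["coords"], data["cvs"], target_s, target_z, n
    )
    win_a, win_b = _state_windows(cfg, n)
    res = run_committor(
        model,
        model.structure(coords),
        win_a,
        win_b,
        n_runs=n_runs,
        max_steps=cfg.committor.max_steps,
        frameset=fs,
        dt=cfg.sampling.dt,
        friction=cfg.sampling.friction,
        seed=_seeds(cfg, "committor")[0],
    )
    out = {"target_s": target_s, "start_cv": list(cv0), **res.to_dict()}
    (workdir / "committor_summary.json").write_text(json.dumps(out, indent=2))
    import pandas as pd

    pd.DataFrame(
        {"run": range(res.n_runs), "seed": res.seeds, "outcome": res.outcomes}
    ).to_csv(workdir / "committor_runs.tsv", sep="\t", index=False)
    log.info("committor: p_B = %.2f [%.2f, %.2f]", res.p_b, res.ci_low, res.ci_high)
    return out


def run_demo(cfg: pio.PipelineConfig, workdir) -> dict:
    """The full scaled-down study; writes every stage artifact plus a report."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    pio.save_config(cfg, workdir / "config.yaml")
    report = {"seed": cfg.seed}
    report["simulate"] = stage_simulate(cfg, workdir)
    report["guess_path"] = stage_build_guess_path(cfg, workdir)
    report["cluster"] = stage_cluster(cfg, workdir)
    report["refined_path"] = stage_refine_path(cfg, workdir)
    report["projection"] = stage_project(cfg, workdir)
    report["metad"] = stage_metad(cfg, workdir)
    report["fes"] = stage_fes(cfg, workdir)
    report["committor"] = stage_committor(cfg, workdir)
    (workdir / "demo_report.json").write_text(json.dumps(report, indent=2))
    return report
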