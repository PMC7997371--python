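"""Readers and writers for the pipeline's interchange formats.

Formats
-------
* Multi-model PDB for bead structures and frame sets. Coordinates are nm
  internally and Å on file; the occupancy column carries the align flag and
  the B-factor column the measure (displacement) flag, following the PLUMED
  path-PDB dialect, so frame sets written here can be fed to PLUMED.
* XYZ trajectories (Å on file).
* PLUMED-style HILLS files with a ``#! FIELDS`` header.
* TSV tables for projections, cluster summaries and free-energy surfaces.
* A schema-validated YAML pipeline configuration; unknown keys are
  rejected. Atom indices in config files are 0-based; path-CV frame indices
  are 1-based (S runs over i = 1..N).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .geometry import Structure
from .path_builder import FrameSet
from .metad import HillsLog, FESGrid
from .units import NM_TO_ANGSTROM, ANGSTROM_TO_NM

__all__ = [
    "PDBParseError",
    "write_pdb",
    "read_pdb",
    "write_xyz",
    "read_xyz",
    "write_frameset",
    "read_frameset",
    "write_hills",
    "read_hills",
    "write_projection_tsv",
    "read_projection_tsv",
    "write_cluster_tsv",
    "write_fes_tsv",
    "PipelineConfig",
    "load_config",
    "save_config",
]


class PDBParseError(ValueError):
    """Malformed PDB content; the message names the offending line."""


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _tag_flags(tag: str) -> tuple:
    occ = 1.0 if tag in ("align", "both") else 0.0
    beta = 1.0 if tag in ("measure", "both") else 0.0
    return occ, beta


def _flags_tag(occ: float, beta: float) -> str:
    if occ > 0 and beta > 0:
        return "both"
    if occ > 0:
        return "align"
    if beta > 0:
        return "measure"
    return "none"


def write_pdb(structures, path) -> None:
    """Write one or more Structures as a multi-model Cα-bead PDB (Å)."""
    if isinstance(structures, Structure):
        structures = [structures]
    lines = []
    for model_no, s in enumerate(structures, start=1):
        lines.append(f"MODEL     {model_no:4d}")
        for i, (xyz, tag) in enumerate(zip(s.coords, s.subset_tags)):
            occ, beta = _tag_flags(tag)
            x, y, z = xyz * NM_TO_ANGSTROM
            lines.append(
                f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{beta:6.2f}           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> list:
    """Read a multi-model Cα-bead PDB into a list of Structures (nm)."""
    models, current, tags = [], [], []
    n_expected = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated ATOM record")
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as err:
                raise PDBParseError(f"line {lineno}: bad coordinates ({err})") from err
            try:
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                beta = float(line[60:66]) if line[60:66].strip() else 1.0
            except ValueError as err:
                raise PDBParseError(f"line {lineno}: bad occupancy/beta ({err})") from err
            current.append((x * ANGSTROM_TO_NM, y * ANGSTROM_TO_NM, z * ANGSTROM_TO_NM))
            tags.append(_flags_tag(occ, beta))
        elif rec == "ENDMDL":
            if not current:
                raise PDBParseError(f"line {lineno}: ENDMDL with no atoms")
            if n_expected is None:
                n_expected = len(current)
            elif len(current) != n_expected:
                raise PDBParseError(
                    f"line {lineno}: model has {len(current)} atoms, "
                    f"expected {n_expected}"
                )
            models.append(Structure(np.array(current), subset_tags=tuple(tags)))
            current, tags = [], []
    if current:  # single-model file without ENDMDL
        models.append(Structure(np.array(current), subset_tags=tuple(tags)))
    if not models:
        raise PDBParseError("no ATOM records found")
    return models


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(frames, path, comment: str = "") -> None:
    """Write structures or coordinate arrays as a multi-frame XYZ file (Å)."""
    lines = []
    for f in frames:
        coords = f.coords if hasattr(f, "coords") else np.asarray(f)
        lines.append(str(len(coords)))
        lines.append(comment)
        for xyz in coords * NM_TO_ANGSTROM:
            lines.append(f"C {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> np.ndarray:
    """Read a multi-frame XYZ file into an (n_frames, n_atoms, 3) array (nm)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"line {i + 1}: expected atom count ({err})") from err
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"line {i + 1}: frame truncated (expected {n} atoms)")
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        frames.append(coords * ANGSTROM_TO_NM)
        i += 2 + n
    return np.array(frames)


# ---------------------------------------------------------------------------
# FrameSet (PDB + YAML sidecar)
# ---------------------------------------------------------------------------

def write_frameset(frameset: FrameSet, pdb_path, sidecar_path=None) -> None:
    pdb_path = Path(pdb_path)
    if sidecar_path is None:
        sidecar_path = pdb_path.with_suffix(".yaml")
    write_pdb(frameset.frames, pdb_path)
    ref = frameset.frames[0]
    meta = {
        "format_version": 1,
        "n_frames": frameset.n_frames,
        "lambda_nm2": float(frameset.lam),
        "name": frameset.name,
        "pdb_file": pdb_path.name,
        # 0-based atom indices, as everywhere in config files
        "align_indices": [int(i) for i in ref.subset_indices("align")],
        "measure_indices": [int(i) for i in ref.subset_indices("measure")],
    }
    Path(sidecar_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_frameset(sidecar_path) -> FrameSet:
    sidecar_path = Path(sidecar_path)
    meta = yaml.safe_load(sidecar_path.read_text())
    frames = read_pdb(sidecar_path.parent / meta["pdb_file"])
    if len(frames) != meta["n_frames"]:
        raise ValueError(
            f"{sidecar_path}: sidecar promises {meta['n_frames']} frames, "
            f"PDB holds {len(frames)}"
        )
    return FrameSet(frames=frames, lam=meta["lambda_nm2"], name=meta.get("name", ""))


# ---------------------------------------------------------------------------
# HILLS (PLUMED-style)
# ---------------------------------------------------------------------------

def write_hills(hills: HillsLog, path) -> None:
    names = list(hills.cv_names)
    cols = (
        ["time"] + names + [f"sigma_{n}" for n in names] + ["height", "biasf"]
    )
    lines = ["#! FIELDS " + " ".join(cols)]
    bf = "inf" if math.isinf(hills.bias_factor) else f"{hills.bias_factor:g}"
    for t, c, h in zip(hills.times, hills.centers, hills.heights):
        row = (
            [f"{t:.3f}"]
            + [f"{v:.9f}" for v in c]
            + [f"{w:.9f}" for w in hills.widths]
            + [f"{h:.9f}", bf]
        )
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path) -> HillsLog:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    cols = lines[0].split()[2:]
    n_cv = (len(cols) - 3) // 2
    names = tuple(cols[1 : 1 + n_cv])
    times, centers, heights, widths, biasf = [], [], [], None, None
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != len(cols):
            raise ValueError(
                f"{path} line {lineno}: {len(parts)} fields, expected {len(cols)}"
            )
        times.append(float(parts[0]))
        centers.append([float(v) for v in parts[1 : 1 + n_cv]])
        widths = [float(v) for v in parts[1 + n_cv : 1 + 2 * n_cv]]
        heights.append(float(parts[1 + 2 * n_cv]))
        biasf = float(parts[2 + 2 * n_cv])
    return HillsLog(
        times=np.array(times),
        centers=np.array(centers),
        widths=np.array(widths),
        heights=np.array(heights),
        bias_factor=biasf,
        cv_names=names,
    )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_projection_tsv(projection, path) -> None:
    pd.DataFrame(
        {"time": projection.times, "S": projection.s, "Z_nm2": projection.z}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_projection_tsv(path):
    from .pathcv import PathProjection

    df = pd.read_csv(path, sep="\t")
    return PathProjection(
        s=df["S"].to_numpy(), z=df["Z_nm2"].to_numpy(), times=df["time"].to_numpy()
    )


def write_cluster_tsv(table, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def write_fes_tsv(fes: FESGrid, path) -> None:
    if fes.is_2d:
        s, z = np.meshgrid(fes.s_centers, fes.z_centers, indexing="ij")
        df = pd.DataFrame(
            {"S": s.ravel(), "Z_nm2": z.ravel(), "F_kcal": fes.free_energy.ravel()}
        )
    else:
        df = pd.DataFrame({"S": fes.s_centers, "F_kcal": fes.free_energy})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class SystemConfig:
    """Mini-VFT construction parameters."""

    n_beads: int = 8
    hinge_angle: float = 35.0
    barrier_scale: float = 1.0
    temperature: float = 300.0
    wide_open_margin: float = 15.0
    wide_open_twist: float = 25.0


@dataclass
class SamplingConfig:
    """Unbiased-MD stage: several runs from each end state."""

    n_trajectories: int = 6
    n_steps: int = 40000
    dt: float = 0.005  # ps
    friction: float = 5.0  # 1/ps
    save_stride: int = 40


@dataclass
class PathConfig:
    """Clustering and path construction."""

    cluster_cutoff: float = 0.15  # nm (1.5 Å)
    k_centroids: int = 10
    n_frames_guess: int = 30
    n_frames_refined: int = 40
    min_intermediates: int = 150
    max_cluster_pool: int = 400  # frames kept (subsampled) for clustering


@dataclass
class MetadConfig:
    """Well-tempered metadynamics schedule."""

    hill_height: float = 0.1  # kcal/mol
    sigma_s: float = 0.2
    sigma_z: float = 0.2  # nm²
    bias_factor: float = 8.0
    pace_ps: float = 1.0
    n_steps: int = 150000
    dt: float = 0.005
    friction: float = 5.0
    save_stride: int = 25
    time_cutoff_policy: str = "at-recrossing"  # or "full"


@dataclass
class CommittorConfig:
    """State windows and shooting parameters (S fractions of the path)."""

    window_a_sfrac: float = 0.25  # A: S <= 1 + frac*(N-1)
    window_b_sfrac: float = 0.45  # B: S >= 1 + frac*(N-1)
    z_max: float = 0.05  # nm²
    start_sfrac: float = 0.38  # shooting point target along S
    start_z: float = 0.05
    n_runs: int = 50
    max_steps: int = 100000


@dataclass
class PipelineConfig:
    system: SystemConfig = field(default_factory=SystemConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    path: PathConfig = field(default_factory=PathConfig)
    metad: MetadConfig = field(default_factory=MetadConfig)
    committor: CommittorConfig = field(default_factory=CommittorConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "system": SystemConfig,
    "sampling": SamplingConfig,
    "path": PathConfig,
    "metad": MetadConfig,
    "committor": CommittorConfig,
}


def _build_section(cls, data: dict, where: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown keys in '{where}': {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(_SECTIONS) | {"seed"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown top-level keys: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    kwargs = {"seed": int(data.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(cls, data.get(name, {}) or {}, name)
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
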