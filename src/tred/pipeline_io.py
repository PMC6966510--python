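"""Configuration, file formats, and the end-to-end pipeline runner.

Conventions enforced at the I/O boundary: 0-based frame indices, µm for
coordinates, seconds for trajectory time, hours for phenotype time.
Trajectory tables are CSV with columns exactly
``track_id,frame,t_s,x_um,y_um[,z_um]``.  Image stacks are multi-page
16-bit TIFF.  Reports are JSON with sorted keys so a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .membrane_sim import (
    CorralParams,
    ImageStack,
    Trajectory2D,
    Trajectory3D,
    simulate_corral_ensemble,
)
from .msd_dynamics import (
    TooShortTrajectoryError,
    compute_msd,
    fit_confined,
    percent_increase,
    summarize_group,
)
from .phenostats import compare_groups

log = logging.getLogger("tred")

__all__ = [
    "TredConfig",
    "GroupSpec",
    "load_config",
    "read_trajectories",
    "write_trajectories",
    "read_stack",
    "write_stack",
    "run_tred",
    "fits_to_frame",
]

TRAJ_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: either simulated or loaded from CSV."""

    label: str
    n_tracks: int = 0
    D_micro: float = 0.0  # µm²/s, simulation ground truth
    L_comp_nm: float = np.inf
    p_hop: float = 0.0
    sigma_loc_nm: float = 20.0
    trajectories_csv: str | None = None  # overrides simulation if set


@dataclass(frozen=True)
class TredConfig:
    """Full pipeline configuration with acquisition defaults of 20
    frames/s, 1200 frames, 107 nm pixels."""

    groups: tuple[GroupSpec, ...]
    fps: float = 20.0
    n_frames: int = 1200
    pixel_nm: float = 107.0
    min_len: int = 50
    max_lag_frac: float = 0.25
    alpha_var: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not self.groups:
            raise ValueError("config defines no groups")


def load_config(path: str | Path) -> TredConfig:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    missing = [k for k in ("groups",) if k not in raw]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    acq = raw.get("acquisition", {})
    fit = raw.get("fit", {})
    groups = tuple(GroupSpec(**g) for g in raw["groups"])
    return TredConfig(
        groups=groups,
        fps=acq.get("fps", 20.0),
        n_frames=acq.get("n_frames", 1200),
        pixel_nm=acq.get("pixel_nm", 107.0),
        min_len=fit.get("min_len", 50),
        max_lag_frac=fit.get("max_lag_frac", 0.25),
        alpha_var=raw.get("stats", {}).get("alpha_var", 0.05),
        seed=raw.get("seed", 0),
        out_dir=raw.get("out_dir"),
    )


# ---------------------------------------------------------------------------
# formats


def write_trajectories(trajs: list[Trajectory2D], path: str | Path) -> None:
    """Write trajectories to the canonical CSV schema."""
    rows = []
    for tr in trajs:
        df = pd.DataFrame({
            "track_id": tr.track_id, "frame": tr.frames, "t_s": tr.t,
            "x_um": tr.x, "y_um": tr.y,
        })
        if isinstance(tr, Trajectory3D):
            df["z_um"] = tr.z
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory2D]:
    """Read a trajectory CSV (``track_id,frame,t_s,x_um,y_um[,z_um]``)."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    has_z = "z_um" in df.columns
    out: list[Trajectory2D] = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        kw = dict(track_id=int(tid), frames=g["frame"].to_numpy(),
                  t=g["t_s"].to_numpy(), x=g["x_um"].to_numpy(),
                  y=g["y_um"].to_numpy())
        if has_z:
            out.append(Trajectory3D(**kw, z=g["z_um"].to_numpy()))
        else:
            out.append(Trajectory2D(**kw))
    return out


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.to_uint16())


def read_stack(path: str | Path, pixel_nm: float = 107.0,
               fps: float = 20.0) -> ImageStack:
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, pixel_size=pixel_nm, dt=1.0 / fps)


# ---------------------------------------------------------------------------
# pipeline


def fits_to_frame(fits, track_ids=None) -> pd.DataFrame:
    """Per-trajectory fit table (CSV-ready)."""
    return pd.DataFrame({
        "track_id": track_ids if track_ids is not None else range(len(fits)),
        "D_um2_s": [f.D for f in fits],
        "L_nm": [f.L for f in fits],
        "tau_s": [f.tau for f in fits],
        "c_um2": [f.c for f in fits],
        "DM_um2_s": [f.D_M for f in fits],
        "rss": [f.rss for f in fits],
        "converged": [f.converged for f in fits],
    })


def _analyze_group(trajs: list[Trajectory2D], label: str, cfg: TredConfig):
    fits, kept_ids, n_excluded = [], [], 0
    for tr in trajs:
        try:
            msd = compute_msd(tr, cfg.max_lag_frac, min_len=cfg.min_len)
            fit = fit_confined(msd)
        except (TooShortTrajectoryError, ValueError):
            n_excluded += 1
            log.warning("group %s: track %s excluded by QC", label, tr.track_id)
            continue
        if not fit.converged:
            n_excluded += 1
            log.warning("group %s: track %s fit did not converge", label, tr.track_id)
            continue
        fits.append(fit)
        kept_ids.append(tr.track_id)
    if not fits:
        raise ValueError(f"group {label!r} is empty after QC")
    return fits, kept_ids, n_excluded


def run_tred(config: TredConfig) -> dict:
    """Run the full pipeline: simulate (or load) each group's
    trajectories, fit MSD curves, summarize groups, compare them
    pairwise on D and L, and assemble a JSON-serializable report.

    Deterministic under the configured seed: per-group seeds are derived
    from ``config.seed`` with a fixed scheme.
    """
    summaries, per_group = {}, {}
    qc = {}
    for gi, g in enumerate(config.groups):
        if g.trajectories_csv:
            trajs = read_trajectories(g.trajectories_csv)
        else:
            if g.n_tracks < 1:
                raise ValueError(f"group {g.label!r} has no input: "
                                 "set n_tracks > 0 or trajectories_csv")
            params = CorralParams(
                D_micro=g.D_micro, L_comp=g.L_comp_nm, p_hop=g.p_hop,
                dt=1.0 / config.fps, n_steps=config.n_frames,
                sigma_loc=g.sigma_loc_nm,
            )
            trajs = simulate_corral_ensemble(
                params, g.n_tracks, seed=(config.seed * 1000 + gi) % (2**31)
            )
        fits, kept, n_exc = _analyze_group(trajs, g.label, config)
        summaries[g.label] = summarize_group(fits, g.label)
        per_group[g.label] = fits
        qc[g.label] = {"n_input": len(trajs), "n_analyzed": len(fits),
                       "n_excluded": n_exc}

    labels = [g.label for g in config.groups]
    comparisons, percent_diffs = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            for quantity in ("D", "L"):
                va = np.array([getattr(f, quantity) for f in per_group[a]])
                vb = np.array([getattr(f, quantity) for f in per_group[b]])
                cmp_ = compare_groups([va, vb], labels=[a, b],
                                      alpha_var=config.alpha_var)
                comparisons.append({
                    "groups": [a, b], "quantity": quantity, "test": cmp_.test,
                    "statistic": cmp_.statistic, "df": cmp_.df, "p": cmp_.p,
                    "stars": cmp_.stars, "f_test_p": cmp_.f_test_p,
                })
                hi, lo = (a, b) if va.mean() >= vb.mean() else (b, a)
                mh = max(va.mean(), vb.mean())
                ml = min(va.mean(), vb.mean())
                if ml > 0:
                    percent_diffs.append({
                        "quantity": quantity, "higher": hi, "lower": lo,
                        "percent": round(percent_increase(mh, ml)),
                    })

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "fps": config.fps, "n_frames": config.n_frames,
            "pixel_nm": config.pixel_nm, "min_len": config.min_len,
            "max_lag_frac": config.max_lag_frac, "alpha_var": config.alpha_var,
            "groups": [vars(g) for g in config.groups],
        },
        "groups": {
            lab: {"mean_D_um2_s": s.mean_D, "sem_D_um2_s": s.sem_D,
                  "mean_L_nm": s.mean_L, "sem_L_nm": s.sem_L, "n": s.n}
            for lab, s in summaries.items()
        },
        "comparisons": comparisons,
        "percent_differences": percent_diffs,
        "qc": qc,
    }
    report["config_hash"] = hashlib.sha256(
        json.dumps(report["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(serialize_report(report))
        for lab, fits in per_group.items():
            fits_to_frame(fits).to_csv(out / f"fits_{lab}.csv", index=False)
    return report


def serialize_report(report: dict) -> str:
    """Stable JSON serialization (sorted keys, fixed separators)."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    return json.dumps(report, sort_keys=True, indent=1, default=default)
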