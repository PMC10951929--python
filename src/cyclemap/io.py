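"""Reading and writing trajectory datasets, latents and reports.

On disk a dataset is one multi-page TIFF per cell plus a CSV manifest
(cell_id, frame, time_min, file, and optionally phase, stage,
division_flag) and a JSON snapshot of the generating configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .data import CellTrajectory, LatentSequence
from .synthetic import GroundTruth, SyntheticConfig

__all__ = ["write_dataset", "read_dataset", "read_trajectories",
           "write_latents_csv", "read_latents_csv"]


def write_dataset(out_dir: str | Path,
                  dataset: list[tuple[CellTrajectory, GroundTruth]],
                  config: SyntheticConfig | None = None) -> Path:
    """Write trajectories as per-cell TIFF stacks plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for traj, truth in dataset:
        fname = f"{traj.cell_id}.tif"
        tifffile.imwrite(out_dir / fname, traj.images.astype(np.float32))
        division = np.zeros(len(traj), dtype=int)
        if truth is not None:
            division[truth.division_frames] = 1
        for t in range(len(traj)):
            rows.append({
                "cell_id": traj.cell_id, "frame": t,
                "time_min": traj.times_min[t], "file": fname,
                "phase": truth.phase[t] if truth is not None else np.nan,
                "stage": (traj.stages[t] if traj.stages is not None else ""),
                "division_flag": division[t],
            })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if config is not None:
        (out_dir / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2))
    return manifest


def read_dataset(manifest: str | Path, image_dir: str | Path | None = None
                 ) -> tuple[list[CellTrajectory], dict]:
    """Load a dataset from its manifest; returns trajectories and metadata.

    Frames are ordered by time within each cell regardless of row order.
    Pixels are rescaled to [0, 1] by the dataset-wide min-max unless they
    already lie in [0, 1], in which case they are kept bit-identical; the
    applied scaling is recorded in the returned metadata.
    """
    manifest = Path(manifest)
    image_dir = Path(image_dir) if image_dir else manifest.parent
    df = pd.read_csv(manifest)
    required = {"cell_id", "frame", "time_min", "file"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    missing = sorted({f for f in df["file"].unique()
                      if not (image_dir / f).exists()})
    if missing:
        raise FileNotFoundError(f"missing image files: {missing}")
    stacks = {f: np.asarray(tifffile.imread(image_dir / f), dtype=np.float64)
              for f in df["file"].unique()}
    lo = min(float(s.min()) for s in stacks.values())
    hi = max(float(s.max()) for s in stacks.values())
    rescaled = not (0.0 <= lo and hi <= 1.0)
    if rescaled:
        span = (hi - lo) or 1.0
        stacks = {f: (s - lo) / span for f, s in stacks.items()}
    trajectories = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        fname = grp["file"].iloc[0]
        stack = stacks[fname]
        if stack.ndim == 2:
            stack = stack[None]
        images = stack[grp["frame"].to_numpy()]
        stages = None
        if "stage" in grp.columns and grp["stage"].notna().all():
            stages = grp["stage"].astype(str).to_numpy()
        trajectories.append(CellTrajectory(
            cell_id=str(cell_id), images=images,
            times_min=grp["time_min"].to_numpy(), stages=stages))
    meta = {"rescaled": rescaled, "source_min": lo, "source_max": hi,
            "n_cells": len(trajectories)}
    return trajectories, meta


def read_trajectories(manifest: str | Path,
                      image_dir: str | Path | None = None
                      ) -> list[CellTrajectory]:
    """:func:`read_dataset` without the metadata."""
    return read_dataset(manifest, image_dir)[0]


def write_latents_csv(path: str | Path, seqs: list[LatentSequence],
                      coords: list[np.ndarray] | None = None) -> None:
    """Write latent sequences (and optional 2-D coordinates) as one CSV."""
    rows = []
    for i, seq in enumerate(seqs):
        for t in range(len(seq)):
            row = {"cell_id": seq.cell_id, "frame": t,
                   "time_min": seq.times_min[t]}
            row.update({f"z{d + 1}": seq.latents[t, d]
                        for d in range(seq.latents.shape[1])})
            if seq.stages is not None:
                row["stage"] = seq.stages[t]
            if coords is not None:
                row["umap1"], row["umap2"] = coords[i][t]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_latents_csv(path: str | Path) -> list[LatentSequence]:
    df = pd.read_csv(path)
    zcols = sorted([c for c in df.columns if c.startswith("z")],
                   key=lambda c: int(c[1:]))
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(LatentSequence(
            cell_id=str(cell_id), latents=grp[zcols].to_numpy(),
            times_min=grp["time_min"].to_numpy(),
            stages=grp["stage"].to_numpy() if "stage" in grp else None))
    return out
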