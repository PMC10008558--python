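"""File containers: HDF5 tracking runs and tabular trajectory files.

One HDF5 container per tracking run (photons, shot positions, ground truth,
estimates, config echo + seed); small tables travel as plain text.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .diffusion_est import DiffusionSeries, Trajectory
from .localization import Estimate, PhotonPattern
from .tracking_sim import EmitterPath, TrackingRun

SCHEMA_VERSION = 1

__all__ = [
    "save_run",
    "load_run",
    "write_trajectory",
    "read_trajectory",
    "write_diffusion_series",
]


def save_run(run: TrackingRun, path, config: dict | None = None) -> None:
    """Serialize a TrackingRun to an HDF5 container."""
    with h5py.File(str(path), "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if run.seed is not None:
            f.attrs["seed"] = run.seed
        if config is not None:
            f.attrs["config_json"] = json.dumps(config, sort_keys=True)
        counts = np.stack([p.counts for p in run.patterns])
        shots = np.stack([p.psf_positions for p in run.patterns])
        foci = np.stack([p.focus_positions for p in run.patterns])
        g = f.create_group("photons")
        g.create_dataset("counts", data=counts)
        g.create_dataset("is_blank", data=run.patterns[0].is_blank)
        s = f.create_group("shots")
        s.create_dataset("psf_positions_nm", data=shots)
        s.create_dataset("focus_positions_nm", data=foci)
        s.create_dataset("pattern_centers_nm", data=run.centers)
        if run.truth is not None:
            t = f.create_group("truth")
            t.create_dataset("positions_nm", data=run.truth.positions)
            t.attrs["dt_s"] = run.truth.dt_s
            t.attrs["efficiency"] = run.truth.efficiency
            t.attrs["background"] = run.truth.background
            if run.truth.states is not None:
                t.create_dataset("states", data=run.truth.states)
        e = f.create_group("estimates")
        frame = run.estimate_frame()
        for col in frame.columns:
            e.create_dataset(col, data=frame[col].to_numpy())


def load_run(path) -> tuple[TrackingRun, dict | None]:
    """Load a TrackingRun from HDF5; returns (run, config-or-None)."""
    from .psf_pattern import build_tracking_pattern

    with h5py.File(str(path), "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported run-container schema version {version} (expected {SCHEMA_VERSION})"
            )
        counts = f["photons/counts"][...]
        blank = f["photons/is_blank"][...].astype(bool)
        shots = f["shots/psf_positions_nm"][...]
        foci = f["shots/focus_positions_nm"][...]
        centers = f["shots/pattern_centers_nm"][...]
        patterns = [
            PhotonPattern(counts[j], shots[j], blank, focus_positions=foci[j], index=j)
            for j in range(len(counts))
        ]
        truth = None
        if "truth" in f:
            t = f["truth"]
            truth = EmitterPath(
                t["positions_nm"][...],
                dt_s=float(t.attrs["dt_s"]),
                states=t["states"][...] if "states" in t else None,
                efficiency=float(t.attrs["efficiency"]),
                background=float(t.attrs["background"]),
            )
        e = f["estimates"]
        ests = []
        for j in range(len(counts)):
            x = e["x_nm"][j]
            if np.isnan(x):
                ests.append(None)
            else:
                ests.append(
                    Estimate(
                        np.array([x, e["y_nm"][j], e["z_nm"][j]]),
                        float(e["c_tilde"][j]),
                        float(e["objective"][j]),
                        int(e["n_total"][j]),
                        j,
                    )
                )
        config = None
        if "config_json" in f.attrs:
            config = json.loads(f.attrs["config_json"])
        run = TrackingRun(
            patterns, centers, truth, ests, build_tracking_pattern(),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
    return run, config


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as TSV with columns t_s, x_nm[, y_nm, z_nm]."""
    t = np.arange(traj.n) * traj.dt_s
    cols = ["x_nm", "y_nm", "z_nm"][: traj.ndim]
    df = pd.DataFrame(traj.positions, columns=cols)
    df.insert(0, "t_s", t)
    df.to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> Trajectory:
    """Read a TSV trajectory; rejects non-uniform sampling with the row number."""
    df = pd.read_csv(path, sep="\t")
    if "t_s" not in df.columns:
        raise ValueError("trajectory file must have a t_s column")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trajectory must have at least 2 rows")
    dt = np.diff(t)
    bad = np.flatnonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-12))
    if len(bad):
        # +3: header line plus 1-based indexing plus the interval's endpoint
        raise ValueError(f"non-uniform sampling interval at row {int(bad[0]) + 3}")
    cols = [c for c in ("x_nm", "y_nm", "z_nm") if c in df.columns]
    if not cols:
        raise ValueError("trajectory file must have x_nm[, y_nm, z_nm] columns")
    return Trajectory(df[cols].to_numpy(dtype=float), float(dt[0]))


def write_diffusion_series(series: DiffusionSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)
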