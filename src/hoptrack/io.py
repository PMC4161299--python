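"""File formats: trajectory/spot CSV dialects, masks, movies, configs.

All tabular interfaces are plain CSV with µm/second units; round-trips are
lossless.  The trajectory dialect has columns
``track_id, frame, x_um, y_um, intensity, background, sigma_px, snr``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import CellGeometry, Spot, TrackSet, Trajectory, geometry_from_mask
from .link import HopChain
from .simulate import GroundTruth, SimConfig

__all__ = [
    "tracks_to_frame",
    "frame_to_tracks",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_spots_csv",
    "read_spots_csv",
    "read_mask",
    "write_movie",
    "read_movie",
    "load_sim_config",
    "dump_sim_config",
    "write_chains_csv",
    "write_ground_truth_csv",
]

_TRACK_COLUMNS = [
    "track_id", "frame", "x_um", "y_um", "intensity", "background",
    "sigma_px", "snr",
]


def tracks_to_frame(trackset: TrackSet) -> pd.DataFrame:
    rows = []
    for t in trackset:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": t.id,
                    "frame": t.frames,
                    "x_um": t.x,
                    "y_um": t.y,
                    "intensity": t.intensity,
                    "background": t.background,
                    "sigma_px": t.sigma,
                    "snr": t.snr,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=_TRACK_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def frame_to_tracks(
    df: pd.DataFrame,
    frame_interval: float = 0.033,
    pixel_size: float = 0.1,
    n_frames: int | None = None,
    geometry: CellGeometry | None = None,
) -> TrackSet:
    missing = [c for c in ("track_id", "frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table is missing columns: {missing}")
    trajectories = []
    for tid, group in df.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy(dtype=np.int64)
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            bad = int(group.index[np.argmax(np.diff(frames) != 1)])
            raise ValueError(
                f"track {tid}: frames not consecutive (first gap at row {bad})"
            )
        trajectories.append(
            Trajectory(
                id=int(tid),
                frames=frames,
                x=group["x_um"].to_numpy(),
                y=group["y_um"].to_numpy(),
                intensity=group.get("intensity", pd.Series(np.ones(len(group)))).to_numpy(),
                background=group.get("background", pd.Series(np.zeros(len(group)))).to_numpy(),
                sigma=group.get("sigma_px", pd.Series(np.full(len(group), 2.0))).to_numpy(),
                snr=group.get("snr", pd.Series(np.full(len(group), np.inf))).to_numpy(),
            )
        )
    return TrackSet(
        trajectories=trajectories,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        n_frames=n_frames,
        geometry=geometry,
    )


def write_tracks_csv(trackset: TrackSet, path) -> None:
    tracks_to_frame(trackset).to_csv(path, index=False)


def read_tracks_csv(path, **kwargs) -> TrackSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the offending file
        raise ValueError(f"could not parse trajectory CSV {path}: {exc}") from exc
    return frame_to_tracks(df, **kwargs)


def write_spots_csv(spots: list[Spot], path) -> None:
    pd.DataFrame(
        {
            "frame": [s.frame for s in spots],
            "x_um": [s.x for s in spots],
            "y_um": [s.y for s in spots],
            "intensity": [s.intensity for s in spots],
            "background": [s.background for s in spots],
            "sigma_px": [s.sigma for s in spots],
            "snr": [s.snr for s in spots],
        }
    ).to_csv(path, index=False)


def read_spots_csv(path) -> dict[int, list[Spot]]:
    df = pd.read_csv(path)
    out: dict[int, list[Spot]] = {}
    for _, row in df.iterrows():
        s = Spot(
            frame=int(row["frame"]),
            x=float(row["x_um"]),
            y=float(row["y_um"]),
            intensity=float(row.get("intensity", 1.0)),
            background=float(row.get("background", 0.0)),
            sigma=float(row.get("sigma_px", 2.0)),
            snr=float(row.get("snr", np.inf)),
        )
        out.setdefault(s.frame, []).append(s)
    return out


def read_mask(path, pixel_size: float) -> CellGeometry:
    """Binary mask (PNG/TIFF) -> cell geometry."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio import v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return geometry_from_mask(arr > 0, pixel_size)


def write_movie(movie: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(movie, dtype=np.uint16), photometric="minisblack")


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


def load_sim_config(path) -> SimConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SimConfig(**data)


def dump_sim_config(config: SimConfig, path) -> None:
    path = Path(path)
    data = asdict(config)
    data.pop("link", None)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def write_chains_csv(chains: list[HopChain], path) -> None:
    pd.DataFrame(
        {
            "chain_id": range(len(chains)),
            "member_track_ids": [";".join(map(str, c.trajectory_ids)) for c in chains],
            "n_hops": [len(c.hop_displacements) for c in chains],
            "lifetime_s": [c.lifetime for c in chains],
        }
    ).to_csv(path, index=False)


def write_ground_truth_csv(truth: GroundTruth, path) -> None:
    dt = truth.config.dt
    rows = []
    for i, v in enumerate(truth.visits):
        rows.append(
            {
                "visit_id": i,
                "molecule_id": v.molecule_id,
                "first_frame": v.first_frame,
                "last_frame": v.last_frame,
                "residence_s": v.n_frames * dt,
                "end_cause": v.end_cause,
                "rebinds": v.rebinds,
                "x_first": v.x[0],
                "y_first": v.y[0],
                "x_last": v.x[-1],
                "y_last": v.y[-1],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
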