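"""Delimited-text readers/writers and provenance records shared by the CLI."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .histo import SCHEMES, RegionScheme
from .trafficking import Run, Track


def write_tracks_csv(tracks: Sequence[Track], path) -> None:
    rows = []
    for t in tracks:
        for frame, pos in enumerate(t.positions):
            rows.append(
                {
                    "track_id": t.track_id,
                    "group": t.group,
                    "frame": frame,
                    "time_s": frame * t.frame_interval_s,
                    "position_um": pos,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path, frame_interval_s: float = 0.5, pixel_size_um: float = 0.1) -> list[Track]:
    df = pd.read_csv(path)
    required = {"track_id", "group", "frame", "position_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        if "time_s" in sub.columns and len(sub) >= 2:
            dt = float(np.diff(sub["time_s"].to_numpy())[0])
        else:
            dt = frame_interval_s
        tracks.append(
            Track(
                track_id=str(tid),
                group=str(sub["group"].iloc[0]),
                frame_interval_s=dt,
                positions=sub["position_um"].to_numpy(dtype=float),
                pixel_size_um=pixel_size_um,
            )
        )
    return tracks


def read_paths_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"track_id", "group", "row_px", "col_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"paths CSV missing columns: {sorted(missing)}")
    return df


def write_runs_csv(runs_by_track: dict[str, list[Run]], groups: dict[str, str], path) -> None:
    rows = [
        {
            "track_id": r.track_id,
            "group": groups.get(r.track_id, ""),
            "direction": r.direction,
            "start_frame": r.start_frame,
            "end_frame": r.end_frame,
            "length_um": r.length_um,
            "duration_s": r.duration_s,
            "speed_um_per_s": r.speed_um_per_s,
        }
        for runs in runs_by_track.values()
        for r in runs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "group",
            "direction",
            "start_frame",
            "end_frame",
            "length_um",
            "duration_s",
            "speed_um_per_s",
        ],
    ).to_csv(path, index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"animal_id", "group", "region", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns: {sorted(missing)}")
    return df


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "gene", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct TSV missing columns: {sorted(missing)}")
    return df


def read_efficiency_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("efficiency TSV needs 'gene' and 'efficiency' (or 'percent') columns")
    if "efficiency" in df.columns:
        return dict(zip(df["gene"], df["efficiency"].astype(float)))
    if "percent" in df.columns:
        return {g: 1.0 + p / 100.0 for g, p in zip(df["gene"], df["percent"].astype(float))}
    raise ValueError("efficiency TSV needs an 'efficiency' or 'percent' column")


def load_scheme(name_or_path: str) -> RegionScheme:
    """A named built-in scheme, or a YAML file with ``name`` and ``regions``."""
    if name_or_path in SCHEMES:
        return SCHEMES[name_or_path]
    import yaml

    with open(name_or_path) as fh:
        data = yaml.safe_load(fh)
    return RegionScheme(data["name"], tuple(data["regions"]))


def provenance(config: dict, seed: int | None) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "tool": "maptrace",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "config": config,
    }


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (set, frozenset)):
            return sorted(v)
        if isinstance(v, pd.DataFrame):
            return v.to_dict(orient="records")
        return str(v)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
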