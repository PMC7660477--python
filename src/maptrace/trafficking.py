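"""Kymograph-derived lysosome trafficking analysis.

Positions are axial distances from the soma in micrometres (soma at 0,
increasing distally), sampled on a uniform frame grid.  A *run* is a maximal
block of consecutive same-direction frame steps at or above a movement
threshold, kept only if it spans a minimum number of frames; it ends at the
first step that is stationary or opposite-signed ("change of state"), and
that terminating frame is not part of the run.  Tracks are classified from
their run lists as anterograde, retrograde, bidirectional or immobile, and
retrograde metrics (per-run speed, run length, total retrograde distance)
are computed for tracks traced long enough to qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import stats as stats_core

CLASSES = ("anterograde", "retrograde", "bidirectional", "immobile")


@dataclass
class Track:
    """Uniformly sampled axial position series for one lysosome."""

    track_id: str
    group: str
    frame_interval_s: float
    positions: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size < 2:
            raise ValueError("a track needs at least 2 samples")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite position in track")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.size

    @property
    def duration_s(self) -> float:
        return (self.positions.size - 1) * self.frame_interval_s


@dataclass
class SegmentationParams:
    """Run-calling parameters.

    ``min_run_frames`` is the minimum number of frames a run must span
    (inclusive); ``min_step_um`` is the per-frame movement threshold below
    which a step counts as stationary (defaults to the pixel size — movement
    below one pixel per frame is within tracing resolution); ``min_trace_s``
    is the minimum traced duration for a track to enter retrograde metrics.
    """

    min_run_frames: int = 3
    min_step_um: float | None = None
    min_trace_s: float = 60.0
    eligibility: Literal["traced", "retrograde_time"] = "traced"
    speed_weighting: Literal["unweighted", "duration"] = "unweighted"

    def __post_init__(self):
        if self.min_run_frames < 2:
            raise ValueError("min_run_frames must be >= 2")
        if self.min_step_um is not None and self.min_step_um < 0:
            raise ValueError("min_step_um must be >= 0")
        if self.min_trace_s < 0:
            raise ValueError("min_trace_s must be >= 0")

    def step_threshold(self, track: Track) -> float:
        return track.pixel_size_um if self.min_step_um is None else self.min_step_um


@dataclass
class Run:
    """A maximal directional movement episode within one track."""

    track_id: str
    direction: Literal["anterograde", "retrograde"]
    start_frame: int
    end_frame: int
    length_um: float
    duration_s: float
    speed_um_per_s: float


@dataclass
class TrackMetrics:
    track_id: str
    eligible: bool
    mean_retro_speed_um_per_s: float | None = None
    retro_run_lengths_um: list[float] = field(default_factory=list)
    total_retro_distance_um: float | None = None


_EPS = 1e-9


def step_signs(positions: np.ndarray, threshold: float) -> np.ndarray:
    """Classify each frame-to-frame step as +1 (anterograde), -1
    (retrograde, toward the soma) or 0 (stationary)."""
    steps = np.diff(np.asarray(positions, dtype=float))
    signs = np.zeros(steps.size, dtype=int)
    signs[steps >= threshold - _EPS] = 1
    signs[steps <= -threshold + _EPS] = -1
    return signs


def segment_runs(track: Track, params: SegmentationParams | None = None) -> list[Run]:
    """Segment a track into runs by scanning maximal same-sign step blocks.

    A block of ``k`` consecutive moving steps of one sign spans ``k + 1``
    frames; it is reported as a run iff ``k + 1 >= min_run_frames``.
    """
    params = params or SegmentationParams()
    if track.n_frames < params.min_run_frames:
        return []
    signs = step_signs(track.positions, params.step_threshold(track))
    runs: list[Run] = []
    i = 0
    while i < signs.size:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < signs.size and signs[j + 1] == signs[i]:
            j += 1
        n_steps = j - i + 1
        if n_steps + 1 >= params.min_run_frames:
            start, end = i, j + 1
            length = abs(track.positions[end] - track.positions[start])
            duration = n_steps * track.frame_interval_s
            runs.append(
                Run(
                    track_id=track.track_id,
                    direction="anterograde" if signs[i] > 0 else "retrograde",
                    start_frame=start,
                    end_frame=end,
                    length_um=float(length),
                    duration_s=float(duration),
                    speed_um_per_s=float(length / duration),
                )
            )
        i = j + 1
    return runs


def classify_track(runs: Sequence[Run]) -> str:
    """Classify a run list as anterograde / retrograde / bidirectional /
    immobile (the latter covers tracks with no qualifying run)."""
    if len({r.track_id for r in runs}) > 1:
        raise ValueError("runs from multiple tracks passed to classify_track")
    has_a = any(r.direction == "anterograde" for r in runs)
    has_r = any(r.direction == "retrograde" for r in runs)
    if has_a and has_r:
        return "bidirectional"
    if has_a:
        return "anterograde"
    if has_r:
        return "retrograde"
    return "immobile"


def retrograde_metrics(
    track: Track, runs: Sequence[Run], params: SegmentationParams | None = None
) -> TrackMetrics:
    """Per-track retrograde summaries for tracks traced long enough.

    Eligibility defaults to total traced duration >= ``min_trace_s`` plus at
    least one retrograde run; ``eligibility='retrograde_time'`` instead
    requires the cumulative retrograde run time to reach the threshold.
    """
    params = params or SegmentationParams()
    retro = [r for r in runs if r.direction == "retrograde"]
    if params.eligibility == "traced":
        time_ok = track.duration_s >= params.min_trace_s
    else:
        time_ok = sum(r.duration_s for r in retro) >= params.min_trace_s
    if not (time_ok and retro):
        return TrackMetrics(track_id=track.track_id, eligible=False)
    speeds = np.array([r.speed_um_per_s for r in retro])
    if params.speed_weighting == "duration":
        weights = np.array([r.duration_s for r in retro])
        mean_speed = float(np.average(speeds, weights=weights))
    else:
        mean_speed = float(speeds.mean())
    lengths = [r.length_um for r in retro]
    return TrackMetrics(
        track_id=track.track_id,
        eligible=True,
        mean_retro_speed_um_per_s=mean_speed,
        retro_run_lengths_um=lengths,
        total_retro_distance_um=float(sum(lengths)),
    )


def movement_class_table(
    classifications: dict[str, str], groups: dict[str, str]
) -> pd.DataFrame:
    """Group x class contingency table of track classifications."""
    known = set(groups.values())
    table = pd.DataFrame(
        0, index=sorted(known), columns=list(CLASSES), dtype=int
    )
    for tid, cls in classifications.items():
        if tid not in groups:
            raise ValueError(f"track {tid!r} has no group label")
        table.loc[groups[tid], cls] += 1
    return table


def path_to_track(
    path,
    pixel_size_um: float,
    frame_interval_s: float,
    soma_side: Literal["left", "right"] = "left",
    width_px: int | None = None,
    track_id: str = "track",
    group: str = "",
) -> Track:
    """Convert a traced kymograph path (row = frame, col = pixel) to a track.

    Vertex rows must be strictly increasing (a path cannot revisit a time
    row); positions are resampled at every integer frame row by linear
    interpolation and converted to micrometres with the soma at 0.  With
    ``soma_side='right'`` the raster width is required to mirror columns.
    """
    path = np.asarray(path, dtype=float)
    rows, cols = path[:, 0], path[:, 1]
    if np.any(np.diff(rows) <= 0):
        raise ValueError("path rows must be strictly increasing (time axis)")
    frames = np.arange(int(np.ceil(rows[0])), int(np.floor(rows[-1])) + 1)
    if frames.size < 2:
        raise ValueError("path spans fewer than 2 frame rows")
    col_at = np.interp(frames, rows, cols)
    if soma_side == "left":
        positions = col_at * pixel_size_um
    elif soma_side == "right":
        if width_px is None:
            raise ValueError("width_px required when soma_side='right'")
        positions = (width_px - 1 - col_at) * pixel_size_um
    else:
        raise ValueError("soma_side must be 'left' or 'right'")
    return Track(
        track_id=track_id,
        group=group,
        frame_interval_s=frame_interval_s,
        positions=positions,
        pixel_size_um=pixel_size_um,
    )


def analyze_tracks(
    tracks: Sequence[Track], params: SegmentationParams | None = None
) -> dict:
    """Segment, classify and summarise a collection of tracks."""
    params = params or SegmentationParams()
    runs_by_track = {t.track_id: segment_runs(t, params) for t in tracks}
    classifications = {tid: classify_track(r) for tid, r in runs_by_track.items()}
    groups = {t.track_id: t.group for t in tracks}
    metrics = {
        t.track_id: retrograde_metrics(t, runs_by_track[t.track_id], params)
        for t in tracks
    }
    return {
        "runs": runs_by_track,
        "classifications": classifications,
        "groups": groups,
        "metrics": metrics,
        "table": movement_class_table(classifications, groups),
    }


def compare_trafficking(
    tracks: Sequence[Track],
    params: SegmentationParams | None = None,
    run_pool: Literal["eligible", "all"] = "eligible",
) -> dict:
    """Two-group trafficking comparison.

    Reports the class-proportion chi-square, a run-level Mann-Whitney on
    retrograde run lengths, and track-level Mann-Whitney tests on mean
    retrograde speed and total retrograde distance, with the sample size at
    each granularity.  ``run_pool`` selects whether the run-level pool is
    restricted to metric-eligible tracks (default) or drawn from all tracks.
    """
    params = params or SegmentationParams()
    res = analyze_tracks(tracks, params)
    group_names = sorted({t.group for t in tracks})
    if len(group_names) != 2:
        raise ValueError("compare_trafficking needs exactly two groups")
    g1, g2 = group_names
    report: dict = {"groups": group_names, "class_table": res["table"].to_dict()}
    # classes observed in neither group carry no information; drop them so the
    # chi-square table has no zero marginal
    ctab = res["table"].loc[[g1, g2]]
    ctab = ctab.loc[:, ctab.sum(axis=0) > 0]
    if ctab.shape[1] < 2:
        # every track falls in one class: no association to test
        report["chi_square"] = stats_core.TestResult(
            test="chi_square_independence", statistic=0.0, df=0, p_value=1.0,
            n={"grand_total": int(ctab.to_numpy().sum())},
            extra={"note": "single movement class observed"},
        ).to_dict()
    else:
        report["chi_square"] = stats_core.chi_square_independence(
            ctab.to_numpy()
        ).to_dict()

    def _pool(group: str, attr: str):
        vals = []
        for t in tracks:
            if t.group != group:
                continue
            m = res["metrics"][t.track_id]
            if attr == "run_lengths":
                if run_pool == "eligible":
                    if m.eligible:
                        vals.extend(m.retro_run_lengths_um)
                else:
                    vals.extend(
                        r.length_um
                        for r in res["runs"][t.track_id]
                        if r.direction == "retrograde"
                    )
            elif m.eligible:
                vals.append(getattr(m, attr))
        return np.array(vals, dtype=float)

    for key, attr in [
        ("run_length", "run_lengths"),
        ("mean_retro_speed", "mean_retro_speed_um_per_s"),
        ("total_retro_distance", "total_retro_distance_um"),
    ]:
        a, b = _pool(g1, attr), _pool(g2, attr)
        if a.size == 0 or b.size == 0:
            report[key] = {"computable": False, "n": {g1: int(a.size), g2: int(b.size)}}
        else:
            r = stats_core.mann_whitney(a, b).to_dict()
            r["n"] = {g1: int(a.size), g2: int(b.size)}
            r["computable"] = True
            report[key] = r
    report["n_eligible"] = {
        g: int(
            sum(
                1
                for t in tracks
                if t.group == g and res["metrics"][t.track_id].eligible
            )
        )
        for g in group_names
    }
    return report
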