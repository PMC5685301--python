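"""Visual stimulus–response metrics from larval position tracks.

Larvae swim in agarose troughs imaged over a screen; after a baseline
period a red bar animates under one half of the trough. Avoidance is
read out as occupancy of the opposite ("down") half, time-averaged over
the stimulus window, plus per-larva mean swim speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_TRACK_COLUMNS = ("larva_id", "frame", "time_s", "x_mm", "y_mm")


@dataclass
class TroughGeometry:
    """Rectangular trough, long axis along y. The midline splits it into
    a lower half (y < midline) and an upper half (y > midline)."""

    length_mm: float = 70.0
    width_mm: float = 10.0

    @property
    def midline_mm(self) -> float:
        return self.length_mm / 2.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("trough dimensions must be positive")


@dataclass
class StimulusWindow:
    start_s: float
    end_s: float
    stimulated_half: str = "upper"  # half under which the bar animates

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("stimulus window must be non-empty")
        if self.stimulated_half not in ("lower", "upper"):
            raise ValueError("stimulated_half must be 'lower' or 'upper'")


@dataclass
class TrajectorySet:
    """Time-stamped larval positions plus trough/stimulus geometry.

    ``tracks`` holds one row per (larva, frame) with columns
    larva_id, frame, time_s, x_mm, y_mm; missing (lost-tracking)
    frames are simply absent rows.
    """

    tracks: pd.DataFrame
    trough: TroughGeometry
    stimulus: StimulusWindow
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_TRACK_COLUMNS if c not in self.tracks.columns]
        if missing:
            raise ValueError(f"tracks missing required columns: {missing}")
        y = self.tracks["y_mm"].to_numpy(float)
        x = self.tracks["x_mm"].to_numpy(float)
        bad = (y < 0) | (y > self.trough.length_mm) | (x < 0) | (x > self.trough.width_mm)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"position outside trough bounds at tracks row {row} "
                f"(x={x[row]:.3f}, y={y[row]:.3f})"
            )
        for lid, grp in self.tracks.groupby("larva_id"):
            t = grp["time_s"].to_numpy(float)
            if (np.diff(t) <= 0).any():
                raise ValueError(f"time not strictly increasing for larva {lid!r}")

    @property
    def larva_ids(self) -> list:
        return sorted(self.tracks["larva_id"].unique().tolist())


@dataclass
class BehaviorMetrics:
    """Group-level summary: time-averaged % of larvae in the
    unstimulated half, and mean swim speed over larvae."""

    percent_down: float
    mean_speed_mm_s: float
    per_larva_speed: pd.Series = field(repr=False, default=None)  # type: ignore
    n_larvae: int = 0


def percent_down(tracks: TrajectorySet) -> float:
    """Time-averaged percentage of larvae in the half away from the bar.

    For each frame inside the stimulus window the fraction of tracked
    larvae in the unstimulated half is computed; the metric is 100x the
    mean over frames. Larvae exactly on the midline count as in the
    stimulated half (conservative: biases against detecting avoidance).
    """
    df = tracks.tracks
    stim = tracks.stimulus
    win = df[(df["time_s"] >= stim.start_s) & (df["time_s"] <= stim.end_s)]
    if win.empty:
        raise ValueError("stimulus window contains no frames")
    y = win["y_mm"].to_numpy(float)
    mid = tracks.trough.midline_mm
    if stim.stimulated_half == "upper":
        down = y < mid  # midline ties (y == mid) fall to the stimulated side
    else:
        down = y > mid
    frac = pd.Series(down, index=win.index).groupby(win["frame"]).mean()
    return float(frac.mean() * 100.0)


def swim_speed(
    tracks: TrajectorySet,
    window: tuple[float, float] | None = None,
    max_missing_fraction: float = 0.5,
) -> pd.Series:
    """Per-larva mean swim speed (mm/s): total path length over elapsed time.

    Uses all frames unless ``window`` restricts it. Lost frames are
    skipped pairwise (displacement over the actual time gap). Larvae
    with a single usable frame, or missing more than
    ``max_missing_fraction`` of the expected frames, are dropped with a
    warning.
    """
    df = tracks.tracks
    if window is not None:
        df = df[(df["time_s"] >= window[0]) & (df["time_s"] <= window[1])]
    n_expected = df["frame"].nunique()
    speeds = {}
    for lid, grp in df.groupby("larva_id"):
        grp = grp.sort_values("time_s")
        if len(grp) < 2:
            log.warning("larva %r has <2 frames; excluded from speed", lid)
            continue
        if n_expected and len(grp) < (1.0 - max_missing_fraction) * n_expected:
            log.warning(
                "larva %r missing >%d%% of frames; dropped",
                lid, int(max_missing_fraction * 100),
            )
            continue
        x = grp["x_mm"].to_numpy(float)
        y = grp["y_mm"].to_numpy(float)
        t = grp["time_s"].to_numpy(float)
        path = float(np.hypot(np.diff(x), np.diff(y)).sum())
        speeds[lid] = path / float(t[-1] - t[0])
    return pd.Series(speeds, name="speed_mm_s")


def behavior_metrics(tracks: TrajectorySet) -> BehaviorMetrics:
    """Compute both stimulus-response readouts for one trajectory set."""
    speeds = swim_speed(tracks)
    return BehaviorMetrics(
        percent_down=percent_down(tracks),
        mean_speed_mm_s=float(speeds.mean()) if len(speeds) else float("nan"),
        per_larva_speed=speeds,
        n_larvae=len(tracks.larva_ids),
    )


def summarize_groups(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Group means with standard errors (sample SD / sqrt(n)).

    Returns a DataFrame indexed by group with columns mean, se, n;
    se is NaN for singleton groups.
    """
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    out = []
    for g, vals in pd.Series(values.to_numpy(float), index=groups.to_numpy()).groupby(level=0):
        v = vals.to_numpy()
        n = len(v)
        if n == 0:
            raise ValueError(f"group {g!r} is empty")
        se = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        out.append({"group": g, "mean": float(v.mean()), "se": se, "n": n})
    return pd.DataFrame(out).set_index("group")
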