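"""File formats, run configuration and the end-to-end driver.

TIFF stacks are read/written with :mod:`tifffile` (page order = slice
order), tabular data as CSV via pandas, configuration as YAML or JSON.
:func:`run_all` ties the pieces together: optional simulation, NMJ and
behaviour quantification, group statistics, and a machine-readable run
manifest recording seeds, parameters and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import behavior as bh
from . import imaging as im
from . import simulate as sim
from . import stats as st

log = logging.getLogger(__name__)

NMJ_CSV_COLUMNS = [
    "larva_id", "group", "pct_red", "pct_green", "n_red_particles",
    "n_green_particles", "mean_green_particle_area_um2", "M1", "M2", "pearson",
]


class FormatError(ValueError):
    """A file is readable but not in the expected format."""


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(
    path: str | Path,
    pixel_size_xy: float = 1.0,
    z_step: float = 1.0,
    channel_label: str = "",
) -> im.ImageStack:
    """Read a multi-page grayscale TIFF (8- or 16-bit) as an ImageStack."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            samples = tif.pages[0].samplesperpixel
            if samples != 1:
                raise FormatError(
                    f"{path}: {samples} samples per pixel (RGB/multi-sample); "
                    "only grayscale pages are supported"
                )
            voxels = tif.asarray()
    except FormatError:
        raise
    except Exception as err:  # truncated / not a TIFF
        raise FormatError(f"{path}: cannot read TIFF ({err})") from err
    if voxels.ndim == 2:
        voxels = voxels[None, ...]
    if voxels.ndim != 3:
        raise FormatError(f"{path}: expected a stack of grayscale pages, "
                          f"got array of shape {voxels.shape}")
    if voxels.dtype == np.uint8:
        bit_depth = 8
    elif voxels.dtype == np.uint16:
        bit_depth = 16
    else:
        raise FormatError(f"{path}: unsupported sample dtype {voxels.dtype}; need uint8/uint16")
    return im.ImageStack(voxels, bit_depth, pixel_size_xy, z_step, channel_label)


def write_stack(stack: im.ImageStack, path: str | Path) -> None:
    """Write an ImageStack as a multi-page grayscale TIFF (lossless)."""
    tifffile.imwrite(Path(path), stack.voxels, photometric="minisblack")


# ---------------------------------------------------------------------------
# track CSVs


def read_tracks(
    path: str | Path,
    trough: bh.TroughGeometry,
    stimulus: bh.StimulusWindow,
    frame_interval_s: float = 1.0,
) -> bh.TrajectorySet:
    """Read larval tracks from CSV; unknown columns pass through."""
    df = pd.read_csv(path)
    missing = [c for c in bh.REQUIRED_TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return bh.TrajectorySet(tracks=df, trough=trough, stimulus=stimulus,
                            frame_interval_s=frame_interval_s)


def write_tracks(traj: bh.TrajectorySet, path: str | Path) -> None:
    traj.tracks.to_csv(path, index=False)


def write_metrics(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from YAML or JSON."""

    seed: int = 0
    pixel_size_xy: float = 0.3  # um/px
    z_step: float = 1.0  # um
    frame_interval_s: float = 1.0
    slice_range: Optional[tuple[int, int]] = None
    roi: Optional[im.RectROI] = None
    min_area_pixels: int = 0
    trough: bh.TroughGeometry = field(default_factory=bh.TroughGeometry)
    stimulus: bh.StimulusWindow = field(
        default_factory=lambda: bh.StimulusWindow(900.0, 1500.0, "upper"))
    alpha: float = 0.05
    tail: str = "two"
    outlier_rejection: bool = True
    n_stacks_per_group: int = 10
    groups: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {"control": {}, "treated": {}})
    imaging_params: dict[str, Any] = field(default_factory=dict)
    behavior_params: dict[str, Any] = field(default_factory=dict)
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "roi" in raw and raw["roi"] is not None:
            raw["roi"] = im.RectROI(**raw["roi"])
        if "trough" in raw:
            raw["trough"] = bh.TroughGeometry(**raw["trough"])
        if "stimulus" in raw:
            raw["stimulus"] = bh.StimulusWindow(**raw["stimulus"])
        if "slice_range" in raw and raw["slice_range"] is not None:
            raw["slice_range"] = tuple(raw["slice_range"])
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# end-to-end driver


def run_all(config: RunConfig) -> dict[str, Any]:
    """Simulate → quantify → compare, writing CSV outputs and a manifest.

    For each configured group: generate ``n_stacks_per_group`` synthetic
    two-channel stacks and one plate-assay trajectory set (group
    parameter shifts come from ``config.groups``), quantify them, then
    compare groups pairwise per metric with optional per-group modified
    Thompson tau outlier rejection and the configured t-test tail.
    Returns the report dict; everything is also written under
    ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    nmj_rows: list[dict[str, Any]] = []
    behavior_rows: list[dict[str, Any]] = []
    speed_records: list[dict[str, Any]] = []

    for group, shifts in config.groups.items():
        img_over = dict(config.imaging_params)
        beh_over = dict(config.behavior_params)
        for k, v in shifts.items():
            if k in sim.SyntheticNMJParams.__dataclass_fields__:
                img_over[k] = v
            if k in sim.SyntheticBehaviorParams.__dataclass_fields__:
                beh_over[k] = v
        log.info("group %s: imaging overrides %s, behaviour overrides %s",
                 group, img_over, beh_over)

        for i in range(config.n_stacks_per_group):
            p = sim.SyntheticNMJParams(
                pixel_size_xy=config.pixel_size_xy, z_step=config.z_step,
                **{**img_over, "seed": int(rng.integers(2**31))})
            pair, _ = sim.generate_nmj_stack(p)
            m = im.quantify_nmj(pair, config.slice_range, config.roi,
                                config.min_area_pixels, larva_id=f"{group}_{i:02d}")
            row = m.as_dict()
            row["group"] = group
            nmj_rows.append(row)

        bp = sim.SyntheticBehaviorParams(
            frame_interval_s=config.frame_interval_s,
            trough_length_mm=config.trough.length_mm,
            trough_width_mm=config.trough.width_mm,
            **{**beh_over, "seed": int(rng.integers(2**31))})
        traj, _ = sim.generate_behavior(bp)
        metrics = bh.behavior_metrics(traj)
        behavior_rows.append({
            "group": group,
            "percent_down": metrics.percent_down,
            "mean_speed_mm_s": metrics.mean_speed_mm_s,
            "n_larvae": metrics.n_larvae,
        })
        for lid, v in metrics.per_larva_speed.items():
            speed_records.append({"group": group, "larva_id": lid, "speed_mm_s": v})

    nmj_df = pd.DataFrame(nmj_rows)[NMJ_CSV_COLUMNS]
    behavior_df = pd.DataFrame(behavior_rows)
    speed_df = pd.DataFrame(speed_records)

    comparisons = compare_groups(
        pd.concat(
            [nmj_df.melt(id_vars=["larva_id", "group"], var_name="metric"),
             speed_df.rename(columns={"speed_mm_s": "value"}).assign(metric="speed_mm_s")],
            ignore_index=True),
        alpha=config.alpha, tail=config.tail,
        outlier_rejection=config.outlier_rejection)

    nmj_path = out_dir / "nmj_metrics.csv"
    beh_path = out_dir / "behavior_metrics.csv"
    cmp_path = out_dir / "comparisons.csv"
    nmj_df.to_csv(nmj_path, index=False)
    behavior_df.to_csv(beh_path, index=False)
    comparisons.to_csv(cmp_path, index=False)

    manifest = {
        "seed": config.seed,
        "config": {k: str(v) for k, v in config.__dict__.items()},
        "outputs": {p.name: _sha256(p) for p in (nmj_path, beh_path, cmp_path)},
        "stats_method": ("Student pooled-variance t-test; modified Thompson tau "
                         f"outlier rejection {'on' if config.outlier_rejection else 'off'} "
                         f"(alpha={config.alpha}, tail={config.tail})"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"nmj": nmj_df, "behavior": behavior_df, "comparisons": comparisons,
            "manifest": manifest}


def compare_groups(
    long_df: pd.DataFrame,
    alpha: float = 0.05,
    tail: str = "two",
    outlier_rejection: bool = True,
) -> pd.DataFrame:
    """Pairwise group comparison per metric.

    ``long_df`` has columns metric, group, value. Outlier rejection (if
    on) runs per group before means/s.e.; singleton or degenerate
    groups are reported with NaN statistics rather than dropped.
    """
    rows = []
    for metric, mdf in long_df.groupby("metric"):
        cleaned: dict[str, np.ndarray] = {}
        for group, gdf in mdf.groupby("group"):
            vals = gdf["value"].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            n_before = len(vals)
            if outlier_rejection and n_before >= 3:
                rep = st.thompson_tau_outliers(vals, alpha)
                vals = np.asarray(rep.kept)
            cleaned[group] = (vals, n_before)
        names = sorted(cleaned)
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                va, na_before = cleaned[ga]
                vb, nb_before = cleaned[gb]
                if len(va) >= 2 and len(vb) >= 2:
                    res = st.t_test(va, vb, tail)
                    p, tstat = res.p_value, res.statistic
                else:
                    p = tstat = float("nan")
                rows.append({
                    "metric": metric, "group_a": ga, "group_b": gb,
                    "mean_a": float(np.mean(va)) if len(va) else float("nan"),
                    "mean_b": float(np.mean(vb)) if len(vb) else float("nan"),
                    "se_a": float(np.std(va, ddof=1) / np.sqrt(len(va))) if len(va) > 1 else float("nan"),
                    "se_b": float(np.std(vb, ddof=1) / np.sqrt(len(vb))) if len(vb) > 1 else float("nan"),
                    "n_a_before": na_before, "n_a_after": len(va),
                    "n_b_before": nb_before, "n_b_after": len(vb),
                    "t": tstat, "p_value": p, "tail": tail,
                })
    return pd.DataFrame(rows)
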