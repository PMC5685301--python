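"""Ground-truthed synthetic inputs for pipeline validation.

Two generators:

* :func:`generate_nmj_stack` — two-channel punctate 3D confocal stacks
  of the larval trunk musculature: green AChR-like clusters (larger
  Gaussian blobs) and red presynaptic puncta (smaller blobs), a
  controllable fraction of which sit inside green clusters. Both
  channels are blurred by a Gaussian PSF, then Poisson shot noise,
  background and Gaussian read noise are applied and the result is
  quantized to the requested bit depth.

* :func:`generate_behavior` — plate-assay trajectories of ~50 larvae
  performing a reflected persistent random walk in a trough; during the
  stimulus window each larva currently over the animated bar is, with
  per-frame probability ``p_avoid``, redirected toward the other half.

Treatment effects (drug exposure, knockdown) are represented only as
parameter shifts supplied by the caller — lower ``p_avoid``, lower
``baseline_speed``, altered ``coloc_fraction`` — never hard-coded.
Both generators are bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .behavior import StimulusWindow, TrajectorySet, TroughGeometry
from .imaging import ImageStack, TwoChannelStack


@dataclass
class SyntheticNMJParams:
    """Knobs of the confocal simulator; defaults mimic a 10-slice,
    ~1 um z-step lateral-muscle acquisition at 0.3 um/px."""

    shape: tuple[int, int, int] = (8, 96, 96)  # (slices, rows, cols)
    n_red_puncta: int = 30
    n_green_clusters: int = 12
    coloc_fraction: float = 0.5
    red_radius_um: float = 0.4
    green_radius_um: float = 1.0
    red_peak: float = 150.0
    green_peak: float = 150.0
    psf_sigma_um: float = 0.25
    background: float = 10.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    bit_depth: int = 8
    pixel_size_xy: float = 0.3  # um / px
    z_step: float = 1.0  # um / slice
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.red_radius_um <= 0 or self.green_radius_um <= 0 or self.psf_sigma_um <= 0:
            raise ValueError("radii and PSF sigma must be positive")
        if self.read_noise_sd < 0 or self.background < 0:
            raise ValueError("noise and background must be nonnegative")


@dataclass
class SyntheticBehaviorParams:
    """Knobs of the plate-assay simulator; defaults mimic 50 larvae,
    a 15-min baseline and a 10-min moving-bar stimulus at 1 frame/s."""

    n_larvae: int = 50
    baseline_duration_s: float = 900.0
    stimulus_duration_s: float = 600.0
    frame_interval_s: float = 1.0
    trough_length_mm: float = 70.0
    trough_width_mm: float = 10.0
    baseline_speed_mm_s: float = 3.0
    heading_noise_sd: float = 0.5  # rad per step
    p_avoid: float = 0.5  # per-frame redirection probability during stimulus
    stimulated_half: str = "upper"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_avoid <= 1.0:
            raise ValueError("p_avoid must be in [0, 1]")
        if self.baseline_speed_mm_s < 0:
            raise ValueError("speed must be nonnegative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        step = self.baseline_speed_mm_s * self.frame_interval_s
        if step >= min(self.trough_length_mm, self.trough_width_mm):
            raise ValueError("trough too small for the per-frame step size")


@dataclass
class GroundTruth:
    """Simulator sidecar for parameter-recovery tests."""

    coloc_fraction: Optional[float] = None
    n_red_particles: Optional[int] = None
    n_green_particles: Optional[int] = None
    p_avoid: Optional[float] = None
    mean_speed_mm_s: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


# ---------------------------------------------------------------------------
# confocal stacks


def _add_blob(volume: np.ndarray, center: np.ndarray, sigma_vox: np.ndarray,
              peak: float) -> None:
    """Add an anisotropic Gaussian blob in place, truncated at 4 sigma."""
    lo = np.maximum(np.floor(center - 4 * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + 4 * sigma_vox).astype(int) + 1,
                    np.asarray(volume.shape))
    if (hi <= lo).any():
        return
    zz, yy, xx = np.meshgrid(*(np.arange(lo[d], hi[d]) for d in range(3)),
                             indexing="ij")
    d2 = (((zz - center[0]) / sigma_vox[0]) ** 2
          + ((yy - center[1]) / sigma_vox[1]) ** 2
          + ((xx - center[2]) / sigma_vox[2]) ** 2)
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += peak * np.exp(-0.5 * d2)


def generate_nmj_stack(params: SyntheticNMJParams) -> tuple[TwoChannelStack, GroundTruth]:
    """Render a two-channel synthetic NMJ stack with known overlap.

    Green clusters are placed uniformly at random (kept clear of the
    volume border and of each other); ``round(coloc_fraction *
    n_red_puncta)`` red puncta are centred inside randomly chosen green
    clusters with jitter at most a quarter of the cluster radius, and
    the remaining red puncta are placed away from every green cluster.
    Raises if the requested objects cannot fit in the volume.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape
    vox = np.array([params.z_step, params.pixel_size_xy, params.pixel_size_xy])

    def um_to_vox(r_um: float) -> np.ndarray:
        return np.array([r_um / params.z_step,
                         r_um / params.pixel_size_xy,
                         r_um / params.pixel_size_xy])

    # rendered widths are floored at the voxel scale: an optical section
    # cannot resolve sub-voxel structure, and unfloored sigmas alias
    # (puncta centred between slice planes would vanish)
    min_sigma_vox = np.array([0.6, 0.5, 0.5])
    green_sigma = np.maximum(um_to_vox(params.green_radius_um / 2.0), min_sigma_vox)
    red_sigma = np.maximum(um_to_vox(params.red_radius_um / 2.0), min_sigma_vox)

    margin = um_to_vox(params.green_radius_um + 2 * params.psf_sigma_um)
    upper = np.array([nz, ny, nx]) - 1 - margin
    if (upper <= margin).any():
        raise ValueError("objects cannot fit in volume: shape too small for radii")

    def uniform_center() -> np.ndarray:
        return margin + rng.random(3) * (upper - margin)

    def xy_dist_um(a: np.ndarray, b: np.ndarray) -> float:
        d = (a - b) * vox
        return math.hypot(d[1], d[2])

    # separations are enforced on the projected xy distance: the analysis
    # runs on a 2D max projection, where z offsets do not separate objects
    min_green_sep_um = 3.0 * params.green_radius_um + 4.0 * params.psf_sigma_um
    green_centers: list[np.ndarray] = []
    for _ in range(params.n_green_clusters):
        for _attempt in range(2000):
            c = uniform_center()
            if all(xy_dist_um(c, g) >= min_green_sep_um for g in green_centers):
                green_centers.append(c)
                break
        else:
            raise ValueError("objects cannot fit in volume: green clusters too crowded")

    n_coloc = round(params.coloc_fraction * params.n_red_puncta)
    red_centers: list[np.ndarray] = []
    # jitter kept to a quarter of the cluster radius so a colocalized
    # punctum's thresholded footprint stays inside its host cluster's
    for _ in range(n_coloc):
        host = green_centers[rng.integers(len(green_centers))]
        jitter_um = rng.uniform(-0.25, 0.25, size=3) * params.green_radius_um
        red_centers.append(host + jitter_um / vox)
    # non-colocalized puncta kept clear of every green cluster and of
    # each other, so each is its own particle
    clear_um = (params.green_radius_um + params.red_radius_um
                + 4.0 * params.psf_sigma_um)
    red_sep_um = 3.0 * params.red_radius_um + 4.0 * params.psf_sigma_um
    for _ in range(params.n_red_puncta - n_coloc):
        for _attempt in range(2000):
            c = uniform_center()
            if (all(xy_dist_um(c, g) >= clear_um for g in green_centers)
                    and all(xy_dist_um(c, r) >= red_sep_um for r in red_centers)):
                red_centers.append(c)
                break
        else:
            raise ValueError("objects cannot fit in volume: red puncta too crowded")

    red = np.zeros(params.shape, dtype=float)
    green = np.zeros(params.shape, dtype=float)
    for c in green_centers:
        _add_blob(green, c, green_sigma, params.green_peak)
    for c in red_centers:
        _add_blob(red, c, red_sigma, params.red_peak)

    psf_vox = um_to_vox(params.psf_sigma_um)
    red = ndimage.gaussian_filter(red, sigma=psf_vox)
    green = ndimage.gaussian_filter(green, sigma=psf_vox)

    max_val = 2**params.bit_depth - 1
    channels = []
    for signal in (red, green):
        if params.poisson_noise:
            signal = rng.poisson(signal).astype(float)
        signal = signal + params.background
        if params.read_noise_sd > 0:
            signal = signal + rng.normal(0.0, params.read_noise_sd, size=signal.shape)
        dtype = np.uint8 if params.bit_depth == 8 else np.uint16
        channels.append(np.clip(np.round(signal), 0, max_val).astype(dtype))

    pair = TwoChannelStack(
        red=ImageStack(channels[0], params.bit_depth, params.pixel_size_xy,
                       params.z_step, "SYT2"),
        green=ImageStack(channels[1], params.bit_depth, params.pixel_size_xy,
                         params.z_step, "AChR"),
    )
    truth = GroundTruth(
        coloc_fraction=params.coloc_fraction,
        n_red_particles=params.n_red_puncta,
        n_green_particles=params.n_green_clusters,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# plate-assay trajectories


def generate_behavior(params: SyntheticBehaviorParams) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate larval trajectories in a trough with optional avoidance.

    Each larva performs a reflected persistent random walk at constant
    speed; during the stimulus window, with probability ``p_avoid`` per
    frame its heading is redirected (with a little angular jitter)
    toward the unstimulated half.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval_s
    total_s = params.baseline_duration_s + params.stimulus_duration_s
    n_frames = int(round(total_s / dt)) + 1
    trough = TroughGeometry(params.trough_length_mm, params.trough_width_mm)
    stim = StimulusWindow(
        start_s=params.baseline_duration_s,
        end_s=total_s,
        stimulated_half=params.stimulated_half,
    )

    # away_sign: direction along y (trough long axis) pointing away from the bar
    away_sign = -1.0 if params.stimulated_half == "upper" else 1.0
    step = params.baseline_speed_mm_s * dt

    x = rng.random(params.n_larvae) * trough.width_mm
    y = rng.random(params.n_larvae) * trough.length_mm
    heading = rng.random(params.n_larvae) * 2 * math.pi

    times = np.arange(n_frames) * dt
    xs = np.empty((n_frames, params.n_larvae))
    ys = np.empty((n_frames, params.n_larvae))
    xs[0], ys[0] = x, y
    for frame in range(n_frames - 1):
        heading = heading + rng.normal(0.0, params.heading_noise_sd, params.n_larvae)
        if stim.start_s <= times[frame + 1] <= stim.end_s and params.p_avoid > 0:
            # only larvae currently over the animated bar respond
            if params.stimulated_half == "upper":
                exposed = y > trough.midline_mm
            else:
                exposed = y < trough.midline_mm
            redirect = exposed & (rng.random(params.n_larvae) < params.p_avoid)
            if redirect.any():
                jitter = rng.normal(0.0, 0.3, int(redirect.sum()))
                heading[redirect] = away_sign * (math.pi / 2.0) + jitter
        x = x + step * np.cos(heading)
        y = y + step * np.sin(heading)
        # reflecting walls: fold the position and mirror the heading
        flip_x = (x < 0) | (x > trough.width_mm)
        x = np.abs(x)
        x = np.where(x > trough.width_mm, 2 * trough.width_mm - x, x)
        flip_y = (y < 0) | (y > trough.length_mm)
        y = np.abs(y)
        y = np.where(y > trough.length_mm, 2 * trough.length_mm - y, y)
        heading = np.where(flip_x, math.pi - heading, heading)
        heading = np.where(flip_y, -heading, heading)
        xs[frame + 1], ys[frame + 1] = x, y

    ids = np.array([f"L{i:03d}" for i in range(params.n_larvae)])
    tracks = pd.DataFrame(
        {
            "larva_id": np.tile(ids, n_frames),
            "frame": np.repeat(np.arange(n_frames), params.n_larvae),
            "time_s": np.repeat(times, params.n_larvae),
            "x_mm": xs.ravel(),
            "y_mm": ys.ravel(),
        }
    )
    traj = TrajectorySet(tracks=tracks, trough=trough, stimulus=stim,
                         frame_interval_s=dt)
    truth = GroundTruth(p_avoid=params.p_avoid,
                        mean_speed_mm_s=params.baseline_speed_mm_s)
    return traj, truth
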