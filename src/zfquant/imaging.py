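"""Confocal NMJ colocalization pipeline.

Quantifies pre-/post-synaptic marker overlap in two-channel confocal
stacks of the zebrafish trunk: maximum-intensity Z projection over a
slice window, per-channel Kapur (maximum-entropy) thresholding, masking,
rectangular ROI cropping (e.g. removing the myoseptum), masked Manders
M1/M2 and Pearson colocalization, and binary particle analysis.

Conventions: coordinates are 0-based ``(row, col)`` with row increasing
downward; slice ranges are half-open ``[start, stop)``. ROI exclusion
removes pixels from the *analysis domain* rather than zeroing them, so
percentage metrics use the cropped denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful analysis (e.g. a
    single-valued histogram, or an empty analysis domain)."""


class UndefinedCoefficientError(ValueError):
    """Raised when a colocalization coefficient has a zero denominator
    (empty channel after masking, or zero variance for Pearson)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ImageStack:
    """A single-channel 3D intensity volume with physical calibration.

    voxels are indexed ``(slice, row, col)``; intensities must lie in
    ``[0, 2**bit_depth - 1]``.
    """

    voxels: np.ndarray
    bit_depth: int = 8
    pixel_size_xy: float = 1.0  # um / pixel
    z_step: float = 1.0  # um / slice
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a 3D (slice, row, col) array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("calibration must be positive")
        lo, hi = self.voxels.min(), self.voxels.max()
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}]"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class TwoChannelStack:
    """Aligned red (presynaptic, e.g. SYT2) and green (postsynaptic,
    e.g. AChR / alpha-bungarotoxin) stacks for one larva."""

    red: ImageStack
    green: ImageStack

    def __post_init__(self) -> None:
        if self.red.voxels.shape != self.green.voxels.shape:
            raise ValueError("red and green stacks must have identical shape")
        if (
            self.red.pixel_size_xy != self.green.pixel_size_xy
            or self.red.z_step != self.green.z_step
        ):
            raise ValueError("red and green stacks must share calibration")


@dataclass
class Projection:
    """A 2D projection with an analysis-domain mask.

    ``domain`` is True where a pixel participates in downstream
    statistics; ROI cropping clears it rather than zeroing intensities.
    """

    pixels: np.ndarray
    pixel_size_xy: float = 1.0
    bit_depth: int = 8
    source_slices: tuple[int, int] = (0, 1)
    domain: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if self.domain is None:
            self.domain = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.domain = np.asarray(self.domain, dtype=bool)
            if self.domain.shape != self.pixels.shape:
                raise ValueError("domain shape must match pixels")

    def in_domain_values(self) -> np.ndarray:
        return self.pixels[self.domain]


@dataclass
class RectROI:
    """Half-open 0-based rectangular pixel bounds.

    mode="retain" keeps only the rectangle in the analysis domain;
    mode="exclude" removes the rectangle (e.g. cropping out the
    myoseptum) while keeping the rest.
    """

    row_start: int
    row_end: int
    col_start: int
    col_end: int
    mode: str = "exclude"

    def __post_init__(self) -> None:
        if self.mode not in ("retain", "exclude"):
            raise ValueError("mode must be 'retain' or 'exclude'")
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError("ROI must be non-empty")


@dataclass
class BinaryMask:
    pixels: np.ndarray
    threshold_used: float
    domain: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.domain is None:
            self.domain = np.ones(self.pixels.shape, dtype=bool)


@dataclass
class ColocResult:
    M1: float
    M2: float
    pearson: float


@dataclass
class Particle:
    label: int
    area_pixels: int
    area_um2: float
    centroid_row: float
    centroid_col: float


@dataclass
class ParticleSet:
    particles: list[Particle]
    percent_positive_pixels: float

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def total_area_pixels(self) -> int:
        return sum(p.area_pixels for p in self.particles)

    @property
    def mean_area_um2(self) -> float:
        if not self.particles:
            return float("nan")
        return float(np.mean([p.area_um2 for p in self.particles]))


@dataclass
class NMJMetrics:
    """Per-larva record of the quantities reported per micrograph:
    percent positive pixels per channel, particle counts/sizes, and the
    masked Manders and Pearson colocalization coefficients."""

    larva_id: str
    pct_red: float
    pct_green: float
    n_red_particles: int
    n_green_particles: int
    mean_green_particle_area_um2: float
    M1: float
    M2: float
    pearson: float

    def as_dict(self) -> dict:
        return {
            "larva_id": self.larva_id,
            "pct_red": self.pct_red,
            "pct_green": self.pct_green,
            "n_red_particles": self.n_red_particles,
            "n_green_particles": self.n_green_particles,
            "mean_green_particle_area_um2": self.mean_green_particle_area_um2,
            "M1": self.M1,
            "M2": self.M2,
            "pearson": self.pearson,
        }


# ---------------------------------------------------------------------------
# operations


def max_z_projection(stack: ImageStack, slice_range: tuple[int, int] | None = None) -> Projection:
    """Maximum-intensity Z projection over a half-open slice window.

    Each output pixel is the maximum over the selected slices at that
    (row, col); calibration is preserved.
    """
    if slice_range is None:
        slice_range = (0, stack.n_slices)
    start, stop = slice_range
    if not (0 <= start < stop <= stack.n_slices):
        raise IndexError(
            f"slice_range [{start}, {stop}) invalid for {stack.n_slices}-slice stack"
        )
    pixels = stack.voxels[start:stop].max(axis=0)
    return Projection(
        pixels=pixels,
        pixel_size_xy=stack.pixel_size_xy,
        bit_depth=stack.bit_depth,
        source_slices=(start, stop),
    )


def crop_roi(image: Projection, roi: RectROI) -> Projection:
    """Restrict the analysis domain by a rectangular ROI.

    Excluded pixels are dropped from the domain, not zeroed, so
    percentage metrics use the reduced denominator.
    """
    nrow, ncol = image.pixels.shape
    if not (0 <= roi.row_start < roi.row_end <= nrow
            and 0 <= roi.col_start < roi.col_end <= ncol):
        raise IndexError(f"ROI out of bounds for {nrow}x{ncol} image")
    rect = np.zeros((nrow, ncol), dtype=bool)
    rect[roi.row_start:roi.row_end, roi.col_start:roi.col_end] = True
    if roi.mode == "retain":
        new_domain = image.domain & rect
    else:
        new_domain = image.domain & ~rect
    if not new_domain.any():
        raise DegenerateInputError("analysis domain empty after ROI cropping")
    return Projection(
        pixels=image.pixels,
        pixel_size_xy=image.pixel_size_xy,
        bit_depth=image.bit_depth,
        source_slices=image.source_slices,
        domain=new_domain,
    )


def kapur_max_entropy_threshold(histogram: Sequence[int]) -> int:
    """Kapur–Sahoo–Wong maximum-entropy threshold of a 256-bin histogram.

    Returns the level ``t`` maximizing ``H_bg(t) + H_fg(t)`` where each
    term is the Shannon entropy of the normalized histogram restricted
    to bins ``<= t`` (background) and ``> t`` (foreground); empty bins
    contribute zero. Ties break to the smallest ``t``.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or len(hist) != 256:
        raise ValueError("histogram must have 256 bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    nonzero = np.flatnonzero(hist)
    if len(nonzero) < 2:
        raise DegenerateInputError(
            "histogram has fewer than 2 populated bins; no threshold separates anything"
        )
    p = hist / hist.sum()
    # cumulative mass and cumulative plogp, both over bins <= t
    P = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = np.cumsum(plogp)
    total_S = S[-1]

    best_t, best_h = -1, -np.inf
    for t in range(256):
        Pb, Pf = P[t], 1.0 - P[t]
        if Pb <= 0 or Pf <= 0:
            continue  # one side empty: no separation at this t
        hb = math.log(Pb) - S[t] / Pb
        hf = math.log(Pf) - (total_S - S[t]) / Pf
        h = hb + hf
        if h > best_h + 1e-12:
            best_h, best_t = h, t
    if best_t < 0:  # unreachable given >=2 populated bins
        raise DegenerateInputError("no valid threshold found")
    return best_t


def _scale_to_256(pixels: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Min–max linear binning of intensities into 256 levels.

    Returns the binned image plus the (lo, step) mapping; 8-bit inputs
    pass through unchanged (step 1, lo 0).
    """
    lo = float(pixels.min())
    hi = float(pixels.max())
    if hi <= 255 and lo >= 0 and np.issubdtype(np.asarray(pixels).dtype, np.integer):
        return np.asarray(pixels, dtype=np.intp), 0.0, 1.0
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.intp), lo, 1.0
    step = (hi - lo) / 255.0
    binned = np.clip(np.round((pixels - lo) / step), 0, 255).astype(np.intp)
    return binned, lo, step


def threshold_projection(image: Projection) -> float:
    """Kapur threshold of a projection on its native intensity scale.

    16-bit images are binned to 256 levels (min–max linear scaling)
    before thresholding and the chosen level is mapped back.
    """
    vals = image.in_domain_values()
    binned, lo, step = _scale_to_256(vals)
    hist = np.bincount(binned, minlength=256)[:256]
    t = kapur_max_entropy_threshold(hist)
    return lo + t * step


def apply_threshold_mask(image: Projection, threshold: float) -> tuple[BinaryMask, Projection]:
    """Binary mask of pixels strictly above threshold, plus the masked
    projection (original intensities where above, zero elsewhere)."""
    if threshold < 0 or threshold > 2**image.bit_depth - 1:
        raise ValueError(
            f"threshold {threshold} outside bit-depth range [0, {2**image.bit_depth - 1}]"
        )
    above = image.pixels > threshold
    mask = BinaryMask(pixels=above, threshold_used=threshold, domain=image.domain.copy())
    masked = Projection(
        pixels=np.where(above, image.pixels, 0),
        pixel_size_xy=image.pixel_size_xy,
        bit_depth=image.bit_depth,
        source_slices=image.source_slices,
        domain=image.domain.copy(),
    )
    return mask, masked


def manders_coefficients(red_masked: Projection, green_masked: Projection) -> tuple[float, float]:
    """Manders M1/M2 on pre-masked channels (no auto-threshold).

    M1 = sum of red intensity over pixels where green > 0, divided by
    total red intensity; M2 symmetrically for green over red-positive
    pixels. Restricted to the shared analysis domain.
    """
    if red_masked.pixels.shape != green_masked.pixels.shape:
        raise ValueError("channel shapes differ")
    dom = red_masked.domain & green_masked.domain
    r = red_masked.pixels[dom].astype(float)
    g = green_masked.pixels[dom].astype(float)
    r_sum, g_sum = r.sum(), g.sum()
    if r_sum <= 0:
        raise UndefinedCoefficientError("M1 undefined: red channel empty after masking")
    if g_sum <= 0:
        raise UndefinedCoefficientError("M2 undefined: green channel empty after masking")
    m1 = float(r[g > 0].sum() / r_sum)
    m2 = float(g[r > 0].sum() / g_sum)
    return m1, m2


def pearson_coefficient(red_masked: Projection, green_masked: Projection) -> float:
    """Product-moment correlation of the two channels over in-domain pixels."""
    if red_masked.pixels.shape != green_masked.pixels.shape:
        raise ValueError("channel shapes differ")
    dom = red_masked.domain & green_masked.domain
    r = red_masked.pixels[dom].astype(float)
    g = green_masked.pixels[dom].astype(float)
    if r.size < 2:
        raise UndefinedCoefficientError("Pearson undefined: fewer than 2 pixels")
    rd = r - r.mean()
    gd = g - g.mean()
    denom = math.sqrt(float((rd * rd).sum()) * float((gd * gd).sum()))
    if denom == 0:
        raise UndefinedCoefficientError("Pearson undefined: zero variance in a channel")
    return float((rd * gd).sum() / denom)


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def analyze_particles(
    mask: BinaryMask, pixel_size_xy: float = 1.0, min_area_pixels: int = 0
) -> ParticleSet:
    """Connected-component particle analysis of a binary mask.

    Particles are 8-connected components (restricted to the analysis
    domain) with area >= ``min_area_pixels``; percent positive pixels is
    100 x true-in-domain / domain size. Operates purely on the binary
    mask, hence insensitive to stain intensity.
    """
    dom = mask.domain
    if not dom.any():
        raise DegenerateInputError("empty analysis domain")
    fg = mask.pixels & dom
    labels, n = ndimage.label(fg, structure=_EIGHT_CONNECTED)
    particles: list[Particle] = []
    if n:
        areas = ndimage.sum_labels(fg, labels, index=range(1, n + 1)).astype(int)
        centroids = ndimage.center_of_mass(fg, labels, index=range(1, n + 1))
        keep = 0
        for lab, area, (cr, cc) in zip(range(1, n + 1), areas, centroids):
            if area < min_area_pixels:
                continue
            keep += 1
            particles.append(
                Particle(
                    label=keep,
                    area_pixels=int(area),
                    area_um2=float(area) * pixel_size_xy**2,
                    centroid_row=float(cr),
                    centroid_col=float(cc),
                )
            )
    pct = 100.0 * float(fg.sum()) / float(dom.sum())
    return ParticleSet(particles=particles, percent_positive_pixels=pct)


def measure_axon_length(
    vertices: Sequence[tuple[float, float]], pixel_size_xy: float
) -> float:
    """Polyline length in micrometres: summed Euclidean segment lengths
    times the pixel size. Used for CaP motor-axon outgrowth traces."""
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least 2 (row, col) vertices")
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * pixel_size_xy)


def quantify_nmj(
    pair: TwoChannelStack,
    slice_range: tuple[int, int] | None = None,
    roi: RectROI | None = None,
    min_area_pixels: int = 0,
    larva_id: str = "",
) -> NMJMetrics:
    """Full per-larva NMJ quantification.

    Pipeline: max Z projection per channel -> per-channel Kapur
    threshold -> intensity mask -> optional ROI crop -> masked Manders
    M1/M2 and Pearson -> per-channel particle analysis. Deterministic
    for a fixed input. Undefined coefficients propagate as NaN.
    """
    stage = "projection"
    try:
        red_proj = max_z_projection(pair.red, slice_range)
        green_proj = max_z_projection(pair.green, slice_range)

        stage = "threshold"
        t_red = threshold_projection(red_proj)
        t_green = threshold_projection(green_proj)

        stage = "mask"
        red_mask, red_masked = apply_threshold_mask(red_proj, t_red)
        green_mask, green_masked = apply_threshold_mask(green_proj, t_green)

        if roi is not None:
            stage = "crop"
            red_masked = crop_roi(red_masked, roi)
            green_masked = crop_roi(green_masked, roi)
            red_mask = BinaryMask(red_mask.pixels, t_red, domain=red_masked.domain)
            green_mask = BinaryMask(green_mask.pixels, t_green, domain=green_masked.domain)

        stage = "colocalization"
        try:
            m1, m2 = manders_coefficients(red_masked, green_masked)
        except UndefinedCoefficientError:
            m1 = m2 = float("nan")
        try:
            pearson = pearson_coefficient(red_masked, green_masked)
        except UndefinedCoefficientError:
            pearson = float("nan")

        stage = "particles"
        cal = pair.red.pixel_size_xy
        red_particles = analyze_particles(red_mask, cal, min_area_pixels)
        green_particles = analyze_particles(green_mask, cal, min_area_pixels)
    except (ValueError, IndexError) as err:
        raise type(err)(f"[{stage}] {err}") from err

    return NMJMetrics(
        larva_id=larva_id,
        pct_red=red_particles.percent_positive_pixels,
        pct_green=green_particles.percent_positive_pixels,
        n_red_particles=red_particles.n_particles,
        n_green_particles=green_particles.n_particles,
        mean_green_particle_area_um2=green_particles.mean_area_um2,
        M1=m1,
        M2=m2,
        pearson=pearson,
    )
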