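# Methods

## Imaging pipeline

The imaging analysis reproduces the classical ImageJ/Fiji workflow for
NMJ marker colocalization on 2D projections.

**Projection.** Maximum-intensity Z projection over a half-open slice
window `[start, stop)`. Coordinates are 0-based `(row, col)` with row
increasing downward. Projections carry an *analysis domain* — a boolean
mask of pixels that participate in downstream statistics.

**Thresholding.** Kapur–Sahoo–Wong maximum entropy: choose the level
`t` maximizing the sum of Shannon entropies of the gray-level
distribution below (`<= t`) and above (`> t`) the candidate, with empty
bins contributing zero. Ties break to the smallest `t` (deterministic).
A histogram with fewer than two populated bins is rejected as
degenerate — no threshold separates anything. 16-bit images are binned
to 256 levels by min–max linear scaling before thresholding, and the
chosen level is mapped back to the native intensity scale; this mirrors
the common tool behaviour and keeps the search space at 256 candidates.
The exact binning inside other implementations varies; ours is stated
here so results are reproducible.

**Masking and ROI.** The binary mask keeps pixels strictly above
threshold; the masked projection retains original intensities there and
zero elsewhere. Rectangular ROIs either retain or exclude a region; in
both cases affected pixels are removed from the analysis domain rather
than zeroed, because zeroing would silently inflate the denominator of
percentage metrics. An empty domain after cropping is an error.

**Colocalization.** Manders M1/M2 are computed on the masked channels
with an effective zero threshold (the thresholding already happened
upstream): M1 is the fraction of total red intensity on green-positive
pixels, M2 symmetrically. A channel that is empty after masking makes
the corresponding coefficient undefined; it propagates as NaN (reported
missing, excluded from group means) and is never imputed as zero.
Pearson is the standard product-moment correlation over in-domain pixel
pairs, undefined (NaN) for zero variance. Swap symmetry
`M1(R, G) = M2(G, R)` and invariance under joint positive rescaling are
enforced by property tests.

**Particles.** 8-connected components of the binary mask restricted to
the domain (`scipy.ndimage.label` with a full 3x3 structure — the
common tool default), with an optional minimum-area filter (default 0:
no filter, as none is stated for the original workflow). Percent
positive pixels = 100 x true-in-domain / domain size, so it is
invariant to any monotone intensity rescaling that preserves the mask.
Areas are converted to um^2 with the square of the pixel size.

**Pipeline order.** `quantify_nmj` runs projection -> per-channel
threshold -> mask -> ROI crop -> Manders/Pearson -> particles. The
threshold histogram is computed before cropping; with the ROI supplied
up front the difference is small, and this order matches the masked
workflow the pipeline emulates.

**Axon length.** Sum of Euclidean polyline segment lengths times the
pixel size; at least two vertices required.

## Behaviour pipeline

Larvae swim in a rectangular trough (long axis = y); after a baseline
period a bar animates under one half. **percent_down**: for every frame
in the stimulus window, the fraction of tracked larvae in the
unstimulated half; the metric is 100x the mean over frames. A larva
exactly on the midline counts as in the *stimulated* half — the
conservative choice, biasing against detecting avoidance. The baseline
period is excluded from the metric. **swim_speed**: per larva, summed
inter-frame displacements divided by elapsed time, over all frames
unless a window is configured (the group value averages per larva, not
per frame — a stated convention). Lost-tracking frames are skipped
pairwise (displacement over the actual time gap); a larva with under
two usable frames, or missing more than half the expected frames, is
dropped with a logged warning. Group summaries report mean and standard
error (sample SD / sqrt(n)); the s.e. of a singleton group is reported
missing.

## Statistics

**Modified Thompson tau.** With sample size n, sample SD s and the
two-sided Student quantile t at alpha/2 on n-2 degrees of freedom,

    tau = t (n-1) / (sqrt(n) sqrt(n-2+t^2)).

Iteratively, the single point with the largest absolute deviation from
the mean is removed if its deviation strictly exceeds tau*s; the rule
repeats on the reduced sample until no removal occurs or fewer than
three points remain. A constant sample never loses points (s = 0 and
the comparison is strict). Rejection runs per treatment group,
before group means and standard errors, with alpha = 0.05 by default.

**t-test.** Student's two-sample t with pooled variance (not Welch):
the plain "t-test" convention of this literature, and stated in output
metadata. One-tailed direction is supplied by the caller
(`greater`/`less` for mean(a) vs mean(b)). Degenerate zero-variance
input yields the limit p-values (1 for equal means, 0 otherwise,
logged). The implementation is the textbook formula; an independent
reference implementation serves as the oracle in tests, and a 10,000-
replicate null simulation checks type-I calibration at alpha = 0.05.

## Synthetic data

**Confocal stacks.** Defaults emulate a ~10-slice acquisition of
lateral trunk muscle at 1.0 um z-step and 0.3 um/px: an 8 x 96 x 96
volume with 12 green (postsynaptic-cluster-like) Gaussian blobs of
radius 1.0 um and 30 red (presynaptic-punctum-like) blobs of radius
0.4 um, peak 150 on 8 bits over a background of 10, Gaussian PSF of
sigma 0.25 um, Poisson shot noise on the pre-background signal and
additive Gaussian read noise (SD 2) after — a simple, controllable and
standard fluorescence model. `round(coloc_fraction * n_red)` red puncta
are centred inside randomly chosen green clusters (jitter a quarter of
the cluster radius, so the punctum's thresholded footprint stays inside
its host's); the rest are rejection-sampled clear of every green
cluster and of each other. Because analysis happens on a 2D max
projection, all separation constraints are enforced on the projected
xy distance — 3D separation does not prevent overlap after projection.
Rendered blob sigmas are floored at the voxel scale (0.6 slice, 0.5 px):
an optical section cannot resolve sub-voxel structure, and narrower
rendering aliases (a punctum centred between slice planes would
vanish). Treatment effects enter only as caller-supplied parameter
shifts.

What the generator does *not* emulate: myotome/myoseptum anatomy,
spatially varying background, chromatic offsets between channels,
photobleaching, or depth-dependent PSF broadening. Passing recovery
tests therefore shows the pipeline is correct and sensitive under a
clean punctate regime, not that it is robust to every real-world
artefact; the ROI mechanism exists precisely because real images need
manual exclusion of structures the simulator does not render.

**Trajectories.** Each of 50 larvae performs a reflected persistent
random walk: constant speed 3.0 mm/s (cruising speed of actively
swimming 4-5 dpf larvae; it also mixes the trough occupancy well within
the stimulus window), per-step heading noise SD 0.5 rad, 1 s frames, in
a 70 x 10 mm trough, 900 s baseline then 600 s stimulus. Walls reflect
both position and heading (a position-only fold lets larvae hug walls,
which distorts occupancy and speed statistics). During the stimulus,
each larva *currently in the stimulated half* is redirected toward the
other half with per-frame probability `p_avoid` (plus 0.3 rad of
angular jitter). Conditioning the response on exposure to the bar is a
deliberate design choice: an unconditional per-frame redirect saturates
occupancy near 99% for any p_avoid >= 0.25, destroying the
dose-response gradation, whereas the conditional response yields a
graded curve (about 50 / 86 / 93 / 96 / 97 % down across p_avoid = 0,
0.25, 0.5, 0.75, 1) while preserving the endpoints (no response at 0,
near-total avoidance at 1). Real larvae burst-swim rather than cruising
at constant speed, startle, and interact; none of that is modelled.

## Numerical choices and edge cases

- Kapur tie-break: smallest argmax, with a 1e-12 slack so float jitter
  cannot flip ties.
- Threshold semantics: mask keeps pixels strictly greater than `t`;
  the minimum legal threshold 0 keeps all positive pixels.
- Undefined coefficients are NaN, never 0; group statistics drop NaNs.
- Speed uses actual time gaps, so irregular frame intervals are handled.
- All simulators take integer seeds and are bit-reproducible; the
  end-to-end driver derives per-stage seeds from the master seed.

## Problem sizes

The test suite and the acceptance script use 1,000 histograms for the
threshold oracle, 100 random masks for the particle oracle, 10,000
null replicates for t-test calibration, 20 seeds per point on a
5-point colocalization grid (96 x 96 x 8 stacks), and 10-20 seeds per
point for the behavioural dose-response (50 larvae, 1,500 frames) —
sizes at which every Monte-Carlo check is stable across seeds.
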