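# Methods

This note records the quantitative procedures `gliaquant` implements, the
numerical choices made where the underlying publications of this field are
silent, and what the synthetic-data generators do and do not emulate.

## Coordinate and unit conventions

Images use 0-based `(row, col)` indexing with rows increasing downward.
All physical quantities are carried in µm (lateral calibration, areas,
radii) and minutes (frame intervals); conversion to pixels happens only at
the operation boundary. Thresholds are always applied strictly
(`pixel > threshold`). Read/write round-trips through multi-page TIFF are
bit-exact for integer dtypes.

## Sholl analysis

A Sholl profile counts, for each sampling radius, the crossings of the
binarized arbor with the circle of that radius centered on the soma. On a
discrete image a crossing is defined as a **maximal 8-connected run of
foreground pixels along the midpoint-rasterized circle**, with runs
spanning the 0°/360° seam merged. This is the standard discrete definition;
it is testable against an independent oracle (connected components of
foreground circle pixels) and against analytic ground truth (a straight ray
of length L crosses every circle of radius < L exactly once). Circle pixels
falling outside the image count as background. Profiles are computed on 2D
z-projections, not in 3D; the default figure granularity is a 5-µm radius
step. Cells clipped by the image border should be excluded by the user
(only whole arbors give meaningful profiles).

The artefact filter applied after thresholding removes connected components
smaller than a configurable minimum size (`min_artifact_size`, default 0 =
off). The filter criterion is a package choice: the upstream literature
states that artefacts were removed but not how.

## Time-lapse motility

Projected frames are registered (below), thresholded, and consecutive
binary masks compared per pixel: *stable* (both frames), *extended* (second
only), *retracted* (first only). Per overlay,

- motility index = (extended + retracted) / stable,
- extension index = extended / stable, retraction index = retracted / stable,

each averaged across the 11 overlays of a 12-frame session. Indices are
per-interval quantities (change over one 4- or 5-min interval), not
normalized per minute. Two cadences are in common use and both are plain
parameters: 5 min × 12 frames and 4 min × 12 frames.

The stability index of an overlay pair is |extension pixels of overlay k
that are stable in overlay k+1| / |extension pixels of overlay k|; the
instability index is the analogous stable→retracted fraction. Pairs with an
empty denominator yield NaN and are omitted from averages (never counted as
zero). The module reports both per-pair values and their average across all
defined pairs. The stability histogram follows pixels from their first
extension→stable transition and reports the fraction still continuously
stable after 1, 2, … subsequent overlays; pixels stable for the entire
session (somas, primary branches) are excluded, and each offset's
denominator includes only pixels observable at that offset.

An overlay with zero stable pixels makes the motility ratio undefined; the
pipeline raises an error naming the interval rather than returning
infinity.

### Movie thresholding

One threshold is derived from the first frame and reused for every frame of
a movie, so that index differences between intervals reflect morphology
rather than threshold drift (per-frame thresholding is available as an
option). The default method is **IsoData** (iterative intermeans — the
midpoint of the background and foreground class means, and the default
auto-threshold of ImageJ). The triangle method is deliberately *not* the
default here: triangle places its cut at the shoulder of the background
peak (roughly 2.5–3 background standard deviations), which is the right
behaviour when segmenting dim objects against a dominant background (see
colocalization below) but lets the extreme tail of the background noise
into the mask. For change classification every stray background pixel
appears once as a spurious extension and once as a spurious retraction, so
a cut deep in the background–foreground gap is required; IsoData provides
it. Both methods and a user-fixed value are selectable.

### Registration

Lateral motion is corrected by integer-pixel phase cross-correlation;
subpixel precision is unnecessary because all downstream analysis operates
on thresholded pixels. Consecutive frames are correlated and the shifts
composed (robust when the scene itself remodels over the session; direct
correlation of every frame against the reference is available as
`strategy="fixed"`). Shifts are undone with a circular shift, and pixels
wrapped in from the opposite border are recorded in a validity mask that
every pixel count honours — border pixels can therefore never inflate
extension or retraction counts.

Each correlation also yields a confidence measure: the correlation peak
divided by the largest value outside a 5×5 exclusion zone around it. Ratios
near 1 (default flag threshold 1.5) indicate the estimate is not
distinguished from the correlation background (e.g. featureless or
excessively noisy frames). The flag is reported, not enforced; deciding
whether a session is usable remains with the analyst.

## Laser-ablation response

R(t) = (Rx(t) − Rx(0)) / Ry(0), with Rx the thresholded foreground pixel
count inside the **full disc** of the inner radius X (~40 µm) and Ry(0) the
annulus X < r ≤ Y (~80 µm) at the first timepoint. The disc (rather than a
thin ring at X) is used because processes entering the inner compartment
accumulate there. A small core around the lesion itself (default 5 µm) is
excluded from Rx so saturated or damaged lesion pixels are never counted.
Disc membership uses center-of-pixel distance in µm. Ry(0) = 0 raises
(the normalizer is undefined), as does geometry extending beyond the image.
Group curves are summarized as per-timepoint mean ± s.e.m.; inferential
statistics are left to standard tools.

## Engulfment (two-channel colocalization)

Each channel is smoothed (Gaussian, default σ = 1 px; the source procedure
states smoothing without parameters), thresholded with the **triangle
method**, and the binary stacks multiplied. Connected components of the
product larger than one pixel — implemented as size ≥ 2, reading "larger
than 1 pixel" strictly — are counted as internalized puncta, using
26-connectivity across z so a punctum spanning planes counts once
(8-connectivity in 2D). Density is the count divided by the total
foreground area of the cell channel; the summed per-plane area is the
default normalizer (the projected area is an alternative the caller can
compute from a projection).

The triangle threshold itself: the line is drawn from the histogram peak to
the farthest non-empty tail bin (the longer tail side, so a left-sided tail
mirrors the geometry), and the selected bin maximizes the perpendicular
distance between histogram and line. Ties break toward the peak — the more
inclusive mask. Constant images have no definable threshold; binarization
then returns an empty mask with a logged warning.

## Intrinsic-signal imaging and ODI

Each pixel's time series is reduced to the amplitude of its discrete
Fourier component at the bin nearest the stimulus repetition frequency,
normalized as 2·|X[k]|/N so a pure sinusoid of amplitude A reports A
(guarded by a Parseval-style test). The stimulus frequency must be below
Nyquist and off the DC bin; it is a required user parameter, since it
depends on screen geometry and sweep speed of the particular rig. Optional
per-pixel linear detrending (hemodynamic drift) is off by default. Phase
maps fall out of the same computation and are exposed, but no retinotopic
analysis is built on them.

Eye responses average the ROI over both stimulus directions;
ODI = (contra − ipsi)/(contra + ipsi), in [−1, 1], positive = contralateral
bias. The binocular-zone ROI is supplied by the user; a fallback selects
pixels above a configurable fraction (default 0.5) of the maximum mean
amplitude.

## EM event statistics

Event counts per microglial process (synaptic-cleft contacts, element
contacts, inclusions) are divided by the process area in µm², since larger
processes meet more neuropil. Densities are averaged across processes
within each animal (typically 50–88 processes), and groups are summarized
as mean ± s.e.m. across **animals** — the unit of replication throughout.

A single, non-iterated pass of Grubbs' test may remove one outlier per
category before aggregation (tiny traced processes produce huge ratios):
G = max|xᵢ − x̄|/s against G_crit = ((n−1)/√n)·√(t²/(n−2+t²)) with t the
α/(2n) Student-t quantile at n−2 df. Defaults are two-sided, α = 0.05
(neither sidedness nor level is stated upstream; a one-sided large-value
variant is a flag, which arguably matches the motivation better). Zero
variance removes nothing; ties on |deviation| remove the first occurrence.
The test is applied per category across the dataset's per-process
densities, masking only the flagged category of the flagged process.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed), and every piece
of recorded ground truth equals what brute-force recomputation from the
generated arrays yields — this is asserted in the test suite.

- **Arbors** are somata with 1-px-wide, 4-connected radial rays (a
  4-connected line cannot slip diagonally through an 8-connected sampling
  circle, keeping crossing counts unambiguous). Branch lengths avoid a
  ±2 px band around every sampling radius so the analytic crossing count is
  exact after rasterization. Branch angles are spaced so runs cannot merge
  on the innermost circle.
- **Time-lapse movies** evolve an arbor tip-wise: retraction removes
  foreground pixels with ≤1 foreground neighbour, extension adds background
  4-neighbours of the foreground, never re-adding a pixel removed in the
  same interval; the exact added/removed sets are recorded per interval.
  Default cadence is 12 frames at 4-min intervals, matching common
  in-vivo protocols.
- **Ablation movies** translate rigid 1-px radial segments toward the
  lesion at a fixed rate; they park fully inside the inner compartment,
  clear of the excluded core, so foreground only moves inward and the
  planted response curve is non-decreasing. Total foreground is constant:
  chemotactic translocation, not growth.
- **Puncta images** plant compact multi-pixel blobs ≥ 4 px apart, wholly
  inside the cell mask, wholly outside it, or overlapping it by exactly one
  pixel (to exercise the >1-pixel rule).
- **iOS sessions** are DC + A·sin(2πft + φ) + Gaussian noise per pixel,
  with the duration constrained to whole stimulus periods so the planted
  amplitude sits on an exact FFT bin.
- **Event tables** draw process areas uniformly and counts from
  Poisson(density × area), the natural model for sparse event counts.

Noisy grayscale variants add i.i.d. Gaussian noise on a baseline offset of
30 (a detector-style pedestal; with a zero background, clipping at the
dtype floor piles half the noise mass into the zero bin and degenerates
every histogram-based auto-threshold). Noiseless binary content is 0/255.

Deliberately **not** emulated: optics (PSF convolution, photon shot noise),
3D arbor geometry (all downstream math operates on 2D projections),
process-width variation, real motion artefacts beyond rigid translation,
and hemodynamics. Passing tests therefore demonstrate correctness of the
measurement code under controlled conditions, not robustness to every
property of real acquisitions — in particular, real movies need a quality
judgement (the registration confidence flag) that synthetic ones never
trigger.

## Problem sizes

The test suite and `scripts/acceptance.py` run on deliberately small
instances — arbors of ≤ 8 branches within ~60–80 px images, 12-frame
movies, 50-image puncta batches, 8×8×720-sample iOS sessions, event tables
up to 1000 processes × 5 animals × 2 groups — chosen so the full
verification cycle completes in seconds while every statistical check
retains comfortable margins (e.g. the planted 2× EM density ratio is
recovered within ~1% at these sizes against a 10% criterion).
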