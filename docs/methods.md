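# Methods

## The measurement problem

Activity of the WNT/planar-cell-polarity (PCP) pathway in single
migrating B lymphocytes is read out two ways: (i) migration and
chemotaxis statistics of tracked cells, and (ii) the asymmetric
subcellular localisation of fluorescent PCP markers, summarised as the
trailing/leading intensity ratio R. `pcpmig` implements both readouts
and, because the underlying live-cell movies are not publicly
deposited, couples them to a generative model so every stage can be
tested against known ground truth.

## Motility model

Each cell is a biased persistent random walk in the image plane
(x right, y down, physical units µm; angles counterclockwise from +x
in the mathematical convention). At each frame interval `dt`:

1. The heading is redrawn from a von Mises distribution centred on the
   direction of the resultant vector
   `v = persistence_kappa · u(θ_prev) + bias_kappa · u(θ_source)`,
   with concentration `|v|`; `u(·)` is the unit vector of an angle and
   `θ_source` points from the cell to the chemokine source. One
   parameter per effect: `bias_kappa = 0` reduces to an unbiased
   persistent walk, both zero to an isotropic walk. The infinite-
   persistence limit (`persistence_kappa = inf`, `bias_kappa = 0`) is
   implemented as a deterministic heading.
2. The step length is gamma distributed with mean `speed_mean · dt`
   and sd `speed_sd · dt` (non-negative, two-moment control;
   deterministic when `speed_sd = 0`).
3. `arrested = True` zeroes the step while freezing the heading and
   hence the polarity axis — the cytochalasin phenotype in which cells
   round up and stop but the marker stays polarised.

The polarity axis is `heading + 180°` for trailing-enriched markers
(`polarity_sign = +1`; VANGL2/ROR2-like) and `heading` for
leading-enriched ones (DVL3/β-arrestin-like).

### Condition presets

| condition    | speed_mean (µm/min) | speed_sd | persistence κ | bias κ | A   | arrested |
|--------------|---------------------|----------|---------------|--------|-----|----------|
| control      | 4                   | 2        | 2             | 0      | 0.3 | no       |
| ccl19        | 7                   | 2        | 2             | 2      | 0.3 | no       |
| ccl19_ck1i   | 2                   | 1        | 2             | 0      | 0   | no       |
| cytochalasin | (arrest)            | —        | —             | 0      | 0.3 | yes      |

The magnitudes are simulator conventions, not measured values: the
source experiments report only the qualitative ordering (chemokine
increases track length, speed and straightness; CK1 inhibition reduces
all four and abolishes both directional bias and marker asymmetry).
The speeds are consistent with cells 15–20 µm in diameter covering
their own size in under 4 minutes, and `dt = 30 s` with the 20–40 s
acquisition interval of the imaging setup the simulator emulates.

## Rendering

Cells are rendered at their true centroids into a two-channel
time-lapse stack (T×C×H×W): the tracker channel as a filled disc of
radius `cell_radius` (default 8 µm), the polarity channel as a
perimeter ring whose intensity at perimeter angle φ is
`base_intensity · (1 + A·cos(φ − φ_peak))`. Averaging the modulation
over the half-rings gives mean intensities ∝ 1 ± 2A/π, so the ideal
trailing/leading ratio is `(1 + 2A/π)/(1 − 2A/π)` — the closed form
used (and confirmed by quadrature in the tests) to validate the
polarity measurement to within pixelation error. Optional noise is
Poisson shot noise on the noise-free image plus additive Gaussian read
noise, clipped at zero, driven by a noise seed independent of the
trajectory seed so tests can vary noise at fixed geometry. Stacks are
written as one 16-bit multi-page TIFF per channel with a plain-text
sidecar carrying `pixel_size_um` and `dt_s`. Cells leaving the field
are clipped silently; the track tables keep them.

Not modelled, deliberately: photobleaching, a z-dimension, cell
division, and cell–cell collision/exclusion. The last one matters for
interpretation: two simulated cells may overlap, and their merged
masks then corrupt detection and polarity readouts. Analyses of
arrested (never-moving) cells therefore place cells on non-overlapping
grids; moving-cell analyses accept the occasional merge as realistic
clutter.

## Detection and tracking

Detection thresholds the tracker channel per frame (Otsu by default),
labels 8-connected components, discards those below `min_area`
(default 20 µm²) and reports intensity-weighted centroids in µm.
Linking is greedy nearest-neighbour: candidate (track, detection)
pairs are processed in ascending distance, rejecting pairs beyond
`max_disp · (gap + 1)`; a track may bridge up to `max_gap` missing
frames; tracks shorter than `min_track_len` are dropped. Distance ties
break on the lexicographically lowest (frame, label) keys and input
rows are canonically sorted first, so the result is invariant to
detection order. Greedy rather than globally optimal assignment is a
design choice: in the sparse-cell regime it is near-optimal (tests
hold it within 10% of the exhaustively enumerated optimum on small
instances, and it recovers ground truth exactly on well-separated
cells) and it is simple enough to reason about.

Headings along a track are the normalised displacement from the
nearest preceding sample at least `min_step = 1 µm` away, reusing the
last valid heading when the cell has not moved that far — sub-pixel
jitter must not flip the leading/trailing split. A cell that never
moved has no heading; its polarity measurement is skipped unless the
caller supplies axes explicitly (the arrest analysis passes the frozen
ground-truth axes, standing in for the pre-arrest heading a real
experiment would use).

## Migration statistics

The four per-track parameters are computed exactly as defined in the
README. `max_speed` uses single-step speeds; a step spanning a bridged
detection gap divides by the full elapsed time so gaps never inflate
it. Straightness of a zero-length track is NaN and excluded from
medians (0/0 is undefined). Group comparison uses the Kruskal–Wallis
rank test with tie correction (scipy), with completely tied data
defined to give H = 0, p = 1. Metrics are invariant under rotation and
translation and scale linearly (straightness: not at all) with the
coordinates — tested as exact properties.

## Directionality

Per track the migration direction is the start-to-end displacement
(matching how direction arrows are drawn in chemotaxis figures), not a
step-averaged heading. The deviation angle is the signed angle from
the track-start→source direction to the migration direction, positive
counterclockwise in the mathematical frame, wrapped to (−180°, 180°];
the compass-style display convention with the source at 0° up is a
plotting transformation only. Tracks displacing less than
`min_displacement = 2 µm` are excluded and counted — the direction of
a near-stationary cell is noise.

The Rayleigh test uses z = n·R̄² with the second-order correction
`p = exp(−z)·[1 + (2z − z²)/(4n) − (24z − 132z² + 76z³ − 9z⁴)/(288n²)]`,
clipped to [1e−12, 1] because the polynomial goes non-positive at
large z. Which p approximation the original commercial software used
is not stated anywhere; this standard correction is validated two
ways: against `pingouin.circ_rayleigh` (z exact, p within 0.01) and
against a 100,000-sample Monte-Carlo null (within ±0.005 absolute for
n ∈ {10, 30, 50} over p ∈ [0.001, 0.2]). It requires n ≥ 5.

## Polarity ratio

The cell mask (or, with `ring_only`, its outer membrane band) is split
by the line through the centroid perpendicular to the heading; pixels
exactly on the line alternate deterministically onto the smaller half,
so symmetric masks split to within one pixel of equal area. This
operationalises "two regions of interest of the same size" without any
operator-placed ROI. R is the ratio of mean marker intensities,
trailing over leading; a non-positive leading mean marks the
measurement invalid (never ±inf). R is invariant under multiplicative
intensity rescaling but not under additive offsets, so an optional
constant-background subtraction (mean of the darkest 5% of pixels
outside all masks) can be applied first; it is off by default on
noise-free synthetic data. Frames where the mask touches the image
border are invalid — truncated halves bias the ratio. The per-cell
summary is the median ratio over valid frames.

## Dose–response

`fit_dose_response` fits `bottom + (top − bottom)/(1 + (d/EC50)^h)` by
Levenberg–Marquardt least squares in (top, bottom, log EC50, h), with
the deterministic initialiser top = max response, bottom = min
response, EC50 = dose nearest the half-range crossing, h = 1. Fewer
than four distinct doses, non-positive doses and constant responses
are rejected (the slope is unidentifiable in the last case).
Generate-then-fit recovers noise-free parameters to at least four
significant figures and, at 5% noise with 8 log-spaced doses × 3
replicates, the median relative EC50 error over 100 seeds is below
10%.

## Problem sizes and numerical conventions

The study-scale analyses use 50 cells × 60 frames per condition
(dt = 30 s, 30 min of imaging — matching the duration of one imaging
period in the emulated experiments) and 200 cells per condition for
the ordinal comparison of the four metrics; rendering-based analyses
use 20 cells × 20 frames on 250×250 px fields at 1 µm/px. Pixel
centres sit at integer coordinates (0-based); all randomness flows
from explicit integer seeds (trajectory and noise streams separate),
and identical seeds give bit-identical tracks, stacks and reports.

## What passing tests do and do not show

The generator reproduces the *phenomenology* the methodology was built
to quantify — directional bias, its loss under CK1 inhibition, arrest
with retained polarity, trailing-edge enrichment of tunable amplitude —
so green tests demonstrate that the measurement pipeline recovers
known ground truth under realistic geometry, sampling and noise. They
do not validate the biological magnitudes: per-condition speeds, bias
strengths and the A = 0.3 modulation are conventions, real cells
change shape rather than staying discs, markers are not pure perimeter
rings, and backgrounds are not constant. Conclusions about real movies
still require the usual controls.
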