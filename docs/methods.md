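# Methods

## Scope

`colonytrack` quantifies collective cell migration on aligned-fiber
substrates from two perspectives: the whole colony (area, perimeter,
circularity, center of mass) and the single cells inside it (straightness,
speed, fiber-relative direction angles), stratified by the colony's leader
percentage N — the fraction of mesenchymal, EMT-induced "leader" cells mixed
into an epithelial "follower" population. The package consumes nucleus-track
tables (TrackMate-style exports) and binarized colony masks produced
upstream; it does not segment or track raw fluorescence images. Because no
public time-lapse dataset exists for this design, the package includes an
agent-based simulator that generates track sets and mask stacks with the
qualitative structure such experiments report, so the entire analysis chain
is testable end to end.

## Colony-level metrics

For a labeled colony mask with pixel size `p` (µm/px), the area is
S = (pixel count)·p² and the perimeter P is the length of the sub-pixel
marching-squares contour at iso-level 0.5, summed over all boundary
contours of the label (internal holes included), scaled by `p`. The raw
0.5-level contour of a binary image staircases along the pixel grid and
overestimates a smooth boundary's length by ≈7%; we therefore smooth each
closed contour with a short periodic moving average (5 vertices) before
measuring it, which brings a rasterized disk's perimeter within 0.4% of
2πr at r = 50 px. Pixel-edge counting was rejected because it caps disk
circularity near 0.79, contradicting the defining property that a circle
scores 1.

Circularity is 4πS/P²: 1 for a circle, tending to 0 as the colony
elongates. With the smoothed-contour perimeter, rasterized disks score
0.992–0.993 at r ≥ 20 px, and the value is invariant under pixel-size
rescaling and stable (<0.2%) under rotation of an elongated ellipse.

The colony's center of mass at a frame is the unweighted mean of all cell
positions recorded at that exact frame; cells in tracking gaps are excluded
rather than interpolated, because no interpolation policy can be validated
without ground truth. Centroid paths are rebased so the first computable
frame sits at (0, 0). Colonies that fragment are still summarized by the
all-cell centroid; for mask-based shape time-series the pipeline follows the
largest connected component per frame (per-fragment analysis is out of
scope).

The start-vs-end circularity comparison is a paired two-sided test on
per-colony differences. The default is the Wilcoxon signed-rank test —
robust at the small colony counts typical of these experiments — with a
paired t-test available by configuration; all-zero differences report p = 1
by convention. At least three colonies are required.

## Single-cell metrics

For a track with positions x₀…x_n (gaps bridged by straight segments):

* total path length d_total = Σ|x_{k+1} − x_k|;
* net displacement d_euclid = |x_n − x₀|;
* straightness = d_euclid / d_total ∈ (0, 1]; a stationary track is 0/0 and
  reports NaN, excluded from group means with an explicit count rather than
  assigned 0 or 1;
* mean speed = d_total / elapsed time (µm/h), using the recorded frame span
  so gapped tracks are handled consistently; net-displacement speed is also
  exported because either reading of "velocity" is defensible;
* direction angles: for each nonzero frame-to-frame step, the unsigned
  angle in [0°, 180°] between the step and the axis perpendicular to the
  fibers (fibers along y → reference +x). 90° is motion along the fiber.
  Angles are per step, not per whole track, so each cell contributes many
  angles to a pooled rose plot; the whole-track angle is exposed as a
  secondary statistic. The fold keeps 0° and 180° distinct so a bimodal
  perpendicular pattern remains visible; its presence is flagged by a large
  SD around an apparently central mean.

Rose-plot histograms use 10° bins over [0°, 180°] (the final bin closed) and
report the arithmetic mean and SD of the folded angles; the arithmetic mean
is what makes "mean angle closest to 90°" a meaningful statement for
fiber-guided motion. Group summaries report mean ± sample SD per
condition × phenotype with cell counts and undefined-metric counts. In the
pipeline, cells tracked for less than 25% of the colony's frame span
(configurable) are excluded from group summaries, because short tracks bias
straightness upward; they remain in the per-cell table, flagged.

Between-condition contrasts use Welch's two-sample t-test with a 95% CI on
the difference of per-cell means. The experimental literature this design
follows reports mean ± SD without naming tests, so the contrast layer is
explicitly exploratory and labeled as such in its output.

## The leader–follower simulator

Each of `n_cells` (default 50) cells performs a persistent biased random
walk at 15-min steps for 24 h (97 frames), starting from a hexagonal packing
with 15 µm spacing. Exactly round(n_cells × leader_fraction) cells are
leaders, assigned uniformly at random. One global PCG64 stream drives all
randomness; identical (parameters, seed) reproduce tracks bit-exactly.

**Heading dynamics.** Cell i keeps a unit heading h_i updated each frame as

    h_i ← normalize(p·h_i + (1 − p)·η_i + c_i·m̂_i)

where η_i is a contact-guidance cue drawn from a von Mises distribution
concentrated on the cell's *current* ± direction along the fiber axis
(concentration κ). Conditioning the cue on the cell's polarity sign lets
guidance be strong and recovery after a perturbation fast without the
heading constantly flipping between +y and −y; κ = 0 recovers the exactly
isotropic limit. Followers default to κ = 4, p = 0.5 (straight, fiber-bound
motion); leaders to κ = 0.3, p = 0.5 (fast, weakly guided wandering —
mesenchymal cells largely ignore contact guidance, which is what drives the
direction-angle spread in leader-rich colonies).

The m̂_i term applies only to followers: the unit consensus direction of
leaders within `coupling_radius` (25 µm), weighted by
c_i = heading_coupling · βL/(1 + βL) with L the crowding measure below.
One nearby leader barely deflects a follower; a leader-rich neighborhood
issues conflicting cues that overwhelm contact guidance. This is the
mechanism behind both the loss of straightness and the flattening of the
90° direction-angle peak as N grows.

**Speed and displacement.** Follower i also receives an alignment velocity
A_i = α_eff·M_i (M_i the mean heading of leaders within the coupling
radius) and an intrinsic speed boost `speed_gain`·|A_i|, with

    α_eff = α / (1 + β·L),   L = 10 · (local leader fraction)

measured within `crowding_radius` (50 µm; the factor 10 expresses the
fraction as an effective count in a ~10-cell contact neighborhood, making
the mechanism independent of colony size). α_eff is the crowding-diluted
coupling: a minority of leaders enhances follower motility, while a leader
majority — "too many leaders" — dilutes the guidance because there is no
single front to follow. Displacement per frame is

    Δx_i = (s_i·h_i + A_i + adhesion_i)·Δt

with s_i the intrinsic speed (8 µm/h followers, 26 µm/h leaders by
default).

**Adhesion.** Neighbors within `adhesion_radius` (25 µm) exert a spring
restoring velocity k_i·(mean over neighbors of extension·unit vector), with
rest length 15 µm; inside the rest length the spring pushes (approximate
volume exclusion — no hard-core collision resolution). The mean (rather
than sum) over neighbors bounds the restoring velocity independently of the
coordination number, keeping the explicit 15-min update stable for
k·Δt < 1; summed springs oscillate violently once k·(neighbor count)·Δt
exceeds 1. Followers adhere strongly (k = 0.15 h⁻¹), leaders weakly
(0.03 h⁻¹), so leader-rich colonies loosen and disperse.

With κ = p = α = adhesion = 0 the model reduces exactly to an unbiased
fixed-step-length 2-D random walk, for which the expected straightness of an
n-step track is √(πn)/2/n (Rayleigh mean); this closed form anchors the
stochastic tests.

**Calibration.** Defaults live in `_defaults.cfg` (flat key = value, units
in key names) and were calibrated so that, averaged over 10 seeds at the
default colony size: a follower-only colony migrates at ≈ 8 µm/h; follower
speed peaks at ≈ 14–15 µm/h at N = 40–60 and declines beyond; pooled
straightness decreases strictly from ≈ 0.94 (N = 0) to ≈ 0.21 (N = 100);
the 80–100° share of pooled step angles decreases strictly from ≈ 0.43 to
≈ 0.13; and colony circularity at 24 h falls below its 0 h value for
N ∈ {20, 40}. Setting α = 0 removes the N-dependence of follower speed
(spread < 0.1% across N), confirming that the leader–follower coupling, not
a side effect, carries the mixing-ratio phenotype.

**Mask rendering.** Masks are the union of rasterized disks of
`cell_radius` (10 µm) at each cell position on a `pixel_size` (2 µm) grid,
labeled by 8-connected component; the field extent is computed from the
tracks with a margin, or validated against an explicit extent.

## What the simulator does and does not emulate

It reproduces the *qualitative* interaction structure: fiber-guided
persistent motion, epithelial cohesion, highly migratory weakly guided
leaders, follower enhancement by a leader minority and its suppression by a
leader majority, colony elongation along the fiber axis. It does not model
proliferation or division, EMT signaling dynamics, 3-D fiber geometry,
traction forces, or realistic nucleus shapes; rendered masks are unions of
disks, not deformable cells, so absolute areas and perimeters of simulated
colonies are stylized. Passing tests therefore demonstrate that the
analysis chain measures these phenomena correctly when present, not that
the simulator's absolute magnitudes match any particular cell line; the two
anchored magnitudes (≈8 µm/h follower-only speed, ≈15 µm/h peak mixed
speed) sit in the range reported for epithelial sheets on aligned
nanofibers.

## Numerical choices and degenerate inputs

* Coordinates are physical µm, image convention (origin top-left, y down);
  frames are 0-based; time at frame k is k·Δt.
* Track-table round-trips preserve coordinates to 6 decimal places;
  TrackMate XML is read-only, rejects branching (splitting/merging) tracks
  explicitly, and requires a recognized spatial unit or an explicit
  override.
* Binary masks are promoted to labels by 8-connected components; float
  images are rejected (thresholding belongs upstream).
* A 1-pixel blob has a small positive perimeter (its smoothed contour), not
  zero; an all-zero mask page yields missing records, never zeros.
* Stationary cells: undefined straightness (NaN), excluded from means with
  a count. Zero-length steps carry no angle and are skipped but counted.
* Problem sizes in the test suite: the calibration checks run 6 mixing
  ratios × 10 seeds at the default 50-cell, 97-frame colony, with masks
  rendered only where shape metrics are asserted; the random-walk limit
  uses 500 walks of 96 steps. These sizes give seed-averaged margins well
  above the observed seed noise for every asserted ordering.

## Known limitations

* The straightness of a follower-only simulated colony (≈0.94) is higher
  than typical measured epithelial values; tightening it would require a
  heading-noise process with long-range temporal correlation that the
  qualitative criteria do not need.
* The crowding dilution uses a single effective-count scale (10 cells);
  colonies much denser than the default packing would need this revisited.
* Shape metrics for fragmenting colonies follow the largest component per
  frame; colony identity is not tracked across frames when several colonies
  of comparable size coexist.
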