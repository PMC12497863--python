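# Methods note

This note records what `tnkit` computes, the assumptions baked into each
stage, and the numerical and design choices a user should know before
trusting the outputs.

## Trajectories and contact kinetics (`tnkit.tracking`)

A track is a sequence of (frame, time, x, y) points with strictly
increasing frames and times; coordinates are in μm, time in seconds.
Gaps in the frame numbering are allowed and handled explicitly.

**Contact detection.** Two tracks are "in contact" at a frame when both
are observed and their centroid distance is ≤ `contact_distance`
(inclusive). Contact episodes are maximal runs of *consecutive* common
frames satisfying this; a run shorter than `min_contact_frames`
(default 2) is discarded. A frame where either cell is unobserved breaks
a run.

**Phase segmentation.** Given a focal track and one contact episode
[s, e] (inclusive frames), the track splits into Ph1 = frames before s,
Ph2 = frames s..e, Ph3 = frames after e. Ph1 or Ph3 may be empty (contact
at the movie boundary); an empty Ph1 makes the deceleration ratio
undefined for that cell, and the cell is excluded from cohort statistics
rather than silently assigned a value.

**Phase velocity.** Two estimators are offered:

- `path` (default): sum of step displacements within the phase divided by
  elapsed time — mean instantaneous speed along the path.
- `net`: net displacement between the phase's first and last point
  divided by elapsed time.

`path` is the default because the deceleration phenomenon is a change in
instantaneous motility, which net displacement underestimates for
meandering cells. A phase with fewer than two points cannot yield a
velocity (`PhaseTooShortError`).

**Deceleration ratio.** ratio = v(Ph2)/v(Ph1). A ratio of 0.2 is exactly
a 5-fold slow-down. When a cell has several contact episodes (possibly
with different partners), the longest is scored; ties go to the earliest
start, then lexicographic partner id, so the choice is deterministic.
Ranking is by ascending ratio with ties broken by track id (1-based
ranks).

## Speed–Distance Index (`tnkit.interaction`)

For a pair of tracks, per common frame t:

- d(t): centroid distance (μm).
- v_rel(t): ‖v→A(t) − v→B(t)‖, each velocity a backward finite
  difference over the previous observed frame. The first common frame of
  a pair — and any frame following a gap in either track — has no
  backward difference and yields no SDI sample, rather than a padded
  zero.
- SDI(t) = v_rel(t) / (d(t) + ε), with ε = 1e-6 by default. ε exists
  only to keep coincident centroids finite; at realistic distances it is
  ~6 orders of magnitude below d and SDI ≈ v_rel/d. Units are 1/s; note
  that some figure conventions label SDI in μm/s, which is dimensionally
  the numerator's unit — we keep 1/s and record the discrepancy here.

Aggregation: samples are assigned to fixed-width time bins (origin either
absolute movie time or each pair's first contact), averaged *within each
pair* per bin first, then summarized across pairs as median and quartiles
(via `np.percentile`). The per-pair mean step prevents long-lived pairs
from dominating the cohort median. Modalities are order-free sorted
labels ("NK-T", "T-T", "NK-NK").

Proximity: a pair distance is "close" iff ≤ 250 px (inclusive),
"distant" otherwise; the distance histogram uses half-open 10-px bins
[0,10), [10,20), … with the final bin closed, so counts always sum to
the number of samples. Distances arriving in μm are converted to px by
dividing by the pixel size.

## Imaging pipeline (`tnkit.imaging`)

Segmentation: per-channel thresholding (Otsu, or a user-fixed value;
a constant frame under Otsu yields zero labels instead of an arbitrary
split), 8-connected component labeling, optional minimum-area filter,
then sequential relabeling. Centroids are unweighted pixel means
(scikit-image regionprops), returned as (label, x=column, y=row).

Linking: greedy nearest-first assignment between consecutive frames.
All candidate (previous, next) detection pairs within `max_displacement`
are sorted by distance (ties by label ids, so linking is deterministic)
and consumed greedily, each detection used at most once. Tracks that
never link beyond a single point are dropped. This is O(n²) per frame
pair and not globally optimal — adequate at the cell densities the
simulator produces, and validated against ground truth identity at low
density; a crowded field would warrant Hungarian assignment instead.

Transfer quantification: within each recipient label, count (and sum the
area of) donor-channel pixels at or above an intensity threshold.
Averages can be reported per cell-frame, per frame, or per video.

## Ligand–receptor TPM screen (`tnkit.lr_screen`)

Pairs may have multi-subunit sides written slash-separated
(e.g. `ITGAL/ITGB2`). A side passes at threshold θ in a cell type iff
*every* subunit has TPM ≥ θ there (inclusive). A pair passes in a given
direction iff the ligand side passes in the ligand cell and the receptor
side in the receptor cell. The default direction is `either`: a pair
passes if at least one of the two cell-type assignments works. Any gene
missing from the expression table makes its side's verdict unknown; a
pair whose every direction is unknown is reported "unevaluable" — a
distinct tri-state, never conflated with failing. `count_by_threshold`
applies the screen at 2 and 10 TPM and checks that the ≥10 set nests
inside the ≥2 set. A curated 16-pair T–NK crosstalk reference table is
packaged (`tnkit.lr_screen.load_reference_pairs`).

## Phospho-flow fold changes (`tnkit.flow`)

fold change = (pX_co / X_co) / (pX_mono / X_mono), the co-culture
phospho-to-total ratio normalized to its monoculture counterpart. Inputs
must be positive finite percentages; violations raise errors naming the
offending field. The statistic is invariant to rescaling either
condition's instrument gain and satisfies fc(co, mono) · fc(mono, co)
= 1, both of which are enforced as tests.

## Synthetic data generator (`tnkit.simulate`)

The generator emulates the *kinematics and measurement geometry* of a
two-population co-culture movie, not cell biology:

- Isotropic random walk with fixed step length = speed × frame interval.
  Directions are rejection-sampled so the endpoint stays inside the
  square arena; this keeps every step's length exact (a reflecting
  boundary would distort step lengths and break the noise-free
  speed-recovery invariants).
- Each T cell gets one scripted contact window: start uniform in
  [n_frames/4, n_frames/2), duration 15–25 frames. During the window the
  partner NK is steered to 0.9 × contact_radius from the T cell and the
  T cell's speed is multiplied by its deceleration factor (scalar
  default 0.1, or a per-cell list).
- After the window the NK flees radially for 3 frames at 3× its base
  speed. Without this scripted disengagement the steered NK can linger
  within the contact distance and contiguously extend the detected
  contact episode into full-speed frames, biasing Ph2 velocity upward.
- Speed noise: each step's length is multiplied by a truncated-at-zero
  Gaussian factor with sd = `noise_sd_frac`. All randomness flows from a
  single `np.random.default_rng(seed)`, so outputs are bit-for-bit
  reproducible.
- Rendering: cells are uint16 disks (intensity 1000) of radius 4 μm on a
  0.5 μm/px grid, one channel per population; transfer events paint up
  to `transfer_pixels` donor-intensity-800 pixels inside the recipient
  mask but outside every donor disk. The 4 μm radius plus the
  0.9 × contact_radius contact offset keeps touching cells' disks
  disjoint, so painted pixels are the only donor signal inside recipient
  masks and transfer counts have exact ground truth.
- `synth_expression` solves interval constraints per gene so that the
  screen applied to the generated table reproduces a prescribed
  pass10 / pass2_only / fail design exactly; contradictory designs raise
  `DesignError` naming the gene. `synth_flow` emits flow tables with
  known fold changes and optional multiplicative noise resampled into
  (0, 100].

What the generator does **not** model: persistent/ballistic migration,
cell shape change, division or death, photobleaching, background noise in
rendered images, or 3D motion.

## Degenerate inputs and numerical conventions

- All thresholds in the package are inclusive (≤ / ≥) unless stated.
- Tracks need ≥ 2 points; phases need ≥ 2 points to have a velocity.
- Track CSVs are written with `%.17g` and read with round-trip float
  parsing, so track I/O is lossless at double precision.
- Empty inputs return empty results (zero-row frames, empty histograms)
  rather than raising, except where a computation is genuinely undefined.

## Known limitations

- Greedy frame linking is not globally optimal under crowding or
  occlusion.
- Otsu segmentation assumes a bimodal intensity histogram; it degrades on
  low-contrast or highly confluent frames (use `fixed` mode there).
- SDI velocities use one-step backward differences and inherit tracking
  jitter; no smoothing is applied.
- The `either` screen direction is a deliberate default, not a claim
  about biology; directional analyses should pass `ligand_on_a` /
  `ligand_on_b` explicitly.
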