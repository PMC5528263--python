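# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `tracmit`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Coordinate and angle conventions

Frames are indexed from 0; image coordinates are 0-based `(row, col)`
with pixel centres at integer coordinates. All orientations (blob
orientation, plate angle, pair axis) are measured from the +x (column)
axis, counter-clockwise in a y-up frame, modulo 180° — a chromatin mass
has no polarity. The L-pattern is assumed oriented with its arms up and
right, so its horizontal arm direction is +x and the "lower-left corner"
of a pattern is the (max-row, min-col) corner of its connected
component. The deviation exported per division is the folded angular
distance from the expected 45° plate position,
`min(|θ−45| mod 180, 180−|θ−45| mod 180) ∈ [0°, 90°]`; both raw θ and
the deviation are exported so either convention is recoverable.

## Registration

Stage drift and positioning hysteresis are translations, so the model is
translation-only; rotation/affine registration is out of scope. Plain
upsampled phase correlation against frame 0 is accurate on static scenes
but is biased by several tenths of a pixel when bright chromatin moves
within the field. `estimate_drift` therefore works in two stages:

1. Hann-windowed phase correlation of each frame against frame 0
   (upsampling factor 20) initialises the shifts.
2. The stack is provisionally aligned and the per-pixel temporal *range*
   (max − min) computed: any pixel a moving cell ever visited has a range
   on the cell-intensity scale, whereas static pattern edges only jitter
   by interpolation. Pixels above `max(0.35·range_max, 8·median(range))`
   (dilated by 3 px) are excluded, and a Gauss–Newton least-squares
   translation fit against frame 0 — coarse-to-fine at Gaussian scales
   σ = 3 then 1 px, restricted to the ≤40 000 highest-gradient static
   pixels, residuals mean-centred so global offsets cancel — refines each
   frame's shift. The refinement repeats once if it moved any estimate by
   more than 0.75 px (a sign the initialisation was unreliable).

Frame 0 is the fixed reference; chained pairwise registration was
rejected because per-link bias accumulates over a 180-frame recording.
On synthetic fields with injected constant or random-walk drifts up to
5 px the maximum per-frame error is ~0.01 px, comfortably inside the
0.25 px contract asserted by the tests. Corrections are applied by
bilinear resampling; border pixels shifted in from outside the field are
zero-filled and flagged in a validity mask that every temporal
projection honours.

## Pattern detection and occupancy

The minimum-intensity projection over (valid) frames keeps only
structures present in every frame — the micropatterns — and suppresses
transient cell signal. The projection is median-filtered (disk radius
2 px), thresholded with Huang's fuzzy-entropy method, and connected
components are kept when their physical area lies within
`pattern_area_um2_band` (default 700 µm² × [0.6, 1.4], tolerant of
threshold-induced erosion/dilation). Each surviving L contributes a
40 × 40 µm analysis box anchored so the L corner sits in the box's
lower-left quadrant (`anchor_offset_px = (−46, −15)` at 0.65 µm/px).
The box doubles as the division-detection region: a cell parked out on
one arm divides outside it and is thereby excluded without any explicit
"bad position" classifier.

Occupancy is scored with fStDev: the per-pixel temporal standard
deviation divided by the temporal mean, averaged over the box
(mean-of-ratio; ratio-of-means is available behind
`fstdev_mode="ratio_of_means"` — the per-pixel ratio image is the more
selective form because it weights every moving pixel equally regardless
of its brightness). Both forms are invariant to a global intensity
scaling, which is the point: chromatin-transgene expression varies
widely between cells, and the normalisation lets one bandpass serve all
of them. The default band (0.12, 0.32), closed on both ends, was
calibrated on the synthetic suite, where the class score distributions
over 10 seeded fields were: empty ≤ 0.076, bad-position ≤ 0.145,
single cells 0.155–0.227, crowded ≥ 0.412. The low edge is deliberately
below the single-cell minimum: a bad-position pattern that sneaks in as
a candidate is harmless (its division is outside the box), whereas a
dividing cell lost to the filter is unrecoverable.

## Anaphase detection

Condensed chromatin is enhanced per frame with a scale-normalised,
*negated* Laplacian of Gaussian, so bright compact blobs give positive
responses and the hard threshold selects chromatin directly. The default
σ = 2.5 px at 0.65 µm/px matches the metaphase plate's half-width; at
this scale the thin pattern arms and the broad, flat interphase nuclei
respond weakly. The hard threshold is relative by default —
`log_threshold_frac = 0.3` times the maximum response over the box's
whole time-lapse — so one setting serves the 250–4000 AU intensity
range; an absolute mode exists for instruments with calibrated response.
The binary mask is closed with a 2 px disk to heal figures fragmented by
intensity variation within chromatin, and components smaller than
`min_blob_area_px = 20` px are dropped: every real chromatin figure at
this resolution is several times larger, and without the floor,
near-threshold noise specks can pair up and their spurious "events" then
deduplicate away the true anaphase at the same location.

Blobs are fitted with second-moment ellipses (a 1/12 px² diagonal term
accounts for finite pixel extent, so even 1-px-wide components have a
positive minor axis). An anaphase figure is an unordered blob pair with
centroid separation in (6, 30) px, orientation difference ≤ 30° (folded
mod 180), and area ratio ≤ 2.0; when pairs share a blob the smallest
area ratio wins, ties broken by smallest separation. The orientation
constraint compares the two masses' own orientations
(`pair_angle_mode="mass"`); comparing each mass to the pair axis is
available but inappropriate for sister chromatid masses, which stay
parallel to the former plate, i.e. perpendicular to the separation axis.
Re-sightings of the same figure — midpoint within 10 px of an earlier
retained event of the same pattern, at any later frame — are dropped,
earliest frame wins.

Accepted events pass a local crowding check: the MinInt projection
(background + pattern, i.e. everything static) is subtracted from the
raw box crop, the residual is thresholded with the intermodes method
(iterated 3-bin mean smoothing of the 256-bin histogram until exactly
two maxima remain, threshold at the mode midpoint), and components above
a 30 px nucleus floor that match neither anaphase mass count as extra
cells, rejecting the event. Subtracting the static layer is essential:
thresholding the raw crop would segment the micropattern itself as an
"extra cell". Intermodes is the default because it is the more sensitive
choice — it keeps more genuinely analyzable cells at the cost of letting
some crowded patterns through; the stricter iterative-intermeans
(isodata) method is available via `crowding_method="intermeans"`. When
the residual cannot be thresholded at all the event is *kept* and
flagged `crowding_uncheckable`, consistent with that sensitivity bias.

## Backtracking

Reunion detection scans backwards from the event frame (window
`reunion_search_frames = 6`): on each earlier LoG frame the intensity
profile along the inter-centroid segment is sampled (bilinear, 2 samples
per pixel). While the masses are separate the profile has two end peaks
with a deep gap; the gap is measured as the minimum between the two
half-profile maxima, relative to their mean height. The first frame
where that ratio reaches `reunion_profile_frac = 0.5` — no gap, a single
central mass — is the last metaphase frame, and certifies the cell
actually segregated its chromosomes (two unrelated adjacent nuclei never
merge and are discarded here). The relative form keeps the test
intensity-invariant. The blob nearest the profile midpoint becomes the
tracking seed.

The plate is then linked backwards greedily: the closest blob within
`max_link_px = 10` of the last tracked position continues the track,
provided it passes the plate shape bands (fitted-ellipse major axis
8–30 px, minor 2–10 px, ratio ≥ 1.8 — a metaphase plate viewed laterally
is elongated; these bands also reject interphase-nucleus rings and
anaphase masses). Up to `max_gap_frames = 3` consecutive frames without
a linkable blob are bridged; a fourth ends the track. Greedy
nearest-neighbour linking with gap closing is the standard
Brownian-motion tracking contract and suffices here because each box
holds at most one plate; global assignment would add nothing. The
earliest linked frame is reported as metaphase start: the track ends
naturally when chromatin stops being plate-shaped, i.e. prometaphase.
A track still linking at frame 0 is flagged `track_truncated` (the plate
may predate the recording, so its duration is a lower bound); ending by
gap exhaustion is the normal case, not truncation.

Metaphase duration is `(anaphase_frame − metaphase_start_frame) ×
frame_interval_min`. The plate angle is the circular median (computed on
doubled angles to respect the 0/180 wrap) of the blob orientations over
the last ≤ 3 metaphase frames, damping single-frame segmentation noise;
single-frame mode is `angle_median_frames = 1`. A division is called
mispositioned when the folded deviation strictly exceeds
`mispositioned_offset_deg = 40`.

## Synthetic fields

The generator renders what the detectors measure, no more:

* **Geometry.** L-shapes of two rectangular arms (default width 10 µm,
  length derived so the filled area is within 2% of 700 µm²), grid
  pitch = arm length + 20 µm spacing, 0.65 µm pixels.
* **Classes.** Exact largest-remainder quotas over
  empty / crowded / bad-position / non-dividing / dividing (default 20%
  each), scattered with the seeded generator — tests can assert exact
  counts. Crowded patterns hold two wandering nuclei (with a larger
  wander amplitude — cells sharing one pattern jostle); bad-position
  cells run a full mitosis parked 33 µm out on the horizontal arm,
  outside every analysis box.
* **Dynamics.** Interphase nuclei are 7 µm-radius discs on a smooth
  seeded wander (amplitude 3.5 px). A dividing cell condenses at a
  sampled metaphase onset into an 8 × 2.8 px-semi-axis plate at the
  sampled true angle, holds for 4–8 frames, then splits into two
  4.5 × 2.8 px masses separating along the plate normal,
  `sep(k) = 8 + 16·(1 − 0.72^k)` px — strictly increasing, saturating
  below the pair-distance band — before decondensing into two daughter
  nuclei.
* **Signal.** Intensities are additive over a 250 AU background
  (pattern +550, nuclei +1600, condensed chromatin +3000), clipped to
  the 250–4000 AU band before Gaussian noise (σ = 30 AU); cells bleach
  exponentially (0.15%/frame), patterns do not — matching a stable
  pattern dye. Global drift is a seeded smooth random walk (default
  amplitude 2 px) plus an optional constant per-frame shift for
  registration tests; the per-frame drift vector is recorded in the
  ground truth.

What the generator does **not** model: chromatin texture and chromosome
arms, cytoplasm, 3-D defocus, camera-specific noise, cell death, and
cells drifting between patterns. Passing tests therefore demonstrate
correctness of the algorithms under realistic geometry, intensity
range, drift and noise — not robustness to every artefact of real
screen data, whose detector settings would be re-calibrated through the
same config file.

## Problem sizes and determinism

The test suite and acceptance script use 4 × 5-pattern fields of 60–72
frames (8–9.6 h of recording) rather than full 180-frame wells — the
pipeline is linear in both, and these sizes exercise every code path:
20 mixed-class fields for end-to-end recovery, 53+ dividing cells
spanning [0°, 180°) for angle accuracy, dedicated fields for drift
recovery and the control-vs-phenotype well comparison. Everything is
deterministic given the seeds: the generator derives per-cell
sub-generators from one root seed, and the pipeline itself contains no
randomness, so repeated runs are byte-identical.

## Known limitations

* Pattern orientation is assumed uniform per field (arms up-right) and
  is not estimated per pattern.
* The fStDev band, LoG threshold fraction, pair constraints and plate
  shape bands are calibrated for HeLa-scale cells at 10× / 0.65 µm
  sampling; other magnifications need re-calibration via the config
  file.
* Only translation drift is corrected; rotation would require a
  different registration model.
* A division whose metaphase predates the recording start yields a
  truncated track and a lower-bound duration, flagged but not excluded.
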