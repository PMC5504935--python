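# Methods

## Problem

Extracting an object of interest from a cluttered color image is hard for a
machine both because "of interest" lives in the operator's head and because
RGB values drift with illumination. This package couples two components:

1. a **P300 speller pipeline** that infers which of nine grid targets an
   operator attends from stimulus-locked EEG, and uses the selection to
   index a per-object dataset of seed pixels and fuzzy parameters; and
2. an **improved fuzzy color extractor (IFCE)**: a seeded region-growing
   segmenter whose pixel similarity is the *angle between RGB vectors*,
   which factors illumination (vector length) out of color (direction).

Human EEG and real photographs are replaced by parametric synthetic
generators; every claim a green test makes is a claim about that stated
synthetic world, not about human subjects.

## Color pattern

A pixel `p = (R, G, B)` is a vector from the origin of RGB space. The
similarity of `p` to a seed `q` is

    d(p, q) = arccos( p.q / (|p| |q|) )  in [0, pi/2],

invariant under `p -> c p` for any `c > 0`, hence under global
multiplicative illumination change (up to 8-bit rounding). The all-zero
pixel has no direction; it is flagged degenerate (`+inf` in vectorized angle
maps, an error for scalar calls). The arccos argument is clamped to
[-1, 1]; near collinearity arccos itself loses ~sqrt(eps) ≈ 2e-8 rad of
precision, which bounds what angle equalities tests may assert.

A second, *non*-invariant quantity is kept deliberately: the squared RGB
distance `sum_i (p_i - q_i)^2`, used un-rooted as the region-growing stop
gate, so its threshold `r` carries squared-intensity units.

`variation_rate(v_ref, v_alt) = 100 |v_ref - v_alt| / v_ref`, rounded
half-up to one decimal, with the *first-measured* (reference illumination)
value as denominator — the convention under which all published example
rates reproduce exactly.

## Fuzzy engine

Input memberships over the angle are piecewise linear with breakpoints
`alpha1 < alpha2` (zero/matched set full below `alpha1`, empty above
`alpha2`; the positive set is its complement on [0, pi/2]; a negative set
mirrors it on the unreachable negative half-domain, kept for completeness).
Intervals are left-closed, following the printed convention. Two rules map
these to a matched weight `wm = mu_Z` and an unmatched weight
`wu = max(mu_N, mu_P)`; on the nonnegative domain `wm + wu = 1` identically.

Output memberships on [0, pi/2]: matched is a descending ramp hitting zero
at `rho_u`, unmatched an ascending ramp starting at `rho_m`, with
`rho_m + rho_u = pi/2`. The crisp output is the centroid of the Mamdani
envelope `max(min(wm, mu_M), min(wu, mu_U))` — the envelope is the pointwise
maximum of the two clipped sets, the standard reading of "envelope of the
cut areas". The centroid is integrated **exactly**: the envelope is
piecewise linear with computable breakpoints (clip heights, ramp ends, and
the crossing of the two clipped functions inside each interval), and each
linear segment contributes closed-form area and moment. A trapezoid-rule
integrator on a uniform 4096-panel grid serves as an independent
cross-check; the two agree to 1e-6 rad over parameter sweeps (trapezoid
error concentrates at the few kinks, O(h^2) each).

A pixel is extracted when the crisp output falls below the per-object
threshold `sigma`. Useful closed forms (used as test oracles):
fully matched gives `rho_u / 3`; fully unmatched gives
`rho_m + 2 (pi/2 - rho_m) / 3`.

**Monotone-threshold vectorization.** The crisp output is continuous and
nondecreasing in the angle (constant below `alpha1`, rising on
`[alpha1, alpha2]`, constant above). "Extract" is therefore equivalent to
`angle < a*` for a critical angle `a*` found once per parameter set by
bisection (tolerance 1e-13 rad). Segmentation uses the threshold on a
vectorized angle map; property tests assert its equivalence with the full
per-pixel chain on random pixels. Pixels whose crisp output equals `sigma`
to within the bisection tolerance are the only possible disagreements — a
measure-zero set never hit by integer-valued images in practice.

## Segmentation

Given a seed and parameters:

1. **Start selection** — the unassigned pixel with the minimal angle to the
   seed (row-major tie-break).
2. **Gate** — the start candidate must satisfy the squared-distance gate
   `d(p, seed)^2 < r`; by default the gate applies to start candidates only
   (`per_pixel_gate=True` extends it to every grown pixel).
3. **Growth** — breadth-first closure of matched pixels under one of three
   neighborhood patterns: 4-adjacent, 4-diagonal, or 8-neighbor (default:
   8-neighbor, the most inclusive pattern).
4. **Repeat** from the next minimal-angle unassigned pixel; stop when the
   candidate fails the match or the gate (or a 512-subregion safety cap).
5. **Object selection** — the largest subregion (earliest wins ties).
6. **Gap filling** — runs of unextracted pixels strictly shorter than
   `gap_threshold`, bounded by extracted pixels on both sides, are filled
   along every row, then every column on the row-filled result (row-first
   order is fixed; the operation is monotone and idempotent).

### Parameter defaults and their provenance

`alpha1, alpha2, rho_m, sigma` per object come from the published trained
dataset (seven objects O1..O7). Two thresholds have no published values and
are experience-set here, **fixed a priori from the dataset geometry**:

- `r = 1000` (≈32 RGB units). The gate must accept pixels that differ from
  the seed by sensor noise (a few units per channel, ≲15 units total) and
  reject the *nearest foreign trained seed* (minimum pairwise seed distance
  ≈ 51 RGB units, O5–O6). 1000 sits between those scales with margin.
- `gap_threshold = 3` px: fills specular pinholes without bridging distinct
  regions.

### An inherent limitation of the published parameters

The trained rows contain mutually confusable pairs: O1 and O4 accept each
other's seed color inside their fuzzy match range (seed angle 0.146 rad vs
thresholds 0.21 / 0.18), as do O5 and O6 (0.133 rad). With the distance gate
active the gate separates them (RGB distances 52 and 51 > sqrt(r)). With the
gate *disabled*, a scene containing both members of a pair cannot yield both
objects under the largest-subregion rule — whichever region is larger wins
both queries. Illumination-robustness is therefore stated on scenes
dominated by the single object of interest (one blob plus clutter), which is
also the regime the gate-free extractor is meant for.

## Speller and timing

3x3 grid, row-major O1..O7 plus two reserved cells (O8, O9). One repetition
flashes the 3 rows and 3 columns once each in seeded-random order; flash
presentation 200 ms, onset-to-onset interval 300 ms (the only reading of the
interstimulus interval consistent with a 6 x 300 ms = 1.8 s repetition; each
flash is followed by a 100 ms blank). Every target is covered exactly twice
per repetition. Offline training uses 6 repetitions per trial; online
selection uses 3 repetitions plus voting.

## EEG pipeline

- **Filter**: 0.1-30 Hz band-pass, 4th-order Butterworth applied
  forward-backward (zero phase). Implemented in second-order sections: with
  a 0.1 Hz edge at a 1 kHz rate the polynomial transfer-function form is
  numerically unstable (poles cross the unit circle in double precision);
  SOS keeps the realized response within 1e-4 of design.
- **Features**: per flash, the (50 ms, 800 ms] window (750 samples),
  mean-removed per channel, reduced 50-fold to 15 values per channel —
  non-overlapping block means by default (anti-alias robust); plain
  take-every-50th decimation is available behind a flag; length is 450
  either way (30 channels concatenated head to tail).
- **FLDA**: `w ∝ (S_w + shrinkage * mean-diag * I)^{-1} (mu_+ - mu_-)`,
  bias at the projected class-mean midpoint (the training procedure defines
  only labels, so the midpoint bias is a convention). Shrinkage defaults to
  0.05: a 450-D scatter estimated from a few hundred epochs is singular
  without it.
- **Repetition classification**: cell at (argmax of the 3 row scores,
  argmax of the 3 column scores), lowest index on ties. Offline trials sum
  each stimulus's scores over the trial's 6 repetitions before the argmax.
- **Online voting**: over 3 repetitions, a target with ≥2 votes wins
  ("more than two votes" read as ≥2 of 3 — a literal >2 would make two of
  the three repetitions redundant); if all three disagree, the target with
  the greatest summed row+column score across the repetitions is selected.
- **Accuracy**: percent correct, rounded half-up to 2 decimals.

## Synthetic world

**Scenes.** Blobs (rectangles/ellipses) colored at their object's seed RGB
plus per-pixel Gaussian channel jitter of sd 3.0 (typical 8-bit camera
sensor noise; keeps within-blob angles ≲0.05 rad, well inside every match
threshold) on a uniform magenta background (180, 40, 170), chosen to sit at
angle > every object's `alpha2` from all seven seeds. Clutter speckles
(1-3 px, uniformly random colors) are scattered with a 2 px keep-out margin
around blobs so a speckle can never join an object's subregion. Ground-truth
masks are recorded before jitter and clutter. The illumination scale is
applied last, then rounding and clipping to 8 bits — so scaled scenes differ
from unscaled ones exactly the way a camera exposure change would.
Not emulated: shading gradients, specular highlights, shadows, texture,
chromatic illumination change (only intensity scales).

**EEG.** Gaussian white channel noise (sd 2.0 uV). Every flash covering the
attended target adds a positive half-cosine deflection: amplitude 5 uV at
the last channel, latency 300 ms, width 300 ms, scaled across the 30
channels by a fixed posterior-weighted gain ramp (0.25 -> 1.0) so the
concatenated features carry redundant spatial signal. The defaults are a
deliberately *high-SNR regime*: real background EEG (~10-50 uV with alpha
rhythms, drift, blinks) is larger than a single-trial P300, which is why
human accuracies need averaging and are not reproducible here. A green
end-to-end test establishes that the pipeline is correct, not that the
human experiment would reach the same accuracy. The zero-amplitude control
establishes the absence of label leakage: selection accuracy is then
statistically indistinguishable from the 1/9 chance level.

**End-to-end runs** train the FLDA on a simulated offline session (18
trials x 6 repetitions by default, targets cycling over all nine cells),
run online selections (3 repetitions, voting), then extract every trained
object from a 7-blob scene and report selection accuracy and per-object
mask IoU. All generators are bit-reproducible from their seeds; derived
seeds are drawn below 2^31.

## Numerical choices

- Bisection tolerance for the match threshold: 1e-13 rad.
- Trapezoid cross-check: 4096 uniform panels on [0, pi/2].
- arccos clamping to [-1, 1]; degenerate (zero) vectors are errors, or
  `+inf` angles in vectorized maps.
- Rounding: variation rates half-up to 1 decimal; accuracies half-up to 2
  decimals (both are presentation conventions of the published tables).
- Filter warm-up: inputs shorter than `3 * (2 * n_sections + 1)` samples
  are rejected.

## Known limitations

- Single-color objects only; no texture/shape cues, no multi-seed merging.
- The gate-free extractor cannot separate the confusable pairs above.
- The ERP surrogate has no latency jitter, no trial-to-trial amplitude
  variability, no correlated noise; FLDA performance on it is optimistic.
- Accuracy of the published human tables is consumed as printed numbers
  (bookkeeping checks), never re-derived.
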