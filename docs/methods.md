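# Methods

This note documents the models, conventions and numerical choices behind
`filotrack`, in the order the pipeline applies them, together with what the
synthetic fixtures do and do not establish about real data.

## Imaging model and calibration

The pipeline assumes 2D time-lapse stacks (single plane or a projection
prepared by the caller) with a membrane-marker *mapping* channel that
outlines the cell, and optionally a *measurement* channel carrying a
labelled protein. All geometry is computed in pixel/frame units and
converted with a `Calibration` (pixel size in nm, frame interval in s). The
defaults, 65 nm and 2 s, describe a 100x/sCMOS live-imaging configuration;
one pixel per frame then corresponds to 32.5 nm/s, which is also the default
threshold separating directed tip/base movement from stalling — i.e. the
state classifier treats sub-pixel-per-frame movement as noise. Movies with
other calibrations get a consistent threshold automatically because
thresholds are stored in physical units.

## Segmentation

* **LoG filter.** The kernel is sampled on an integer grid truncated at
  4 sigma and applied as written; its centre value is `-1/(pi sigma^4)`, so
  bright structures respond negatively and thresholding operates on the
  negated response (cell interior high). A membrane marker produces a bright
  rim rather than a filled body, so interior holes are filled after
  thresholding. `sigma_log` should match the expected protrusion width via
  the FWHM relation `w = 2 sqrt(2 ln 2) sigma` (default sigma 2.6 px →
  w ≈ 6.1 px ≈ 398 nm at 65 nm pixels).
* **Auto-thresholds.** Otsu, Triangle, Li, Yen, Mean and IsoData come from
  scikit-image; Huang (fuzzy-entropy minimisation) and Renyi entropy are
  implemented on 256-bin histograms. "RenyiEntropy" maximises the sum of
  the two class Renyi entropies at a single order (alpha = 2, exposed as a
  parameter; alpha → 1 gives the classic maximum-entropy method, registered
  as "MaxEntropy"). Entropy-based thresholds can sit close to the dark
  mode's upper tail on strongly bimodal histograms; this is inherent to the
  criterion and the tests assert class separation rather than a particular
  threshold value.
* **Adaptive mode.** Eight one-sided LoG kernels (the full kernel with the
  half-plane opposite each principal direction zeroed, centre line kept) are
  applied separately; per-direction masks are OR-combined and a 3x3 median
  filter removes speckle. The construction of the directional kernels is a
  design choice of this package.
* **Body/protrusion split.** The body is the n-fold morphological opening
  (default structuring element: 3x3 square, i.e. 8-connected; a diamond
  element is available) of the largest connected component; protrusions are
  the connected components of the difference. `n` (default 4) must exceed
  half the widest filopodium's width in pixels. If erosion annihilates the
  mask the pipeline fails loudly (`OverErosionError`) rather than producing
  an empty segmentation. An `n` that is too small leaves wide protrusions
  inside the body; too large shaves genuine body area — the per-frame label
  masks written by the pipeline are the intended diagnostic.
* **Fragments.** Protrusion components not touching the body (weak signal,
  focus loss) are flagged; optional joining repeatedly draws the shortest
  1-px line between the two closest disconnected components (close fragments
  merge first, then attach to the cell) for at most 10 rounds; anything
  still disconnected is excluded from measurement.
* **Base and tip.** The base is the centroid of the protrusion's
  body-contact pixels snapped to the nearest boundary-polygon point (the
  boundary is the longest 0.5-level contour of the body mask, sub-pixel).
  The tip is the protrusion pixel farthest from the base — deliberately
  simple, and known to mis-assign tips of looping or backward-bent
  filopodia; such tracks are meant to be removed via the editing API.
  Optional tip fitting searches a radius `r = clamp(sqrt((area/2)/pi), 3,
  20)` px around the mapped tip for strict local maxima of the measurement
  channel and moves the tip to their intensity-weighted mean; the tip radius
  becomes half the maxima's mean squared error about the new tip, floored at
  1 px as a numerical guard (a single maximum would otherwise give a
  zero-radius ROI).

## Length, straightness and movement

* **Corrected length.** Raw length is half the protrusion ROI perimeter
  (Crofton estimate, 4 directions). In a closed ROI the base edge adds
  `w/2` to the half-perimeter while the two sides fall `w/2` short of the
  axis length — those cancel — leaving the rounded tip cap's quarter
  circumference as the systematic overestimate. The correction is therefore
  `(pi/4) w`, scaled by `min[(D/w)^2, 1]` so it fades out for blob-like
  detections whose base-tip distance `D` is below the width. The constant
  was validated against rasterised capsules (axis lengths 2–15 µm at
  w ≈ 6 px): error is within 6% at 2 µm and under 1% at 15 µm.
* **Straightness** `D/length` (waviness its complement) is flagged
  unreliable below `length < 2w`, where the end-correction regime biases it.
* **DCTM / DCBM.** `dctm_t = (Tip_t - Tip_{t-1}) · u_t` with
  `u_t = unit(Tip_t - Base_t)`; DCBM analogously for the base. Projection on
  the *current* axis discounts lateral swinging, at the cost of a residual
  `sin(dtheta/2)` of tip speed under pure rotation (0.4% at 0.5°/frame,
  4.4% at 5°/frame). The first frame, frames following a gap, and frames
  with a degenerate axis (tip = base) are missing; nothing is interpolated,
  and any metric touching a missing frame stays missing.
* **Series cleaning.** Movement series pass a 0.5–99.5 percentile filter
  (removes focus/reconstruction spikes) and a centred 5-point rolling mean
  that ignores missing values and truncates at the ends; positions missing
  on input remain missing on output.
* **States.** The smoothed movement is averaged over a centred 10-s window
  (full coverage required, so window edges stay unclassified) and compared
  with ±32.5 nm/s: extending / retracting / stalling for the tip, invading /
  retracting / stable for the base. Fractions are over classified frames
  and sum to 1.
* **Persistence.** Biased sample autocorrelation of the mean-subtracted,
  smoothed movement series; the first non-positive value is linearly
  interpolated between lags and converted to seconds. Series with no
  crossing return the maximum available lag flagged *censored*; constant
  series are rejected.
* **Fluorescence.** Tip and base ROIs are disks of radius `tip_radius`
  (default w/2, or the fitted radius). The thresholded tip mean keeps
  pixels above the Otsu threshold computed within the tip disk, which
  separates tip signal from background where the disk overhangs unlabelled
  area. Background is the mean in a 3-px-wide annulus starting 2 px outside
  the whole cell mask; normalised values are
  `(x - background)/(body - background)` and are flagged undefined when the
  body does not exceed background.
* **Predicted base.** For filopodia that form after the movie start, the
  base is walked backwards (default 20 frames): each earlier frame's
  predicted base is that frame's boundary point nearest the following
  frame's (predicted) base; a base-sized disk is measured and normalised
  per-frame, and the pre-formation summary is the mean of the last 3 frames
  before formation.
* **Boundary profile.** The body boundary is resampled to a fixed number of
  arc-length-equidistant points; intensity is a small disk (radius 2 px)
  placed 3 px inside the boundary (the paperless "small internal area" is a
  package choice), and local edge velocity is the temporal intensity change
  at the fixed boundary coordinate divided by the frame interval — positive
  where the cell advances outward.

## Tracking

Linking cost is `(d_base + d_tip)/overlap * dT`, read as: positional
distances penalise, mask overlap rewards, longer gaps penalise. Zero overlap
forbids the link (finite surrogate 1e12 keeps the solver exact). Birth and
death enter as a padded diagonal whose default price is the 95th percentile
of the finite pair costs in the frame — permissive enough that genuinely
new/vanished protrusions don't force bad links. Gap closing is off by
default (one-step linking); an optional `max_gap` lets tracks pend through
out-of-focus frames. Track filtering defaults (min 3 frames, max length
≥ 1.8 µm, at least one |dL| ≥ 0.1 µm, mean waviness ≤ 0.35) target
boundary-noise detections; "min length change" is interpreted as the maximum
absolute frame-to-frame length change over the track, which removes
perfectly static detections. Edits (delete, delete-range, relink) replay
deterministically from CSV and refuse dangling or already-applied
references.

## Coupling statistics

* **CCF.** Classical biased sample cross-correlation: value at lag k is
  `sum_t (f_{t+k} - fbar)(m_t - mbar) / (n s_f s_m)` with whole-series
  moments, so the zero-lag self-CCF is exactly 1 and magnitudes are bounded
  by 1. Negative offsets mean fluorescence precedes movement. Tracks with
  fewer than 17 paired valid points are excluded (too short for meaningful
  block randomization). The default window is ±6 s (3 frames at 2 s).
* **Clustering.** Complete-linkage agglomerative clustering on Euclidean
  distances between CCF vectors restricted to ±6 s. The cut (cluster count
  or height) is an explicit parameter — the responding/other split is a
  judgement call, not automatic; the responding subcluster is the one with
  maximal mean zero-offset CCF under the chosen cut.
* **Block randomization.** Each track's smoothed movement series is
  reshuffled in blocks of 8 frames (within-block order kept, preserving
  short-range autocorrelation on the scale of typical tip persistence);
  CCFs are recomputed against the unshuffled fluorescence and reclustered
  identically. A randomization is accepted only when the top subcluster's
  size matches the real one to within 15%, which controls the selection
  bias of always reading out a max-selected cluster. The one-sided p-value
  is the fraction of accepted randomizations whose top-subcluster mean
  zero-offset CCF reaches the observed value; p = 0 is reported with its
  resolution 1/n_accepted as the quotable upper bound. If fewer than 1% of
  the first 500 attempts are accepted the test aborts with diagnostics
  (the subcluster size is then too atypical for a size-matched null).
* **Markov null.** Each series (jointly valid time points) is binned into 9
  equal-width intervals over its observed range; a transition matrix is
  fitted on the occupied states. The model is invalid — and the track
  discarded — when fewer than two states are occupied or an occupied state
  has no outgoing transition (e.g. it appears only at the series end); this
  mirrors the behaviour of standard Markov-chain fitting on short series.
  10,000 independent chain pairs are simulated from the two matrices
  (vectorised), each starting at its series' initial state; Pearson
  correlations of the simulated pairs (on bin midpoints) form the null, and
  `p = fraction of simulated correlations >= observed`, with a z-score
  against the simulated mean/SD as a second summary.
* **Seeding.** Every stochastic component takes a `numpy` Generator seeded
  from the single configuration seed; per-track Markov tests use
  `seed + track_id + 1` substreams so results are independent of track
  order. Identical configuration and seed reproduce all output tables
  byte-for-byte (CSV floats are written at fixed precision).

## Synthetic fixtures: what they establish

The movie generator renders a disk body plus capsule protrusions (rectangle
with a semicircular tip cap — the shape the length correction is exact for)
with scripted nucleation, velocity schedules, angular drift, tip-localised
Gaussian fluorescence and optional pre-formation accumulation, over additive
Gaussian noise; truth (base/tip coordinates, axis lengths, velocities,
identities) is recorded analytically before rasterisation. The coupled
series generator produces a movement AR(1) and a fluorescence series equal
to `c * movement(t + lag) + sqrt(1 - c^2) *` independent AR(1), so the true
coupling and lead/lag are known exactly.

The standard benchmark (6 filopodia, 120 frames, ≤ 3 px/frame tip drift,
oscillating 30–36 nm/s schedules) is sized to run in seconds; on it the
pipeline reaches 100% per-frame detection of filopodia ≥ 1.8 µm and ≥ 99%
correct frame-to-frame links, and the block-randomization test rejects a
decoupled null at its nominal 5% rate over 200 seeded datasets
(16 tracks x 60 points, 100 accepted randomizations each) while rejecting
coupling 0.8 with p below the 1/n_accepted resolution.

What passing these tests does **not** show: robustness to uneven
illumination, photobleaching, Poisson-dominated noise, crossing or branching
filopodia (branched tips are explicitly out of scope — delete such tracks
via edits), retrograde-flow contamination of DCTM, or 3D effects collapsed
by projection. Real movies also have smoothly textured membranes rather than
two-level intensities, so threshold-method choice matters more in practice
than on fixtures.

## Known limitations

* The Euclidean-farthest tip rule mis-handles looping/buckling filopodia.
* DCTM assumes no retrograde flow; it reads out net tip-edge movement.
* The Renyi-entropy threshold is a single-order formulation; thresholds may
  differ by a gray level or two from other implementations of the same name.
* The boundary-profile velocity is an intensity-differencing proxy, not an
  optical-flow edge velocity; it is meaningful for monotone local edge
  motion.
* State classification needs a full 10-s window, so the first/last frames of
  every track (and frames adjacent to gaps) are unclassified.
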