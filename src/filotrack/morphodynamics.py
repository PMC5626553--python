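"""Per-frame and per-track shape, movement and fluorescence metrics.

All geometry arrives in pixel/frame units from segmentation; this module
converts to physical units (µm, nm/s, s) using the movie calibration.

Movement metrics
----------------
* ``dL`` — change in corrected length between successive frames (µm).
* ``DCTM`` — direction-corrected tip movement: the tip displacement from
  the previous frame projected onto the current base->tip axis (nm/s). This
  discounts lateral swinging of the filopodium, so it tracks productive
  extension/retraction of the tip.
* ``DCBM`` — the same projection applied to the base displacement (base
  invasion / retraction rate).

Time series of tip/base movement are cleaned with a 0.5–99.5 percentile
filter and a centred five-step rolling mean before state classification
(extending / retracting / stalling at ±32.5 nm/s over a 10 s window, i.e.
one pixel per frame at 65 nm / 2 s calibration) and persistence estimation.
Missing frames stay missing throughout; nothing is interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters as skfilters
from statsmodels.tsa.stattools import acf as sm_acf

from .calibration import Calibration
from .errors import DegenerateSeriesError, ParameterError
from .segmentation import (SQUARE_3, FrameSegmentation, ProtrusionGeometry,
                           SegmentationParams)

#: End-correction constant: the tip quarter-circumference term pi*w/4.
#: In a closed protrusion ROI the base edge contributes +w/2 to the
#: half-perimeter while the two sides fall w/2 short of the axis length;
#: these cancel, so only the rounded tip cap inflates the estimate.
END_CORRECTION_FACTOR = math.pi / 4.0


@dataclass
class AnalysisParams:
    """Parameters of the downstream time-series analysis.

    ``state_threshold_nm_s`` is the movement magnitude separating directed
    tip/base movement from stalling; 32.5 nm/s equals one 65-nm pixel per
    2-s frame. ``state_window_s`` is the averaging window for state calls.
    """

    state_threshold_nm_s: float = 32.5
    state_window_s: float = 10.0
    rolling_window: int = 5
    percentile_low: float = 0.5
    percentile_high: float = 99.5
    new_filo_max_start_length_um: float = 2.0
    initial_window_points: int = 10
    preformation_points: int = 3
    min_series_points_ccf: int = 17
    ccf_max_lag_s: float = 6.0

    def __post_init__(self) -> None:
        if self.state_threshold_nm_s <= 0 or self.state_window_s <= 0:
            raise ParameterError("state threshold and window must be positive")
        if self.rolling_window < 1:
            raise ParameterError("rolling_window must be >= 1")

    def state_window_frames(self, calib: Calibration) -> int:
        return max(1, round(self.state_window_s / calib.frame_interval_s))


# --------------------------------------------------------------------------
# shape metrics
# --------------------------------------------------------------------------

def corrected_length(geom: ProtrusionGeometry, params: SegmentationParams,
                     calib: Calibration) -> float:
    """Corrected protrusion length in µm.

    ``length = perimeter/2 - (pi/4) * w * min[(D/w)^2, 1]`` where ``w`` is
    the FWHM width implied by the LoG scale and ``D`` the Euclidean
    base-tip distance. The quadratic ramp switches the correction off for
    blob-like protrusions whose extent is below their width.
    """
    w = params.width_px
    d = geom.euclidean_d_px
    scale = min((d / w) ** 2, 1.0) if w > 0 else 1.0
    length_px = geom.perimeter_px / 2.0 - END_CORRECTION_FACTOR * w * scale
    return calib.px_to_um(max(length_px, 0.0))


@dataclass(frozen=True)
class StraightnessResult:
    straightness: float
    waviness: float
    reliable: bool  # False for short protrusions (length < 2w)


def straightness(geom: ProtrusionGeometry, length_um: float,
                 params: SegmentationParams, calib: Calibration) -> StraightnessResult:
    """Straightness = D/length; waviness = 1 - straightness.

    Both are systematically biased for protrusions shorter than about twice
    their width; those results are flagged unreliable.
    """
    if length_um <= 0:
        return StraightnessResult(float("nan"), float("nan"), False)
    d_um = calib.px_to_um(geom.euclidean_d_px)
    s = d_um / length_um
    reliable = length_um >= 2.0 * calib.px_to_um(params.width_px)
    return StraightnessResult(s, 1.0 - s, reliable)


# --------------------------------------------------------------------------
# movement metrics
# --------------------------------------------------------------------------

def directional_movement(track, calib: Calibration) -> pd.DataFrame:
    """Per-frame dL (µm), DCTM and DCBM (nm/s) for one track.

    ``track`` must expose ``entries``: an ordered list of
    ``(frame_index, ProtrusionGeometry)``. The result is indexed by the full
    frame range of the track; frames missing from the track, the first
    frame, frames following a gap, and frames with a degenerate (tip==base)
    axis carry NaN.
    """
    entries = dict(track.entries)
    frames = sorted(entries)
    if len(frames) < 1:
        raise DegenerateSeriesError("track has no entries")
    index = range(frames[0], frames[-1] + 1)
    out = pd.DataFrame(index=pd.Index(index, name="frame"),
                       columns=["dctm_nm_s", "dcbm_nm_s"], dtype=float)
    dt = calib.frame_interval_s
    for f in frames:
        prev = entries.get(f - 1)
        cur = entries[f]
        if prev is None:
            continue
        axis = cur.tip_rc - cur.base_rc
        norm = float(np.linalg.norm(axis))
        if norm == 0:
            continue
        u = axis / norm
        tip_disp = cur.tip_rc - prev.tip_rc
        base_disp = cur.base_rc - prev.base_rc
        out.at[f, "dctm_nm_s"] = float(tip_disp @ u) * calib.pixel_size_nm / dt
        out.at[f, "dcbm_nm_s"] = float(base_disp @ u) * calib.pixel_size_nm / dt
    return out


def length_series(track, params: SegmentationParams, calib: Calibration) -> pd.Series:
    """Corrected length (µm) per frame over the track's frame range."""
    entries = dict(track.entries)
    frames = sorted(entries)
    index = pd.Index(range(frames[0], frames[-1] + 1), name="frame")
    s = pd.Series(np.nan, index=index, name="length_um")
    for f, geom in entries.items():
        s.at[f] = corrected_length(geom, params, calib)
    return s


def delta_length(lengths: pd.Series) -> pd.Series:
    """dL(T_n) = Length(T_n) - Length(T_n-1); NaN across gaps."""
    return lengths.diff()


# --------------------------------------------------------------------------
# series preprocessing and state classification
# --------------------------------------------------------------------------

def preprocess_series(series: pd.Series | Sequence[float],
                      params: AnalysisParams) -> pd.Series:
    """Percentile-filter then smooth a movement series.

    Values outside the [0.5, 99.5] percentile range of the series are
    replaced by NaN (out-of-focus frames and reconstruction errors produce
    extreme spikes), then a centred 5-point rolling mean is applied,
    ignoring NaN and truncating the window at the series ends. Positions
    that were missing on input remain missing on output.
    """
    s = pd.Series(series, dtype=float).copy()
    was_missing = s.isna()
    if s.notna().sum() > 0:
        lo = np.nanpercentile(s.values, params.percentile_low)
        hi = np.nanpercentile(s.values, params.percentile_high)
        s[(s < lo) | (s > hi)] = np.nan
    smooth = s.rolling(params.rolling_window, center=True, min_periods=1).mean()
    smooth[was_missing] = np.nan
    return smooth


TIP_STATES = ("extending", "retracting", "stalling")
BASE_STATES = ("invading", "retracting", "stable")


@dataclass
class StateClassification:
    tip_states: pd.Series        # str or NaN per frame
    base_states: pd.Series
    tip_fractions: Dict[str, float]
    base_fractions: Dict[str, float]


def _classify(series: pd.Series, window: int, thr: float,
              names: tuple[str, str, str]) -> tuple[pd.Series, Dict[str, float]]:
    win_mean = series.rolling(window, center=True, min_periods=window).mean()
    states = pd.Series(pd.NA, index=series.index, dtype=object)
    states[win_mean > thr] = names[0]
    states[win_mean < -thr] = names[1]
    states[(win_mean >= -thr) & (win_mean <= thr)] = names[2]
    classified = states.notna()
    n = int(classified.sum())
    fractions = {name: (float((states == name).sum()) / n if n else float("nan"))
                 for name in names}
    return states, fractions


def classify_states(dctm_smoothed: pd.Series, dcbm_smoothed: pd.Series,
                    params: AnalysisParams, calib: Calibration) -> StateClassification:
    """Assign per-frame tip and base movement states and time fractions.

    The smoothed movement is averaged over a centred window of
    ``state_window_s`` and compared with ±``state_threshold_nm_s``; the
    window mean requires full coverage, so edges and gap-adjacent frames
    stay unclassified. Fractions are taken over classified frames and sum
    to 1.
    """
    window = params.state_window_frames(calib)
    if dctm_smoothed.notna().sum() < window:
        raise DegenerateSeriesError(
            f"track shorter than one {params.state_window_s}-s window; "
            "no state classification"
        )
    thr = params.state_threshold_nm_s
    tip_states, tip_frac = _classify(dctm_smoothed, window, thr, TIP_STATES)
    base_states, base_frac = _classify(dcbm_smoothed, window, thr, BASE_STATES)
    return StateClassification(tip_states, base_states, tip_frac, base_frac)


@dataclass(frozen=True)
class PersistenceResult:
    seconds: float
    censored: bool  # True when the ACF never crossed zero in the data


def tip_persistence(series: pd.Series | Sequence[float], params: AnalysisParams,
                    calib: Calibration) -> PersistenceResult:
    """Time for the autocorrelation of tip movement to first reach zero.

    The (biased) sample autocorrelation of the mean-subtracted series is
    scanned for its first non-positive value; the crossing is located by
    linear interpolation between lags and converted to seconds. When no
    crossing occurs within the available lags, the maximum lag is returned
    flagged as censored. The conventional input is the percentile-filtered,
    rolling-mean-smoothed tip movement series.
    """
    x = pd.Series(series, dtype=float).dropna().values
    if len(x) < 2 * params.rolling_window:
        raise DegenerateSeriesError("series too short for persistence estimate")
    if np.allclose(x, x[0]):
        raise DegenerateSeriesError("zero-variance series: persistence undefined")
    nlags = len(x) - 1
    rho = sm_acf(x, nlags=nlags, fft=True)
    below = np.nonzero(rho <= 0)[0]
    if below.size == 0:
        return PersistenceResult(calib.frames_to_s(nlags), censored=True)
    k = int(below[0])
    lag = (k - 1) + rho[k - 1] / (rho[k - 1] - rho[k]) if k > 0 else 0.0
    return PersistenceResult(calib.frames_to_s(float(lag)), censored=False)


# --------------------------------------------------------------------------
# fluorescence
# --------------------------------------------------------------------------

@dataclass
class FluorescenceMeasures:
    proj_mean: float
    base_mean: float
    tip_mean: float
    tip_thresh_mean: float
    body_mean: float
    background: float
    normalized_tip: float
    normalized_base: float


def _disk_mask(shape: tuple[int, int], center_rc: np.ndarray, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius ** 2


def background_annulus(seg: FrameSegmentation, start_px: int = 2,
                       width_px: int = 3) -> np.ndarray:
    """Ring of pixels outside the whole cell mask, ``start_px`` to
    ``start_px + width_px`` pixels from it (background reference region)."""
    cell = seg.body_mask | (seg.protrusion_labels > 0)
    inner = ndimage.binary_dilation(cell, structure=SQUARE_3, iterations=start_px)
    outer = ndimage.binary_dilation(cell, structure=SQUARE_3,
                                    iterations=start_px + width_px)
    return outer & ~inner


def measure_fluorescence(seg: FrameSegmentation, geom: ProtrusionGeometry,
                         measurement_image: np.ndarray) -> FluorescenceMeasures:
    """Mean fluorescence in the protrusion, base, tip and body regions.

    Tip and base regions are disks of radius ``geom.tip_radius_px``. The tip
    thresholded mean keeps only pixels above the Otsu threshold computed
    inside the tip disk (separates tip signal from background when the disk
    overhangs unlabelled area). Background is the mean in an annulus just
    outside the cell; normalised values are
    ``(x - background) / (body - background)`` and NaN when the body does
    not exceed background.
    """
    img = np.asarray(measurement_image, dtype=float)
    pmask = tuple(geom.pixels.T)
    proj_mean = float(img[pmask].mean())
    body_mean = float(img[seg.body_mask].mean())
    tip_disk = _disk_mask(img.shape, geom.tip_rc, geom.tip_radius_px)
    base_disk = _disk_mask(img.shape, geom.base_rc, geom.tip_radius_px)
    tip_mean = float(img[tip_disk].mean()) if tip_disk.any() else float("nan")
    base_mean = float(img[base_disk].mean()) if base_disk.any() else float("nan")
    tip_vals = img[tip_disk]
    if tip_vals.size and np.ptp(tip_vals) > 0:
        thr = skfilters.threshold_otsu(tip_vals)
        bright = tip_vals[tip_vals > thr]
        tip_thresh_mean = float(bright.mean()) if bright.size else tip_mean
    else:
        tip_thresh_mean = tip_mean
    bg_mask = background_annulus(seg)
    background = float(img[bg_mask].mean()) if bg_mask.any() else float("nan")
    denom = body_mean - background
    if not np.isfinite(denom) or denom <= 0:
        norm_tip = norm_base = float("nan")
    else:
        norm_tip = (tip_thresh_mean - background) / denom
        norm_base = (base_mean - background) / denom
    return FluorescenceMeasures(proj_mean, base_mean, tip_mean, tip_thresh_mean,
                                body_mean, background, norm_tip, norm_base)


def predicted_base_fluorescence(
    track,
    segs: Sequence[FrameSegmentation],
    measurement_images: Sequence[np.ndarray],
    seg_params: SegmentationParams,
    params: AnalysisParams,
) -> tuple[pd.DataFrame, float]:
    """Back-propagate a new filopodium's base and read pre-formation signal.

    Starting from the base at the formation frame ``t0``, each earlier
    frame's predicted base is the boundary point closest to the (predicted)
    base of the following frame, walked back for up to ``base_back_frames``
    frames. A base-sized disk ROI is measured there and normalised against
    that frame's body/background. Returns the per-frame table and the
    pre-formation summary: the mean normalised value over the last
    ``preformation_points`` frames before ``t0``.
    """
    frames = sorted(dict(track.entries))
    t0 = frames[0]
    if t0 == 0:
        raise DegenerateSeriesError(
            "track starts on the first movie frame: formation not observed, "
            "no base prediction possible"
        )
    geom0 = dict(track.entries)[t0]
    radius = geom0.tip_radius_px
    pos = geom0.base_rc.copy()
    rows = []
    first = max(0, t0 - seg_params.base_back_frames)
    for f in range(t0 - 1, first - 1, -1):
        boundary = segs[f].boundary
        d2 = np.sum((boundary - pos) ** 2, axis=1)
        pos = boundary[int(np.argmin(d2))].astype(float)
        img = np.asarray(measurement_images[f], dtype=float)
        disk = _disk_mask(img.shape, pos, radius)
        base_mean = float(img[disk].mean()) if disk.any() else float("nan")
        body_mean = float(img[segs[f].body_mask].mean())
        bg_mask = background_annulus(segs[f])
        background = float(img[bg_mask].mean()) if bg_mask.any() else float("nan")
        denom = body_mean - background
        norm = (base_mean - background) / denom if denom > 0 else float("nan")
        rows.append({"frame": f, "base_y": pos[0], "base_x": pos[1],
                     "base_mean": base_mean, "normalized_base": norm})
    table = pd.DataFrame(rows).sort_values("frame").reset_index(drop=True)
    last = table.tail(params.preformation_points)["normalized_base"]
    preformation = float(last.mean()) if len(last) else float("nan")
    return table, preformation


# --------------------------------------------------------------------------
# boundary profile
# --------------------------------------------------------------------------

def resample_boundary(boundary: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed boundary polygon to ``n_points`` equally spaced
    (by arc length) points, starting at the polygon's first vertex."""
    diffs = np.diff(boundary, axis=0)
    seglen = np.sqrt((diffs ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    rows = np.interp(targets, s, boundary[:, 0])
    cols = np.interp(targets, s, boundary[:, 1])
    return np.stack([rows, cols], axis=1)


def boundary_profile(
    segs: Sequence[FrameSegmentation],
    image_stack: np.ndarray,
    calib: Calibration,
    n_points: int = 100,
    sample_depth_px: float = 3.0,
    sample_radius_px: float = 2.0,
) -> pd.DataFrame:
    """Per-frame boundary intensity and local edge velocity.

    Each frame's body boundary is resampled to ``n_points``; intensity is
    the mean of a small disk placed ``sample_depth_px`` inside the boundary
    (toward the body centroid), and velocity is the temporal change of raw
    intensity at the fixed boundary coordinate divided by the frame
    interval — positive when the cell advances outward past the point.
    Velocity is NaN on the last frame.
    """
    if len(segs) < 2:
        raise ParameterError("boundary_profile needs at least 2 frames")
    image_stack = np.asarray(image_stack, dtype=float)
    rows = []
    for t, seg in enumerate(segs):
        pts = resample_boundary(seg.boundary, n_points)
        centroid = np.argwhere(seg.body_mask).mean(axis=0)
        for k, p in enumerate(pts):
            inward = centroid - p
            nrm = np.linalg.norm(inward)
            sample = p + (inward / nrm * sample_depth_px if nrm > 0 else 0.0)
            disk = _disk_mask(image_stack.shape[1:], sample, sample_radius_px)
            intensity = float(image_stack[t][disk].mean()) if disk.any() else float("nan")
            pr, pc = int(round(p[0])), int(round(p[1]))
            pr = np.clip(pr, 0, image_stack.shape[1] - 1)
            pc = np.clip(pc, 0, image_stack.shape[2] - 1)
            if t + 1 < len(segs):
                velocity = (image_stack[t + 1, pr, pc] - image_stack[t, pr, pc]) \
                    / calib.frame_interval_s
            else:
                velocity = float("nan")
            rows.append({"frame": t, "point": k, "row": p[0], "col": p[1],
                         "intensity": intensity, "velocity": float(velocity)})
    return pd.DataFrame(rows)
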