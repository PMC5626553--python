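"""Ground-truthed synthetic movies and coupled time series.

The generator emulates the imaging regime the analysis is designed for: a
bright growth-cone-like body with thin, dynamic, capsule-shaped protrusions
in the mapping (membrane) channel, and tip-enriched fluorescence — optionally
with pre-formation accumulation at the future base site — in the measurement
channel. Every output is a deterministic function of (spec, seed), and the
analytic ground truth (true base/tip coordinates, lengths, velocities,
identities, coupling coefficients) is recorded before rasterisation so each
downstream stage can be scored against it.

The capsule (a rectangle capped by a semicircle at the tip) is the canonical
protrusion shape because the perimeter-based length correction is derived
from exactly that end geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import Calibration
from .errors import ParameterError, SpecError
from .timelapse import TimeLapse


# --------------------------------------------------------------------------
# rasterisation primitives
# --------------------------------------------------------------------------

def rasterize_capsule(
    shape: tuple[int, int],
    base_rc: Sequence[float],
    tip_rc: Sequence[float],
    width_px: float,
) -> np.ndarray:
    """Boolean mask of a capsule: all pixels within ``width/2`` of the
    base->tip axis segment, shortened at the tip so that the rounded cap
    ends exactly at ``tip_rc`` (the true axis length is base-to-tip)."""
    p0 = np.asarray(base_rc, float)
    p1 = np.asarray(tip_rc, float)
    r = width_px / 2.0
    axis = p1 - p0
    norm = np.linalg.norm(axis)
    if norm > r:  # pull the segment end back so the cap apex sits at tip_rc
        p1 = p0 + axis * (norm - r) / norm
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    pts = np.stack([rr, cc], axis=-1).astype(float)
    seg = p1 - p0
    seg_len2 = max(float(seg @ seg), 1e-12)
    t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    d2 = np.sum((pts - closest) ** 2, axis=-1)
    return d2 <= r ** 2


def rasterize_disk(shape: tuple[int, int], center_rc: Sequence[float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius ** 2


def gaussian_spot(shape: tuple[int, int], center_rc: Sequence[float],
                  amplitude: float, sigma: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma ** 2))


# --------------------------------------------------------------------------
# movie specification
# --------------------------------------------------------------------------

@dataclass
class FilopodiumSpec:
    """Kinetics of one synthetic filopodium.

    ``velocity_nm_s`` may be a scalar (constant tip velocity) or a per-frame
    schedule; the axis length integrates it from ``nucleation_frame``
    starting at ``initial_length_um``. ``angle_deg`` positions the base on
    the body circle; ``angular_drift_deg_per_frame`` produces lateral
    drift of the whole structure.
    """

    angle_deg: float
    nucleation_frame: int = 0
    end_frame: Optional[int] = None
    initial_length_um: float = 1.0
    velocity_nm_s: float | Sequence[float] = 0.0
    angular_drift_deg_per_frame: float = 0.0
    width_px: float = 6.0
    tip_amplitude: float = 0.0
    preformation_frames: int = 0
    preformation_amplitude: float = 0.0

    def velocity_at(self, frame: int) -> float:
        if np.isscalar(self.velocity_nm_s):
            return float(self.velocity_nm_s)
        sched = np.asarray(self.velocity_nm_s, float)
        k = frame - self.nucleation_frame
        return float(sched[min(max(k, 0), len(sched) - 1)])


@dataclass
class MovieSpec:
    """Specification of a synthetic growth-cone movie."""

    shape: tuple[int, int] = (200, 200)
    n_frames: int = 30
    pixel_size_nm: float = 65.0
    frame_interval_s: float = 2.0
    body_center: tuple[float, float] = (100.0, 100.0)
    body_radius_px: float = 30.0
    body_jitter_px: float = 0.0
    filopodia: list[FilopodiumSpec] = field(default_factory=list)
    background: float = 40.0
    body_intensity: float = 420.0
    protrusion_intensity: float = 420.0
    measurement_body_intensity: float = 220.0
    tip_spot_sigma_px: float = 2.0
    noise_sd: float = 8.0
    seed: int = 0

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_nm, self.frame_interval_s)


def _filopodium_state(spec: MovieSpec, f: FilopodiumSpec, frame: int,
                      jitter: np.ndarray) -> Optional[dict]:
    """Analytic base/tip/length of one filopodium at one frame (or None)."""
    if frame < f.nucleation_frame:
        return None
    if f.end_frame is not None and frame > f.end_frame:
        return None
    calib = spec.calibration
    length_px = calib.um_to_px(f.initial_length_um)
    for k in range(f.nucleation_frame, frame):
        length_px += calib.nm_per_s_to_px_per_frame(f.velocity_at(k + 1))
    length_px = max(length_px, f.width_px / 2.0 + 1.0)
    theta = math.radians(
        f.angle_deg + f.angular_drift_deg_per_frame * (frame - f.nucleation_frame)
    )
    u = np.array([math.sin(theta), math.cos(theta)])  # (row, col) direction
    center = np.asarray(spec.body_center, float) + jitter
    base = center + spec.body_radius_px * u
    tip = base + length_px * u
    return {
        "base_rc": base,
        "tip_rc": tip,
        "length_px": length_px,
        "velocity_nm_s": f.velocity_at(frame),
        "direction": u,
    }


def generate_movie(spec: MovieSpec) -> tuple[TimeLapse, pd.DataFrame]:
    """Render a movie and its per-frame, per-filopodium ground truth.

    Returns a two-channel :class:`TimeLapse` (channel 0 = mapping/membrane,
    channel 1 = measurement) and a ground-truth table with one row per
    (frame, filopodium) giving true base/tip coordinates, axis length and
    tip velocity.
    """
    rng = np.random.default_rng(spec.seed)
    calib = spec.calibration
    T = spec.n_frames
    H, W = spec.shape
    stack = np.zeros((T, 2, H, W), dtype=np.float32)
    truth_rows = []
    jitters = (rng.standard_normal((T, 2)) * spec.body_jitter_px
               if spec.body_jitter_px > 0 else np.zeros((T, 2)))
    for t in range(T):
        body = rasterize_disk(spec.shape, np.asarray(spec.body_center) + jitters[t],
                              spec.body_radius_px)
        mapping = np.full(spec.shape, spec.background, dtype=float)
        mapping[body] = spec.background + spec.body_intensity
        measurement = np.full(spec.shape, spec.background, dtype=float)
        measurement[body] = spec.background + spec.measurement_body_intensity
        for i, f in enumerate(spec.filopodia):
            state = _filopodium_state(spec, f, t, jitters[t])
            # pre-formation fluorescence accumulation at the future base
            if (state is None and f.preformation_frames > 0
                    and f.nucleation_frame - f.preformation_frames <= t < f.nucleation_frame):
                nasc = _filopodium_state(spec, f, f.nucleation_frame, jitters[t])
                ramp = 1.0 - (f.nucleation_frame - t - 1) / max(f.preformation_frames, 1)
                measurement += gaussian_spot(spec.shape, nasc["base_rc"],
                                             f.preformation_amplitude * ramp,
                                             spec.tip_spot_sigma_px)
            if state is None:
                continue
            tip = state["tip_rc"]
            if not (0 <= tip[0] < H and 0 <= tip[1] < W):
                raise SpecError(
                    f"filopodium {i} exits the frame at t={t} (tip at {tip})"
                )
            capsule = rasterize_capsule(spec.shape, state["base_rc"], tip, f.width_px)
            mapping[capsule] = spec.background + spec.protrusion_intensity
            if f.tip_amplitude > 0:
                measurement += gaussian_spot(spec.shape, tip, f.tip_amplitude,
                                             spec.tip_spot_sigma_px)
            truth_rows.append({
                "frame": t,
                "filopodium": i,
                "base_y": state["base_rc"][0],
                "base_x": state["base_rc"][1],
                "tip_y": tip[0],
                "tip_x": tip[1],
                "length_px": state["length_px"],
                "length_um": calib.px_to_um(state["length_px"]),
                "tip_velocity_nm_s": state["velocity_nm_s"],
            })
        if spec.noise_sd > 0:
            mapping = mapping + rng.normal(0.0, spec.noise_sd, spec.shape)
            measurement = measurement + rng.normal(0.0, spec.noise_sd, spec.shape)
        stack[t, 0] = mapping
        stack[t, 1] = measurement
    truth = pd.DataFrame(truth_rows)
    movie = TimeLapse(stack, calibration=calib, mapping_channel=0,
                      measurement_channel=1)
    return movie, truth


# --------------------------------------------------------------------------
# canonical benchmark fixture and scoring
# --------------------------------------------------------------------------

def benchmark_movie_spec(
    n_frames: int = 120,
    n_filopodia: int = 6,
    seed: int = 0,
    drift: bool = True,
    shape: tuple[int, int] = (200, 200),
) -> MovieSpec:
    """A standard test movie: several filopodia cycling through extension
    and retraction with moderate lateral drift (at most a few px/frame at
    the tip), tip-enriched measurement fluorescence, and mild noise."""
    filos = []
    for i in range(n_filopodia):
        period = 30 + 4 * i
        half = period // 2
        amp = 30.0 + 3.0 * (i % 3)
        schedule = np.tile(np.concatenate([np.full(half, amp),
                                           np.full(period - half, -amp)]),
                           n_frames // period + 2)[:n_frames]
        filos.append(FilopodiumSpec(
            angle_deg=i * 360.0 / n_filopodia,
            initial_length_um=1.9 + 0.1 * i,
            velocity_nm_s=schedule,
            angular_drift_deg_per_frame=((1.2 if i % 2 == 0 else 0.8) if drift else 0.0),
            width_px=6.0,
            tip_amplitude=150.0,
        ))
    return MovieSpec(shape=shape, n_frames=n_frames, body_radius_px=28.0,
                     filopodia=filos, noise_sd=8.0, seed=seed)


def match_to_truth(tracks, truth: pd.DataFrame,
                   max_dist_px: float = 10.0) -> pd.DataFrame:
    """Match every track entry to the nearest ground-truth filopodium.

    Returns one row per (track, frame) with the matched truth id (or -1
    when no truth tip lies within ``max_dist_px``)."""
    rows = []
    by_frame = dict(tuple(truth.groupby("frame")))
    for tr in tracks:
        for f, geom in tr.entries:
            sub = by_frame.get(f)
            match, dist = -1, np.inf
            if sub is not None:
                tips = sub[["tip_y", "tip_x"]].to_numpy()
                d = np.sqrt(((tips - geom.tip_rc) ** 2).sum(axis=1))
                j = int(np.argmin(d))
                if d[j] <= max_dist_px:
                    match, dist = int(sub.iloc[j]["filopodium"]), float(d[j])
            rows.append({"track_id": tr.track_id, "frame": f,
                         "truth_id": match, "tip_dist_px": dist})
    return pd.DataFrame(rows)


def evaluate_tracking(tracks, truth: pd.DataFrame,
                      max_dist_px: float = 10.0,
                      min_length_um: float = 0.0) -> dict:
    """Score detection and frame-to-frame link fidelity against ground truth.

    ``detection_rate``: fraction of truth (frame, filopodium) rows of length
    >= ``min_length_um`` matched by some detected protrusion.
    ``link_accuracy``: fraction of consecutive same-track entry pairs whose
    matched truth identities agree (both matched).
    """
    matches = match_to_truth(tracks, truth, max_dist_px)
    key = matches.set_index(["frame", "truth_id"])
    eligible = truth[truth["length_um"] >= min_length_um]
    detected = sum(
        (int(r["frame"]), int(r["filopodium"])) in key.index
        for _, r in eligible.iterrows()
    )
    detection_rate = detected / len(eligible) if len(eligible) else float("nan")
    m = matches.set_index(["track_id", "frame"])["truth_id"]
    correct = total = 0
    for tr in tracks:
        frames = [f for f, _ in tr.entries]
        for a, b in zip(frames, frames[1:]):
            if b != a + 1:
                continue
            ta, tb = m.at[(tr.track_id, a)], m.at[(tr.track_id, b)]
            if ta >= 0 and tb >= 0:
                total += 1
                correct += int(ta == tb)
    link_accuracy = correct / total if total else float("nan")
    return {"detection_rate": detection_rate, "link_accuracy": link_accuracy,
            "n_links_scored": total, "n_truth_rows": int(len(eligible))}


# --------------------------------------------------------------------------
# coupled time series
# --------------------------------------------------------------------------

def _standardized_ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with (population) unit variance."""
    innov_sd = math.sqrt(1.0 - phi ** 2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n) * innov_sd
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


@dataclass
class CoupledSeriesTruth:
    coupling: float
    lag_frames: int
    ar_coeff: float


def generate_coupled_series(
    n_points: int,
    coupling: float,
    ar_coeff: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    lag_frames: int = 0,
    movement_scale_nm_s: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, CoupledSeriesTruth]:
    """Generate a (fluorescence, movement) pair with known coupling.

    Movement is a standardized AR(1) with coefficient ``ar_coeff`` scaled to
    ``movement_scale_nm_s``; fluorescence is
    ``coupling * movement(t + lag_frames) + sqrt(1 - coupling^2) * e(t)``
    with ``e`` an independent AR(1) of the same coefficient, plus optional
    white observation noise. A positive ``lag_frames`` means fluorescence
    *leads* movement by that many frames (its information appears earlier),
    so the cross-correlation peak sits at a negative offset under the
    "negative offset = fluorescence precedes movement" convention.
    """
    if n_points < 17:
        raise SpecError("n_points must be >= 17 (minimum usable series length)")
    if not (0.0 <= coupling <= 1.0):
        raise SpecError("coupling must be in [0, 1]")
    if abs(ar_coeff) >= 1.0:
        raise SpecError("|ar_coeff| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    n_ext = n_points + abs(lag_frames)
    m_ext = _standardized_ar1(n_ext, ar_coeff, rng)
    e = _standardized_ar1(n_points, ar_coeff, rng)
    # fluorescence couples to movement(t + lag_frames); draw both from one
    # extended realisation so the shifted segment exists at the edges
    idx = np.arange(n_points)
    if lag_frames >= 0:
        movement = m_ext[idx]
        coupled = m_ext[idx + lag_frames]
    else:
        movement = m_ext[idx + abs(lag_frames)]
        coupled = m_ext[idx]
    fluor = coupling * coupled + math.sqrt(1.0 - coupling ** 2) * e
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, n_points)
    movement = movement * movement_scale_nm_s
    truth = CoupledSeriesTruth(coupling=coupling, lag_frames=lag_frames,
                               ar_coeff=ar_coeff)
    return fluor, movement, truth
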