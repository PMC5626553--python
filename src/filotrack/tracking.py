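"""Linking per-frame protrusions into filopodium tracks.

Frame-to-frame identity is resolved with a one-step Hungarian linear
assignment. The linking cost between a protrusion in frame ``t-1`` and a
candidate in frame ``t`` is

    cost = (dist(base1, base2) + dist(tip1, tip2)) / overlap_area * dT

so close base/tip positions and large mask overlap favour a link, and links
across larger frame gaps are penalised. Pairs with zero mask overlap are
forbidden (infinite cost surrogate). Unmatched candidates start new tracks;
unmatched previous protrusions end their tracks (optionally after a grace
period of ``max_gap`` frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .calibration import Calibration
from .errors import EditError, ParameterError
from .segmentation import ProtrusionGeometry, SegmentationParams

#: Finite stand-in for a forbidden link (keeps the assignment solver happy).
INF_COST = 1e12


# --------------------------------------------------------------------------
# cost computation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkCost:
    d_base: float
    d_tip: float
    overlap_area: int
    dT: int
    cost: float


def _overlap_area(a: ProtrusionGeometry, b: ProtrusionGeometry) -> int:
    pa = {tuple(p) for p in a.pixels}
    pb = {tuple(p) for p in b.pixels}
    return len(pa & pb)


def link_cost(prev: ProtrusionGeometry, nxt: ProtrusionGeometry, dT: int = 1) -> LinkCost:
    """Linking cost between a protrusion and a next-frame candidate."""
    if dT < 1:
        raise ParameterError("dT must be >= 1 frame")
    d_base = float(np.linalg.norm(prev.base_rc - nxt.base_rc))
    d_tip = float(np.linalg.norm(prev.tip_rc - nxt.tip_rc))
    overlap = _overlap_area(prev, nxt)
    cost = (d_base + d_tip) / overlap * dT if overlap > 0 else INF_COST
    return LinkCost(d_base, d_tip, overlap, dT, cost)


def solve_assignment(
    cost: np.ndarray,
    no_link_cost: Optional[float] = None,
) -> list[tuple[int, int]]:
    """Minimum-cost one-to-one partial assignment for a rectangular matrix.

    Birth/death is modelled by padding the matrix to square with a
    ``no_link_cost`` diagonal (default: the 95th percentile of the finite
    pair costs), so any row/column may remain unassigned at that price.
    Pairs at or above :data:`INF_COST` are never linked.
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    finite = cost[cost < INF_COST]
    if no_link_cost is None:
        no_link_cost = float(np.percentile(finite, 95)) if finite.size else 1.0
    big = np.zeros((n + m, m + n))
    big[:n, :m] = cost
    big[:n, m:] = INF_COST
    big[n:, :m] = INF_COST
    np.fill_diagonal(big[:n, m:], no_link_cost)   # track death
    np.fill_diagonal(big[n:, :m], no_link_cost)   # track birth
    rows, cols = linear_sum_assignment(big)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < n and j < m and cost[i, j] < INF_COST]


def link_frames(
    prev: Sequence[ProtrusionGeometry],
    nxt: Sequence[ProtrusionGeometry],
    dT: int | Sequence[int] = 1,
    max_cost: Optional[float] = None,
    no_link_cost: Optional[float] = None,
) -> list[tuple[int, int]]:
    """One-to-one partial assignment between two protrusion lists.

    Returns accepted ``(prev_index, next_index)`` pairs minimising total
    cost; links whose cost exceeds ``max_cost`` or whose masks do not
    overlap are rejected, and unmatched items are left for birth/death
    handling by the caller.
    """
    n, m = len(prev), len(nxt)
    if n == 0 or m == 0:
        return []
    dts = [dT] * n if np.isscalar(dT) else list(dT)
    cost = np.full((n, m), INF_COST)
    for i, g in enumerate(prev):
        for j, h in enumerate(nxt):
            cost[i, j] = link_cost(g, h, dts[i]).cost
    links = solve_assignment(cost, no_link_cost)
    if max_cost is not None:
        links = [(i, j) for i, j in links if cost[i, j] <= max_cost]
    return links


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------

@dataclass
class Track:
    """One filopodium: ordered (frame, geometry) entries plus edit history."""

    track_id: int
    entries: List[tuple[int, ProtrusionGeometry]] = field(default_factory=list)
    edit_log: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.entries]
        if frames and any(b <= a for a, b in zip(frames, frames[1:])):
            raise ParameterError("track frame indices must be strictly increasing")

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.entries]

    @property
    def start_frame(self) -> int:
        return self.entries[0][0]

    @property
    def n_frames(self) -> int:
        return len(self.entries)


@dataclass
class TrackingParams:
    max_cost: Optional[float] = None
    no_link_cost: Optional[float] = None
    max_gap: int = 0  # frames a track may pend before it is closed

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ParameterError("max_gap must be >= 0")


def build_tracks(
    frames: Sequence[Sequence[ProtrusionGeometry]],
    params: TrackingParams | None = None,
) -> list[Track]:
    """Link per-frame protrusion lists into tracks (deterministic).

    Every protrusion belongs to exactly one track; protrusions that fail to
    link start new tracks. With ``max_gap > 0`` a track that misses a frame
    stays eligible for linking for that many extra frames (gap closing);
    the default is strict one-step linking.
    """
    if len(frames) < 1:
        raise ParameterError("need at least one frame")
    params = params or TrackingParams()
    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    for t, geoms in enumerate(frames):
        geoms = list(geoms)
        candidates = [tr for tr in active
                      if t - tr.entries[-1][0] <= 1 + params.max_gap]
        prev_geoms = [tr.entries[-1][1] for tr in candidates]
        dts = [t - tr.entries[-1][0] for tr in candidates]
        links = link_frames(prev_geoms, geoms, dT=dts or 1,
                            max_cost=params.max_cost,
                            no_link_cost=params.no_link_cost)
        matched_next = set()
        for i, j in links:
            candidates[i].entries.append((t, geoms[j]))
            matched_next.add(j)
        for j, g in enumerate(geoms):
            if j not in matched_next:
                tr = Track(track_id=next_id, entries=[(t, g)])
                next_id += 1
                tracks.append(tr)
                active.append(tr)
        active = [tr for tr in active
                  if t - tr.entries[-1][0] <= params.max_gap]
    return tracks


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

@dataclass
class TrackFilterParams:
    """Thresholds separating genuine filopodia from boundary noise."""

    min_frames: int = 3
    min_start_frame: int = 0
    min_max_length_um: float = 1.8
    min_length_change_um: float = 0.1
    max_mean_waviness: float = 0.35

    def __post_init__(self) -> None:
        if min(self.min_frames, self.min_start_frame) < 0:
            raise ParameterError("frame thresholds must be >= 0")
        if min(self.min_max_length_um, self.min_length_change_um) < 0:
            raise ParameterError("length thresholds must be >= 0")
        if not (0 <= self.max_mean_waviness <= 1):
            raise ParameterError("max_mean_waviness must be in [0, 1]")


def filter_tracks(
    tracks: Iterable[Track],
    p: TrackFilterParams,
    seg_params: SegmentationParams,
    calib: Calibration,
) -> list[Track]:
    """Pure filter: keep tracks that look like real filopodia.

    Retains tracks with at least ``min_frames`` entries, appearing no
    earlier than ``min_start_frame``, reaching ``min_max_length_um``,
    showing at least one frame-to-frame length change of
    ``min_length_change_um`` (rejects static noise), and with mean waviness
    at most ``max_mean_waviness``. Output preserves input order.
    """
    from . import morphodynamics as md

    kept = []
    for tr in tracks:
        if tr.n_frames < p.min_frames:
            continue
        if tr.start_frame < p.min_start_frame:
            continue
        lengths = md.length_series(tr, seg_params, calib)
        if not (lengths.max(skipna=True) >= p.min_max_length_um):
            continue
        dl = lengths.diff().abs()
        if p.min_length_change_um > 0 and not (dl.max(skipna=True) >= p.min_length_change_um):
            continue
        wav = []
        for f, geom in tr.entries:
            res = md.straightness(geom, lengths.at[f], seg_params, calib)
            if np.isfinite(res.waviness):
                wav.append(res.waviness)
        if wav and float(np.mean(wav)) > p.max_mean_waviness:
            continue
        kept.append(tr)
    return kept


# --------------------------------------------------------------------------
# programmatic editing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackEdit:
    """One manual correction: ``delete`` a track, ``delete_range`` of frames,
    or ``relink`` the tail of one track to the head of another."""

    op: str  # "delete" | "delete_range" | "relink"
    track_id: int
    frame_from: Optional[int] = None
    frame_to: Optional[int] = None
    target_id: Optional[int] = None


def edit_tracks(tracks: Sequence[Track], edits: Sequence[TrackEdit]) -> list[Track]:
    """Apply manual edits to a track list, returning a new list.

    Each applied edit is appended to the affected track's ``edit_log``.
    Edits referencing missing tracks/frames raise :class:`EditError`, so
    replaying an already-applied deletion is rejected rather than silently
    ignored.
    """
    by_id = {tr.track_id: replace(tr, entries=list(tr.entries),
                                  edit_log=list(tr.edit_log))
             for tr in tracks}
    order = [tr.track_id for tr in tracks]
    for e in edits:
        if e.track_id not in by_id:
            raise EditError(f"edit {e} references missing track {e.track_id}")
        tr = by_id[e.track_id]
        if e.op == "delete":
            del by_id[e.track_id]
            order.remove(e.track_id)
        elif e.op == "delete_range":
            if e.frame_from is None or e.frame_to is None:
                raise EditError(f"delete_range needs frame_from/frame_to: {e}")
            before = len(tr.entries)
            tr.entries = [(f, g) for f, g in tr.entries
                          if not (e.frame_from <= f <= e.frame_to)]
            if len(tr.entries) == before:
                raise EditError(f"edit {e} removed no frames")
            if not tr.entries:
                del by_id[e.track_id]
                order.remove(e.track_id)
            else:
                tr.edit_log.append(f"delete_range {e.frame_from}-{e.frame_to}")
        elif e.op == "relink":
            if e.target_id is None or e.target_id not in by_id:
                raise EditError(f"edit {e} references missing target {e.target_id}")
            if e.frame_from is None:
                raise EditError(f"relink needs frame_from: {e}")
            tgt = by_id[e.target_id]
            head = [(f, g) for f, g in tr.entries if f <= e.frame_from]
            tail = [(f, g) for f, g in tgt.entries if f > e.frame_from]
            if not head or not tail:
                raise EditError(f"relink {e} produces an empty head or tail")
            if head[-1][0] >= tail[0][0]:
                raise EditError(f"relink {e} would create overlapping frames")
            tr.entries = head + tail
            tr.edit_log.append(
                f"relink tail of {e.track_id}@{e.frame_from} to head of {e.target_id}"
            )
            del by_id[e.target_id]
            order.remove(e.target_id)
        else:
            raise EditError(f"unknown edit op {e.op!r}")
    return [by_id[i] for i in order]


def edits_to_dataframe(edits: Sequence[TrackEdit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "op": e.op, "track_id": e.track_id,
        "frame_from": e.frame_from, "frame_to": e.frame_to,
        "target_id": e.target_id,
    } for e in edits])


def edits_from_dataframe(df: pd.DataFrame) -> list[TrackEdit]:
    def _opt(v):
        return None if pd.isna(v) else int(v)
    return [TrackEdit(op=str(r["op"]), track_id=int(r["track_id"]),
                      frame_from=_opt(r.get("frame_from")),
                      frame_to=_opt(r.get("frame_to")),
                      target_id=_opt(r.get("target_id")))
            for _, r in df.iterrows()]


def tracks_to_dataframe(tracks: Sequence[Track]) -> pd.DataFrame:
    """Long-format table: one row per (track, frame) with geometry in pixels."""
    rows = []
    for tr in tracks:
        for f, g in tr.entries:
            rows.append({
                "track_id": tr.track_id, "frame": f,
                "base_x": g.base_xy[0], "base_y": g.base_xy[1],
                "tip_x": g.tip_xy[0], "tip_y": g.tip_xy[1],
                "area_px": g.area_px, "perimeter_px": g.perimeter_px,
            })
    return pd.DataFrame(rows)
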