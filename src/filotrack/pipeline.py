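"""End-to-end pipeline: segment -> track -> filter -> (edits) -> measure -> analyze.

``run_pipeline`` processes one movie and writes the full output bundle
(label masks, boundary polygons, track and metrics tables, track summaries,
an analysis report, the resolved configuration and a plain-text log);
``run_batch`` maps it over a directory of movies and adds a combined
summary table. All randomness is drawn from the single config seed.
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dynamics, io, morphodynamics as md, tracking
from .config import PipelineConfig
from .errors import DegenerateSeriesError, FilotrackError
from .segmentation import FrameSegmentation, segment_frame
from .timelapse import TimeLapse

METRIC_UNITS = ("track_id, frame: index; time_s: s; length_um, dl_um: um; "
                "dctm_nm_s, dcbm_nm_s: nm/s; straightness, waviness: unitless; "
                "fluorescence means: image intensity; norm_tip, norm_base: ratio; "
                "base_x..tip_y: pixels")


def segment_movie(movie: TimeLapse, config: PipelineConfig) -> list[FrameSegmentation]:
    return [
        segment_frame(movie.mapping_frame(t), config.segmentation,
                      measurement_image=movie.measurement_frame(t))
        for t in range(movie.n_frames)
    ]


def track_movie(segs: Sequence[FrameSegmentation], config: PipelineConfig,
                apply_filter: bool = True) -> list[tracking.Track]:
    frames = [[seg.geometries[lab] for lab in sorted(seg.geometries)]
              for seg in segs]
    tracks = tracking.build_tracks(frames, config.tracking)
    if apply_filter:
        tracks = tracking.filter_tracks(tracks, config.filtering,
                                        config.segmentation, config.calibration)
    return tracks


def measure_tracks(
    tracks: Sequence[tracking.Track],
    segs: Sequence[FrameSegmentation],
    movie: TimeLapse,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Long-format per-frame metrics table (one row per track-frame)."""
    calib = movie.calibration
    sp = config.segmentation
    rows = []
    for tr in tracks:
        lengths = md.length_series(tr, sp, calib)
        dl = md.delta_length(lengths)
        dmov = md.directional_movement(tr, calib)
        for f, geom in tr.entries:
            length = float(lengths.at[f])
            s = md.straightness(geom, length, sp, calib)
            meas_img = movie.measurement_frame(f)
            if meas_img is not None:
                fl = md.measure_fluorescence(segs[f], geom, meas_img)
            else:
                fl = None
            rows.append({
                "track_id": tr.track_id,
                "frame": f,
                "time_s": calib.frames_to_s(f),
                "length_um": length,
                "dl_um": float(dl.at[f]),
                "dctm_nm_s": float(dmov.at[f, "dctm_nm_s"]),
                "dcbm_nm_s": float(dmov.at[f, "dcbm_nm_s"]),
                "straightness": s.straightness,
                "waviness": s.waviness,
                "proj_mean": fl.proj_mean if fl else np.nan,
                "base_mean": fl.base_mean if fl else np.nan,
                "tip_mean": fl.tip_mean if fl else np.nan,
                "tip_thresh_mean": fl.tip_thresh_mean if fl else np.nan,
                "body_mean": fl.body_mean if fl else np.nan,
                "background": fl.background if fl else np.nan,
                "norm_tip": fl.normalized_tip if fl else np.nan,
                "norm_base": fl.normalized_base if fl else np.nan,
                "base_x": geom.base_xy[0],
                "base_y": geom.base_xy[1],
                "tip_x": geom.tip_xy[0],
                "tip_y": geom.tip_xy[1],
            })
    return pd.DataFrame(rows)


def _track_frame_table(metrics: pd.DataFrame, track_id: int,
                       config: PipelineConfig) -> pd.DataFrame:
    """One track's metrics re-indexed to its full frame range, with the
    movement series preprocessed (percentile filter + rolling mean)."""
    sub = metrics[metrics["track_id"] == track_id].set_index("frame").sort_index()
    full = sub.reindex(range(sub.index.min(), sub.index.max() + 1))
    ap = config.analysis
    full["dctm_nm_s"] = md.preprocess_series(full["dctm_nm_s"], ap)
    full["dcbm_nm_s"] = md.preprocess_series(full["dcbm_nm_s"], ap)
    return full


def summarize_movie(
    metrics: pd.DataFrame,
    config: PipelineConfig,
    tracks: Optional[Sequence[tracking.Track]] = None,
    segs: Optional[Sequence[FrameSegmentation]] = None,
    movie: Optional[TimeLapse] = None,
) -> pd.DataFrame:
    """Per-track summary table, including pre-formation fluorescence for
    newly formed filopodia when segmentation context is available."""
    calib = config.calibration
    rows = []
    track_map = {tr.track_id: tr for tr in tracks} if tracks else {}
    for tid in sorted(metrics["track_id"].unique()):
        table = _track_frame_table(metrics, tid, config)
        pre = float("nan")
        tr = track_map.get(tid)
        if (tr is not None and segs is not None and movie is not None
                and movie.measurement_channel is not None and tr.start_frame > 0):
            try:
                meas = [movie.measurement_frame(t) for t in range(movie.n_frames)]
                _, pre = md.predicted_base_fluorescence(
                    tr, segs, meas, config.segmentation, config.analysis)
            except DegenerateSeriesError:
                pre = float("nan")
        summary = dynamics.summarize_track(table, config.analysis, calib,
                                           preformation_fluor=pre)
        summary["track_id"] = tid
        rows.append(summary)
    df = pd.DataFrame(rows)
    cols = ["track_id"] + [c for c in df.columns if c != "track_id"]
    return df[cols]


def analyze_movie(metrics: pd.DataFrame, config: PipelineConfig) -> dict:
    """CCF clustering plus optional null-model tests; returns a JSON-able report."""
    calib = config.calibration
    ap = config.analysis
    profiles, fluor_list, move_list, excluded = [], [], [], []
    for tid in sorted(metrics["track_id"].unique()):
        table = _track_frame_table(metrics, tid, config)
        f = table["norm_tip"].to_numpy()
        m = table["dctm_nm_s"].to_numpy()
        try:
            profiles.append(dynamics.ccf_fluorescence_movement(
                f, m, ap, calib, track_id=int(tid)))
            fluor_list.append(f)
            move_list.append(m)
        except DegenerateSeriesError as err:
            excluded.append({"track_id": int(tid), "reason": str(err)})
    report: dict = {
        "seed": config.seed,
        "n_tracks": int(metrics["track_id"].nunique()),
        "n_ccf_profiles": len(profiles),
        "excluded": excluded,
    }
    if len(profiles) >= 2:
        clus = dynamics.cluster_ccfs(profiles, n_clusters=config.n_clusters)
        report["ccf_cluster"] = {
            "labels": {int(p.track_id): int(l)
                       for p, l in zip(profiles, clus.labels)},
            "responding_label": clus.responding_label,
            "responding_size": int(len(clus.responding_indices)),
            "responding_mean_ccf0": clus.responding_mean_ccf0,
        }
        if config.run_randomization:
            try:
                rnd = dynamics.block_randomization_test(
                    fluor_list, move_list, ap, calib,
                    n_clusters=config.n_clusters,
                    block=config.randomization_block,
                    n_accepted=config.n_accepted_randomizations,
                    seed=config.seed)
                report["block_randomization"] = {
                    "observed_mean_ccf0": rnd.observed_mean_ccf0,
                    "p_value": rnd.p_value,
                    "p_resolution": rnd.p_resolution,
                    "n_accepted": rnd.n_accepted,
                    "n_attempts": rnd.n_attempts,
                }
            except FilotrackError as err:
                report["block_randomization"] = {"error": str(err)}
        if config.run_markov:
            markov = []
            for p, f, m in zip(profiles, fluor_list, move_list):
                try:
                    res = dynamics.markov_null_test(
                        f, m, n_sim=config.n_markov_simulations,
                        seed=config.seed + p.track_id + 1)
                    markov.append({"track_id": int(p.track_id),
                                   "observed_corr": res.observed_corr,
                                   "p_value": res.p_value,
                                   "z_score": res.z_score})
                except (DegenerateSeriesError, FilotrackError) as err:
                    markov.append({"track_id": int(p.track_id),
                                   "discarded": str(err)})
            report["markov_null"] = markov
        report["ccf_profiles"] = [
            {"track_id": int(p.track_id),
             "lags_s": [float(v) for v in p.lags_s],
             "values": [float(v) for v in p.values]}
            for p in profiles
        ]
    return report


def run_pipeline(config: PipelineConfig, input_path: str | Path,
                 output_dir: Optional[str | Path] = None) -> dict:
    """Process one movie end to end; returns a manifest of written files.

    On a stage failure, outputs produced so far are kept and a
    ``failure_manifest.json`` records the stage and error.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"input": str(input_path), "outputs": {}, "counts": {}}
    log_lines = [f"input: {input_path}", f"seed: {config.seed}"]
    stage = "read"
    try:
        movie = io.read_timelapse(Path(input_path), config.calibration,
                                  config.mapping_channel,
                                  config.measurement_channel, config.axes)
        log_lines.append(f"frames: {movie.n_frames}  channels: {movie.n_channels}")

        stage = "segment"
        segs = segment_movie(movie, config)
        io.write_label_masks(out / "label_masks.tif", segs)
        io.write_boundaries(out / "boundaries.csv", segs)
        manifest["outputs"]["label_masks"] = "label_masks.tif"
        manifest["outputs"]["boundaries"] = "boundaries.csv"
        n_prot = sum(len(s.geometries) for s in segs)
        manifest["counts"]["protrusions"] = n_prot
        log_lines.append(f"segmented protrusions (all frames): {n_prot}")

        stage = "track"
        tracks = track_movie(segs, config, apply_filter=False)
        log_lines.append(f"raw tracks: {len(tracks)}")
        tracks = tracking.filter_tracks(tracks, config.filtering,
                                        config.segmentation, config.calibration)
        log_lines.append(f"filtered tracks: {len(tracks)}")

        stage = "edits"
        if config.edits_file:
            edits = tracking.edits_from_dataframe(io.read_table(config.edits_file))
            tracks = tracking.edit_tracks(tracks, edits)
            log_lines.append(f"applied edits: {len(edits)}")
        io.write_table(out / "tracks.csv", tracking.tracks_to_dataframe(tracks),
                       units="coordinates: pixels; area_px: pixels^2; "
                             "perimeter_px: pixels")
        manifest["outputs"]["tracks"] = "tracks.csv"
        manifest["counts"]["tracks"] = len(tracks)

        stage = "measure"
        metrics = measure_tracks(tracks, segs, movie, config)
        io.write_table(out / "metrics.csv", metrics, units=METRIC_UNITS)
        manifest["outputs"]["metrics"] = "metrics.csv"
        manifest["counts"]["metric_rows"] = len(metrics)
        log_lines.append(f"metric rows: {len(metrics)}")

        stage = "summarize"
        if len(metrics):
            summaries = summarize_movie(metrics, config, tracks, segs, movie)
            io.write_table(out / "track_summaries.csv", summaries,
                           units="lengths: um; rates: nm/s; persistence: s; "
                                 "fractions, fluor: unitless")
            manifest["outputs"]["track_summaries"] = "track_summaries.csv"

        stage = "analyze"
        report = analyze_movie(metrics, config) if len(metrics) else {}
        (out / "analysis_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        manifest["outputs"]["analysis_report"] = "analysis_report.json"
    except Exception as err:  # keep partial outputs, record the failure
        manifest["failure"] = {"stage": stage, "error": str(err),
                               "traceback": traceback.format_exc()}
        (out / "failure_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        raise
    finally:
        config.to_yaml(out / "resolved_config.yaml")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_batch(config: PipelineConfig, input_dir: str | Path,
              output_dir: Optional[str | Path] = None) -> dict:
    """Run the pipeline over every TIFF in a directory (batch mode).

    Each movie gets its own output bundle; a combined per-track summary
    table (with a ``movie`` column) is written at the top level.
    """
    input_dir = Path(input_dir)
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    movies = sorted(p for p in input_dir.iterdir()
                    if p.suffix.lower() in (".tif", ".tiff"))
    combined = []
    manifests = {}
    for path in movies:
        sub = out / path.stem
        manifests[path.name] = run_pipeline(config, path, sub)
        summary_file = sub / "track_summaries.csv"
        if summary_file.exists():
            df = io.read_table(summary_file)
            df.insert(0, "movie", path.stem)
            combined.append(df)
    if combined:
        io.write_table(out / "combined_summaries.csv", pd.concat(combined),
                       units="lengths: um; rates: nm/s; persistence: s; "
                             "fractions, fluor: unitless")
    (out / "batch_manifest.json").write_text(
        json.dumps(manifests, indent=2, sort_keys=True))
    return manifests
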