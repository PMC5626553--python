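import math

import numpy as np
import pytest

from filotrack import AnalysisParams, Calibration, PipelineConfig, SegmentationParams
from filotrack import pipeline
from filotrack.segmentation import ProtrusionGeometry, geometry_from_mask
from filotrack.synthetic import benchmark_movie_spec, generate_movie, rasterize_capsule


@pytest.fixture(scope="session")
def calib() -> Calibration:
    return Calibration(pixel_size_nm=65.0, frame_interval_s=2.0)


@pytest.fixture()
def seg_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture()
def analysis_params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture(scope="session")
def bench():
    """Segmented + tracked 120-frame benchmark movie (6 drifting filopodia)."""
    spec = benchmark_movie_spec(n_frames=120, seed=1)
    movie, truth = generate_movie(spec)
    cfg = PipelineConfig()
    cfg.measurement_channel = 1
    segs = pipeline.segment_movie(movie, cfg)
    tracks = pipeline.track_movie(segs, cfg)
    return {"spec": spec, "movie": movie, "truth": truth, "cfg": cfg,
            "segs": segs, "tracks": tracks}


@pytest.fixture(scope="session")
def small_movie():
    """A short movie for pipeline/IO tests."""
    spec = benchmark_movie_spec(n_frames=14, n_filopodia=4, seed=7)
    movie, truth = generate_movie(spec)
    return spec, movie, truth


def analytic_geometry(base_rc, tip_rc, width_px: float = 6.0,
                      label: int = 1) -> ProtrusionGeometry:
    """Geometry with a perimeter consistent with an ideal capsule, so that
    the corrected length equals the base-tip axis length exactly."""
    base = np.asarray(base_rc, float)
    tip = np.asarray(tip_rc, float)
    d = float(np.linalg.norm(tip - base))
    perimeter = 2.0 * d + (math.pi / 2.0) * width_px
    return ProtrusionGeometry(
        label=label, area_px=max(int(d * width_px), 1), perimeter_px=perimeter,
        base_rc=base, tip_rc=tip, tip_radius_px=width_px / 2.0,
        euclidean_d_px=d, width_px=width_px,
        pixels=np.round([base, (base + tip) / 2, tip]).astype(int),
    )


def capsule_geometry(base_rc, tip_rc, width_px: float = 6.0,
                     shape=(160, 160), label: int = 1,
                     params: SegmentationParams | None = None) -> ProtrusionGeometry:
    """Geometry measured from an actual rasterised capsule mask."""
    params = params or SegmentationParams(sigma_log=width_px / (2 * math.sqrt(2 * math.log(2))))
    mask = rasterize_capsule(shape, base_rc, tip_rc, width_px)
    return geometry_from_mask(mask, base_rc, params, label=label)
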