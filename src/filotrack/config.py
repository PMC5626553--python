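"""Pipeline configuration: one object holding every stage's parameters.

The config round-trips losslessly through YAML, and every pipeline run
writes the resolved configuration next to its outputs so results are
reproducible from the output directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .calibration import Calibration
from .morphodynamics import AnalysisParams
from .segmentation import SegmentationParams
from .tracking import TrackFilterParams, TrackingParams


@dataclass
class PipelineConfig:
    calibration: Calibration = field(default_factory=Calibration)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    filtering: TrackFilterParams = field(default_factory=TrackFilterParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    mapping_channel: int = 0
    measurement_channel: Optional[int] = None
    axes: Optional[str] = None       # e.g. "TCYX"; None = infer
    output_dir: str = "filotrack_out"
    edits_file: Optional[str] = None
    n_clusters: int = 2
    run_randomization: bool = False
    run_markov: bool = False
    n_accepted_randomizations: int = 1000
    randomization_block: int = 8
    n_markov_simulations: int = 10_000
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("calibration", Calibration),
                         ("segmentation", SegmentationParams),
                         ("tracking", TrackingParams),
                         ("filtering", TrackFilterParams),
                         ("analysis", AnalysisParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
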