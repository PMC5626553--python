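"""In-memory representation of a multi-channel time-lapse stack."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calibration import Calibration
from .errors import ParameterError


@dataclass
class TimeLapse:
    """A T x C x Y x X pixel stack with calibration and channel roles.

    The *mapping* channel (a membrane marker) drives segmentation geometry;
    the optional *measurement* channel (a labelled protein) is the one whose
    fluorescence is quantified inside the segmented regions.
    """

    data: np.ndarray  # (T, C, Y, X)
    calibration: Calibration = field(default_factory=Calibration)
    mapping_channel: int = 0
    measurement_channel: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # T, Y, X -> insert singleton channel axis
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ParameterError(
                f"expected a 3D (T,Y,X) or 4D (T,C,Y,X) stack, got ndim={self.data.ndim}"
            )
        n_ch = self.data.shape[1]
        for name, idx in (("mapping", self.mapping_channel),
                          ("measurement", self.measurement_channel)):
            if idx is not None and not (0 <= idx < n_ch):
                raise ParameterError(
                    f"{name} channel index {idx} out of range; "
                    f"available channels: {list(range(n_ch))}"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def mapping_frame(self, t: int) -> np.ndarray:
        return self.data[t, self.mapping_channel]

    def measurement_frame(self, t: int) -> Optional[np.ndarray]:
        if self.measurement_channel is None:
            return None
        return self.data[t, self.measurement_channel]
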