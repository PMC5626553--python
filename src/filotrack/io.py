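"""Readers and writers: TIFF stacks, label masks, CSV tables.

Every CSV table starts with a ``#``-prefixed header comment declaring its
units, and floats are written with a fixed format so identical runs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .calibration import Calibration
from .errors import ParameterError
from .segmentation import FrameSegmentation
from .timelapse import TimeLapse

FLOAT_FORMAT = "%.9g"


def read_timelapse(
    path: str | Path,
    calibration: Calibration,
    mapping_channel: int = 0,
    measurement_channel: Optional[int] = None,
    axes: Optional[str] = None,
) -> TimeLapse:
    """Read a multi-page TIFF into a normalised T x C x Y x X stack.

    3D stacks are treated as single-channel (T, Y, X). For 4D stacks the
    axis order must be resolvable: either the TIFF metadata provides it, or
    ``axes`` must be given explicitly ("TCYX" or "CTYX").
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_axes = tf.series[0].axes if tf.series else ""
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim == 3:
        return TimeLapse(data[:, None, :, :], calibration=calibration,
                         mapping_channel=mapping_channel,
                         measurement_channel=measurement_channel)
    if data.ndim != 4:
        raise ParameterError(f"cannot interpret {data.ndim}-D TIFF {path}")
    order = axes or meta_axes
    if sorted(order) != sorted("TCYX"):
        raise ParameterError(
            f"ambiguous 4D axes {order!r} in {path}; pass axes='TCYX' or 'CTYX'")
    if order == "CTYX":
        data = np.moveaxis(data, 0, 1)
    elif order != "TCYX":
        raise ParameterError(f"unsupported axis order {order!r}; use TCYX or CTYX")
    return TimeLapse(data, calibration=calibration,
                     mapping_channel=mapping_channel,
                     measurement_channel=measurement_channel)


def write_timelapse(path: str | Path, movie: TimeLapse) -> None:
    tifffile.imwrite(Path(path), movie.data.astype(np.float32),
                     metadata={"axes": "TCYX"})


def write_label_masks(path: str | Path, segs: Sequence[FrameSegmentation]) -> None:
    """Per-frame label masks: 0 background, 1 body, label+1 per protrusion."""
    stack = []
    for seg in segs:
        lab = np.zeros(seg.body_mask.shape, dtype=np.uint16)
        lab[seg.body_mask] = 1
        pr = seg.protrusion_labels
        lab[pr > 0] = (pr[pr > 0] + 1).astype(np.uint16)
        stack.append(lab)
    tifffile.imwrite(Path(path), np.stack(stack), metadata={"axes": "TYX"})


def write_boundaries(path: str | Path, segs: Sequence[FrameSegmentation]) -> None:
    rows = []
    for t, seg in enumerate(segs):
        for k, (r, c) in enumerate(seg.boundary):
            rows.append((t, k, c, r))
    df = pd.DataFrame(rows, columns=["frame", "vertex_index", "x", "y"])
    write_table(path, df, units="frame: index; vertex_index: index; x, y: pixels")


def write_table(path: str | Path, df: pd.DataFrame, units: str = "") -> None:
    """Write a CSV with a leading '# units:' comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if units:
            fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
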