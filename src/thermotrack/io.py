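"""Thermal frame data model and raster I/O.

Frames are 2-D temperature rasters in degrees Celsius. On disk a sequence is
a multi-page 16-bit unsigned TIFF plus a JSON sidecar holding the linear
quantization (``temperature = raw * scale + offset``) and per-frame metadata
(frame indices, altitudes). Temperatures are held internally as floats;
quantization exists only at the file boundary. Plain-text whitespace grids
are accepted for small fixtures.

Pixel coordinates are (row, col), 0-based, row 0 at top, throughout the
package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

__all__ = ["ThermalFrame", "FrameSequence", "read_frames", "write_frames"]


@dataclass
class ThermalFrame:
    """A single calibrated thermal frame.

    Parameters
    ----------
    values : ndarray of shape (height, width)
        Temperatures in degrees Celsius. Must be finite.
    frame_index : int
        Position of the frame in its recording; non-negative.
    altitude : float, optional
        Camera altitude above ground in meters.
    timestamp : float, optional
        Acquisition time in seconds.
    """

    values: np.ndarray
    frame_index: int = 0
    altitude: float | None = None
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("frame values must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame contains non-finite temperatures")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class FrameSequence:
    """An ordered recording of frames with strictly increasing indices."""

    frames: list[ThermalFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            return
        shape = self.frames[0].values.shape
        for prev, cur in zip(self.frames, self.frames[1:]):
            if cur.frame_index <= prev.frame_index:
                raise ValueError(
                    "frame indices must be strictly increasing "
                    f"({prev.frame_index} then {cur.frame_index})"
                )
        for f in self.frames:
            if f.values.shape != shape:
                raise ValueError("all frames in a sequence must share height/width")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[ThermalFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> ThermalFrame:
        return self.frames[i]

    @property
    def altitudes(self) -> list[float | None]:
        return [f.altitude for f in self.frames]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_frames(path: str | Path) -> FrameSequence:
    """Read a frame sequence from a TIFF+sidecar container or a text grid.

    ``.tif``/``.tiff`` files need a JSON sidecar ``<stem>.json`` with keys
    ``scale``, ``offset``, ``frame_index`` and optionally ``altitude``.
    ``.txt`` files hold a single whitespace-separated temperature grid and
    need no sidecar.
    """
    path = Path(path)
    if path.suffix == ".txt":
        values = np.loadtxt(path, ndmin=2)
        return FrameSequence([ThermalFrame(values=values, frame_index=0)])
    if path.suffix not in (".tif", ".tiff"):
        raise ValueError(f"unsupported raster container: {path.suffix!r}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar: expected {sidecar} next to {path}"
        )
    meta = json.loads(sidecar.read_text())
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None]
    scale = float(meta["scale"])
    offset = float(meta["offset"])
    indices = [int(i) for i in meta["frame_index"]]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError("sidecar frame_index is not strictly increasing")
    altitudes = meta.get("altitude")
    if altitudes is None:
        altitudes = [None] * len(indices)
    frames = [
        ThermalFrame(
            values=page.astype(float) * scale + offset,
            frame_index=idx,
            altitude=None if alt is None else float(alt),
        )
        for page, idx, alt in zip(raw, indices, altitudes)
    ]
    return FrameSequence(frames)


def write_frames(seq: FrameSequence, path: str | Path) -> None:
    """Write a sequence as 16-bit TIFF pages plus a JSON sidecar.

    The scale/offset are chosen to span the sequence's temperature range, so
    the round-trip error is at most half the quantization step
    ``(max - min) / 65535``.
    """
    if len(seq) == 0:
        raise ValueError("cannot write an empty sequence")
    path = Path(path)
    stack = np.stack([f.values for f in seq.frames])
    lo = float(stack.min())
    hi = float(stack.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    raw = np.round((stack - lo) / scale).astype(np.uint16)
    tifffile.imwrite(path, raw, photometric="minisblack")
    meta = {
        "scale": scale,
        "offset": lo,
        "frame_index": [f.frame_index for f in seq.frames],
        "altitude": [f.altitude for f in seq.frames],
    }
    _sidecar_path(path).write_text(json.dumps(meta))
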