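"""Per-frame hot-object detection.

Hot objects are pixels strictly warmer than a threshold adapted to each
frame: the median frame temperature plus a constant offset ``c``. The median
makes the threshold robust to the hot objects themselves, so the same ``c``
works across scenes whose absolute background temperature differs.
Above-threshold pixels are grouped into connected components (blobs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ThermalFrame

__all__ = [
    "DetectionParams",
    "Blob",
    "dynamic_threshold",
    "segment",
    "extract_blobs",
    "detect",
]


@dataclass
class DetectionParams:
    """Detector configuration.

    ``c`` is the offset in degrees Celsius added to the frame median
    (default 5, the operating point used throughout); ``min_area`` discards
    components smaller than the given pixel count; ``connectivity`` is 4 or 8
    for component grouping.
    """

    c: float = 5.0
    min_area: int = 2
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class Blob:
    """A connected set of hot pixels in one frame."""

    rows: np.ndarray
    cols: np.ndarray
    frame_index: int = 0
    peak_temp: float = float("nan")

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def pixels(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        return (
            int(self.rows.min()),
            int(self.cols.min()),
            int(self.rows.max()),
            int(self.cols.max()),
        )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Full-frame boolean mask of this blob."""
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m

    def to_dict(self) -> dict:
        r0, c0, r1, c1 = self.bounding_box
        return {
            "frame_index": self.frame_index,
            "area": self.area,
            "centroid": list(self.centroid),
            "bbox": [r0, c0, r1, c1],
            "peak_temp": self.peak_temp,
            "rows": self.rows.tolist(),
            "cols": self.cols.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Blob":
        return cls(
            rows=np.asarray(d["rows"], dtype=int),
            cols=np.asarray(d["cols"], dtype=int),
            frame_index=int(d["frame_index"]),
            peak_temp=float(d["peak_temp"]),
        )


def dynamic_threshold(frame: ThermalFrame, c: float = 5.0) -> float:
    """Median frame temperature plus the offset ``c`` (degrees Celsius).

    For an even pixel count the median is the mean of the two central order
    statistics.
    """
    return float(np.median(frame.values)) + c


def segment(frame: ThermalFrame, threshold: float) -> np.ndarray:
    """Boolean mask of pixels strictly warmer than ``threshold``."""
    return frame.values > threshold


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def extract_blobs(
    mask: np.ndarray, frame: ThermalFrame, params: DetectionParams | None = None
) -> list[Blob]:
    """Connected components of ``mask`` with area >= ``min_area``.

    Blobs are sorted by the (min_row, min_col) of their bounding boxes;
    ``peak_temp`` is the maximum temperature over the blob.
    """
    params = params or DetectionParams()
    if mask.shape != frame.values.shape:
        raise ValueError("mask and frame shapes differ")
    labels, n = ndimage.label(mask, structure=_STRUCTURES[params.connectivity])
    blobs = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < params.min_area:
            continue
        blobs.append(
            Blob(
                rows=rows,
                cols=cols,
                frame_index=frame.frame_index,
                peak_temp=float(frame.values[rows, cols].max()),
            )
        )
    blobs.sort(key=lambda b: (b.bounding_box[0], b.bounding_box[1]))
    return blobs


def detect(frame: ThermalFrame, params: DetectionParams | None = None) -> list[Blob]:
    """Threshold a frame dynamically and return its blobs."""
    params = params or DetectionParams()
    th = dynamic_threshold(frame, params.c)
    return extract_blobs(segment(frame, th), frame, params)
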