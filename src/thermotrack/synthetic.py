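"""Synthetic thermal scenes with ground truth.

The generator emulates the study conditions the pipeline was designed for:
top-view frames of a grass field at 15–23 °C background with per-pixel
Gaussian sensor noise, containing warm animals, uniformly hot lamps
(halogen-spotlight distractors) and shallow warm molehills. Object pixel
footprints follow the inverse-square law in altitude, referenced to a
305-pixel footprint at 5 m for a 0.05 m² animal; sub-pixel coverage mixes
object and background temperature so small high-altitude objects fade
rather than vanish abruptly.

Radial temperature profiles (additive over background, °C):

* animal — steep rise across a thin boundary shell of width ``shell_width``
  onto a gently tilted core plateau; the tilt keeps the contour-mean
  signature strictly increasing toward the center, matching the
  edge-concentrated gradient of real insulated animals.
* lamp — uniform hot disk; its signature is flat from the first interior
  contour on.
* molehill — shallow wide linear cone, a sun-warmed soil mound.

Besides the geometric footprint loss, the apparent temperature contrast of
real objects falls with sensor distance (less radiation reaches the
sensor). That is emulated by the optional ``contrast_decay`` scene
parameter: the core offset of every object decays exponentially with
altitude above the reference altitude. It is off by default and switched on
for altitude-sweep experiments, where high-altitude observations must be
genuinely ambiguous.

All outputs are pure functions of the spec and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .classify import ANIMAL, NON_ANIMAL, TrainingSet
from .detection import Blob, DetectionParams, detect
from .io import FrameSequence, ThermalFrame
from .signatures import blob_features

__all__ = [
    "ObjectSpec",
    "SceneSpec",
    "GroundTruthObject",
    "GroundTruthTrack",
    "generate_scene",
    "generate_sequence",
    "generate_training_set",
    "generate_evaluation_set",
    "random_animal",
    "random_lamp",
    "random_molehill",
]

#: Inverse-square footprint reference: a 0.05 m² animal covers 305 px at 5 m.
REF_FOOTPRINT_PX = 305.0
REF_ALTITUDE_M = 5.0

_CLASSES = (ANIMAL, "lamp", "molehill")


@dataclass
class ObjectSpec:
    """One rendered hot object.

    ``area_px`` is the pixel footprint at the scene's reference altitude;
    the rendered footprint scales with (reference_altitude / altitude)².
    ``core_offset`` is the peak temperature above background in °C.
    ``shell_width`` (animal only) is the boundary-gradient width in pixels.
    ``velocity`` is (d_row, d_col) pixels per frame.
    """

    object_class: str
    center: tuple[float, float]
    area_px: float = REF_FOOTPRINT_PX
    core_offset: float = 12.0
    shell_width: float = 1.5
    velocity: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.object_class not in _CLASSES:
            raise ValueError(f"unknown object class {self.object_class!r}")
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")
        if self.core_offset <= 0:
            raise ValueError("core_offset must be positive")

    @property
    def label(self) -> str:
        return ANIMAL if self.object_class == ANIMAL else NON_ANIMAL


@dataclass
class SceneSpec:
    """A full scene: frame geometry, background, objects and altitude."""

    shape: tuple[int, int] = (240, 320)
    background_temp: float = 19.0
    noise_sd: float = 0.3
    objects: list[ObjectSpec] = field(default_factory=list)
    altitude: float = REF_ALTITUDE_M
    reference_altitude: float = REF_ALTITUDE_M
    contrast_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.altitude <= 0 or self.reference_altitude <= 0:
            raise ValueError("altitudes must be positive")
        if self.contrast_decay < 0:
            raise ValueError("contrast_decay must be >= 0")

    @property
    def contrast_factor(self) -> float:
        """Multiplier on every core offset at this scene's altitude."""
        excess = max(0.0, self.altitude - self.reference_altitude)
        return math.exp(-self.contrast_decay * excess)


@dataclass
class GroundTruthObject:
    """Rendered-object truth for one frame."""

    object_class: str
    label: str
    centroid: tuple[float, float]
    radius: float
    rows: np.ndarray
    cols: np.ndarray

    @property
    def area(self) -> int:
        return int(self.rows.size)


@dataclass
class GroundTruthTrack:
    """Per-frame positions of one object through a sequence."""

    object_index: int
    object_class: str
    label: str
    frames: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    radii: list[float] = field(default_factory=list)


def _scaled_radius(obj: ObjectSpec, spec: SceneSpec) -> float:
    area = obj.area_px * (spec.reference_altitude / spec.altitude) ** 2
    return math.sqrt(area / math.pi)


def _profile(obj: ObjectSpec, r: np.ndarray, radius: float) -> np.ndarray:
    """Additive temperature at radial distance r (°C over background)."""
    rel = np.clip(r / radius, 0.0, 1.0)
    if obj.object_class == ANIMAL:
        shell = np.clip((radius - r) / obj.shell_width, 0.0, 1.0)
        tilt = 0.9 + 0.1 * (1.0 - rel)
        return obj.core_offset * shell * tilt
    if obj.object_class == "lamp":
        return np.full_like(r, obj.core_offset)
    # molehill: linear cone
    return obj.core_offset * (1.0 - rel)


def _render_object(
    values: np.ndarray, obj: ObjectSpec, center: tuple[float, float], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Add one object to ``values``; returns its ground-truth pixel arrays."""
    h, w = values.shape
    r0 = max(0, int(math.floor(center[0] - radius - 1)))
    r1 = min(h, int(math.ceil(center[0] + radius + 2)))
    c0 = max(0, int(math.floor(center[1] - radius - 1)))
    c1 = min(w, int(math.ceil(center[1] + radius + 2)))
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dist = np.hypot(rr - center[0], cc - center[1])
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    values[r0:r1, c0:c1] += _profile(obj, dist, radius) * coverage
    inside = coverage >= 0.5
    return rr[inside].ravel(), cc[inside].ravel()


def _check_layout(spec: SceneSpec) -> list[float]:
    radii = [_scaled_radius(o, spec) for o in spec.objects]
    h, w = spec.shape
    for obj, rad in zip(spec.objects, radii):
        r, c = obj.center
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"object center {obj.center} outside the frame")
    for i in range(len(spec.objects)):
        for j in range(i + 1, len(spec.objects)):
            ci, cj = spec.objects[i].center, spec.objects[j].center
            if math.hypot(ci[0] - cj[0], ci[1] - cj[1]) < radii[i] + radii[j] + 4:
                raise ValueError(
                    f"objects {i} and {j} overlap at altitude {spec.altitude} m"
                )
    return radii


def generate_scene(
    spec: SceneSpec, frame_index: int = 0, rng: np.random.Generator | None = None
) -> tuple[ThermalFrame, list[GroundTruthObject]]:
    """Render one frame and its ground truth.

    Objects whose center lies outside the frame are silently dropped (they
    have left the field of view); overlapping objects raise, since the
    emulated scenes are sparse.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    radii = _check_layout(spec)
    values = np.full(spec.shape, spec.background_temp, dtype=float)
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    truth = []
    factor = spec.contrast_factor
    for obj, radius in zip(spec.objects, radii):
        if factor != 1.0:
            obj = replace(obj, core_offset=obj.core_offset * factor)
        rows, cols = _render_object(values, obj, obj.center, radius)
        truth.append(
            GroundTruthObject(
                object_class=obj.object_class,
                label=obj.label,
                centroid=obj.center,
                radius=radius,
                rows=rows,
                cols=cols,
            )
        )
    frame = ThermalFrame(values=values, frame_index=frame_index,
                         altitude=spec.altitude)
    return frame, truth


def generate_sequence(
    spec: SceneSpec,
    n_frames: int,
    altitude_profile: Sequence[float] | None = None,
) -> tuple[FrameSequence, list[GroundTruthTrack]]:
    """Render a sequence with moving objects and an altitude profile.

    Objects advance by their velocity each frame; footprints rescale with
    altitude. Ground-truth tracks record each object's per-frame centroid
    and are truncated when the object leaves the frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if altitude_profile is None:
        altitude_profile = [spec.altitude] * n_frames
    if len(altitude_profile) != n_frames:
        raise ValueError("altitude_profile length must equal n_frames")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    frames = []
    tracks = [
        GroundTruthTrack(object_index=i, object_class=o.object_class, label=o.label)
        for i, o in enumerate(spec.objects)
    ]
    for n in range(n_frames):
        alt = float(altitude_profile[n])
        visible = []
        vis_idx = []
        for i, obj in enumerate(spec.objects):
            r = obj.center[0] + obj.velocity[0] * n
            c = obj.center[1] + obj.velocity[1] * n
            if 0 <= r < h and 0 <= c < w:
                visible.append(replace(obj, center=(r, c)))
                vis_idx.append(i)
        frame_spec = replace(spec, objects=visible, altitude=alt)
        frame, truth = generate_scene(frame_spec, frame_index=n, rng=rng)
        frames.append(frame)
        for i, gt in zip(vis_idx, truth):
            tracks[i].frames.append(n)
            tracks[i].centroids.append(gt.centroid)
            tracks[i].radii.append(gt.radius)
    return FrameSequence(frames), tracks


def random_animal(rng: np.random.Generator,
                  center: tuple[float, float]) -> ObjectSpec:
    """An animal with realistic footprint and coat-limited surface warmth."""
    return ObjectSpec(
        object_class=ANIMAL,
        center=center,
        area_px=rng.uniform(200.0, 420.0),
        core_offset=rng.uniform(8.0, 15.0),
        shell_width=rng.uniform(1.0, 3.0),
    )


def random_lamp(rng: np.random.Generator,
                center: tuple[float, float]) -> ObjectSpec:
    """A halogen spotlight: small, very hot, uniform."""
    return ObjectSpec(
        object_class="lamp",
        center=center,
        area_px=rng.uniform(60.0, 160.0),
        core_offset=rng.uniform(25.0, 60.0),
    )


def random_molehill(rng: np.random.Generator,
                    center: tuple[float, float]) -> ObjectSpec:
    """A sun-warmed soil mound: wide, shallow, gently graded."""
    return ObjectSpec(
        object_class="molehill",
        center=center,
        area_px=rng.uniform(300.0, 700.0),
        core_offset=rng.uniform(5.5, 8.0),
    )


def _random_scene_conditions(rng: np.random.Generator,
                             altitude_range: tuple[float, float]) -> dict:
    return {
        "background_temp": rng.uniform(15.0, 23.0),
        "noise_sd": rng.uniform(0.2, 0.4),
        "altitude": rng.uniform(*altitude_range),
    }


def generate_training_set(
    n_animal: int = 140,
    n_nonanimal: int = 359,
    seed: int = 0,
    altitude_range: tuple[float, float] = (3.0, 8.0),
    n_coeff: int = 7,
    detection: DetectionParams | None = None,
    contrast_decay: float = 0.0,
    max_retries: int = 20,
) -> TrainingSet:
    """Labeled feature vectors from randomized single-object scenes.

    Each vector comes from rendering one object in a random scene, running
    detection and the full signature/DCT pipeline on the blob nearest the
    object's true center. Undetected renders are resampled a bounded number
    of times. Non-animal scenes alternate lamps and molehills. The default
    class counts are 140 animal and 359 non-animal vectors — the non-animal
    class is more heterogeneous and gets more data.
    """
    if n_animal < 1 or n_nonanimal < 1:
        raise ValueError("class counts must be >= 1")
    rng = np.random.default_rng(seed)
    detection = detection or DetectionParams()
    X, y = [], []
    queue = [ANIMAL] * n_animal + ["lamp", "molehill"] * (n_nonanimal // 2 + 1)
    queue = queue[: n_animal + n_nonanimal]
    factories = {ANIMAL: random_animal, "lamp": random_lamp,
                 "molehill": random_molehill}
    for cls in queue:
        blob = None
        for _ in range(max_retries):
            cond = _random_scene_conditions(rng, altitude_range)
            center = (rng.uniform(60, 180), rng.uniform(80, 240))
            obj = factories[cls](rng, center)
            spec = SceneSpec(objects=[obj], seed=int(rng.integers(2**31)),
                             contrast_decay=contrast_decay, **cond)
            frame, truth = generate_scene(spec)
            blob = _nearest_blob(detect(frame, detection), truth[0])
            if blob is not None:
                break
        if blob is None:
            raise RuntimeError(
                f"could not render a detectable {cls} in {max_retries} tries"
            )
        fv = blob_features(frame, blob, n_coeff=n_coeff)
        X.append(fv.coefficients)
        y.append(ANIMAL if cls == ANIMAL else NON_ANIMAL)
    return TrainingSet(X=np.vstack(X), y=np.array(y))


def generate_evaluation_set(
    n_per_class: int,
    seed: int = 0,
    altitude_range: tuple[float, float] = (3.0, 8.0),
    n_coeff: int = 7,
    detection: DetectionParams | None = None,
    contrast_decay: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature vectors of whatever the detector finds at a given altitude.

    Renders ``n_per_class`` scenes per object class and keeps only the
    detected ones — unlike :func:`generate_training_set` it does not resample
    misses, so at high altitude faint classes thin out exactly as they do in
    real sweeps. Returns (X, labels, altitudes) for the detected objects.
    """
    rng = np.random.default_rng(seed)
    detection = detection or DetectionParams()
    factories = {ANIMAL: random_animal, "lamp": random_lamp,
                 "molehill": random_molehill}
    X, y, alts = [], [], []
    for cls in (ANIMAL, "lamp", "molehill"):
        for _ in range(n_per_class):
            cond = _random_scene_conditions(rng, altitude_range)
            center = (rng.uniform(60, 180), rng.uniform(80, 240))
            obj = factories[cls](rng, center)
            spec = SceneSpec(objects=[obj], seed=int(rng.integers(2**31)),
                             contrast_decay=contrast_decay, **cond)
            frame, truth = generate_scene(spec)
            blob = _nearest_blob(detect(frame, detection), truth[0])
            if blob is None:
                continue
            X.append(blob_features(frame, blob, n_coeff=n_coeff).coefficients)
            y.append(ANIMAL if cls == ANIMAL else NON_ANIMAL)
            alts.append(cond["altitude"])
    if X:
        return np.vstack(X), np.array(y), np.array(alts)
    return np.empty((0, n_coeff)), np.array([]), np.array([])


def _nearest_blob(blobs: list[Blob], gt: GroundTruthObject,
                  slack: float = 4.0) -> Blob | None:
    """The detected blob closest to a ground-truth object, if close enough."""
    best, best_d = None, float("inf")
    for b in blobs:
        r, c = b.centroid
        d = math.hypot(r - gt.centroid[0], c - gt.centroid[1])
        if d < best_d:
            best, best_d = b, d
    if best is not None and best_d <= gt.radius + slack:
        return best
    return None
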