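"""End-to-end pipeline: detection → features → kNN → tracking.

Glues the per-frame stages together over a whole recording and returns both
the per-frame kNN decisions and the track-level decisions, so the gain from
temporal aggregation can be measured directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .classify import ThermalKNNClassifier, TrainingSet
from .detection import DetectionParams, detect
from .io import FrameSequence
from .signatures import blob_features
from .synthetic import GroundTruthTrack
from .tracking import Track, Tracker, TrackerParams

__all__ = ["DetectionRecord", "PipelineResult", "run_pipeline", "match_truth"]


@dataclass
class DetectionRecord:
    """One detection with its per-frame and track-level classifications."""

    frame_index: int
    centroid: tuple[float, float]
    area: int
    altitude: float | None
    g_a: float
    knn_label: str
    track_id: int | None = None
    track_label: str | None = None
    true_label: str | None = None


@dataclass
class PipelineResult:
    records: list[DetectionRecord] = field(default_factory=list)
    tracks: list[Track] = field(default_factory=list)


def run_pipeline(
    seq: FrameSequence,
    training: TrainingSet | ThermalKNNClassifier,
    detection: DetectionParams | None = None,
    tracker_params: TrackerParams | None = None,
    k: int = 11,
    n_coeff: int = 7,
) -> PipelineResult:
    """Run the full recognition pipeline over a frame sequence.

    Each frame is thresholded and its blobs classified by kNN; the
    vote fraction g_A of each blob feeds the tracker, which links
    detections across frames and accumulates the animal belief. After the
    last frame every track is identified and its final label propagated
    back to all member detections.
    """
    detection = detection or DetectionParams()
    clf = (training.classifier(k=k) if isinstance(training, TrainingSet)
           else training)
    tracker = Tracker(tracker_params)
    result = PipelineResult()
    per_frame: list[list[DetectionRecord]] = []
    for frame in seq:
        blobs = detect(frame, detection)
        records = []
        dets = []
        for blob in blobs:
            fv = blob_features(frame, blob, n_coeff=n_coeff)
            g_a = float(clf.vote_fraction(fv.coefficients[None, :])[0])
            knn_label = clf.predict(fv.coefficients[None, :])[0]
            rec = DetectionRecord(
                frame_index=frame.frame_index,
                centroid=blob.centroid,
                area=blob.area,
                altitude=frame.altitude,
                g_a=g_a,
                knn_label=str(knn_label),
            )
            records.append(rec)
            dets.append((blob.centroid, g_a))
        tracker.step(frame.frame_index, dets)
        per_frame.append(records)
        result.records.extend(records)
    result.tracks = tracker.finalize()

    member_map = {
        (m.frame_index, round(m.centroid[0], 6), round(m.centroid[1], 6)): t
        for t in result.tracks
        for m in t.members
    }
    for rec in result.records:
        key = (rec.frame_index, round(rec.centroid[0], 6), round(rec.centroid[1], 6))
        track = member_map.get(key)
        if track is not None:
            rec.track_id = track.id
            rec.track_label = track.final_label
    return result


def match_truth(
    result: PipelineResult,
    truth_tracks: list[GroundTruthTrack],
    slack: float = 4.0,
) -> list[DetectionRecord]:
    """Attach ground-truth labels to detections by nearest true object.

    A detection is matched to the ground-truth object whose centroid in the
    same frame is nearest and within that object's radius plus ``slack``
    pixels; unmatched detections keep ``true_label=None``. Returns the
    matched records only.
    """
    by_frame: dict[int, list[tuple[tuple[float, float], float, str]]] = {}
    for t in truth_tracks:
        for f, c, r in zip(t.frames, t.centroids, t.radii):
            by_frame.setdefault(f, []).append((c, r, t.label))
    matched = []
    for rec in result.records:
        best_label, best_d = None, float("inf")
        for c, r, label in by_frame.get(rec.frame_index, []):
            d = math.hypot(rec.centroid[0] - c[0], rec.centroid[1] - c[1])
            if d < best_d and d <= r + slack:
                best_label, best_d = label, d
        if best_label is not None:
            rec.true_label = best_label
            matched.append(rec)
    return matched
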