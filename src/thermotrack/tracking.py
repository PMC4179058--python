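"""Multi-frame tracking with recursive Bayesian belief accumulation.

Detections are linked across frames with a lightweight gating tracker: each
active track predicts a guess region — a disk whose center extrapolates the
track's last movement and whose radius is a fixed gate — and a detection may
join a track only inside that region. Every accepted detection updates the
track's belief that the tracked object is an animal via Bayes' rule

    Bel(n) = Bel(n-1) * g / (Bel(n-1) * g + (1 - Bel(n-1)) * (1 - g))

where ``g`` is the kNN animal-vote fraction clamped into [0.05, 0.95] so the
belief can never get stuck at 0 or 1. In log-odds the update is additive, so
the final belief depends only on the multiset of likelihoods, not their
order. A new track starts at the indifferent prior 0.5 and a track ends when
it misses more than a fixed number of consecutive frames. After a track is
identified, all of its member detections inherit the final label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import ANIMAL, NON_ANIMAL, clamp_likelihood

__all__ = [
    "GuessRegion",
    "TrackerParams",
    "TrackMember",
    "Track",
    "Tracker",
    "predict_guess_region",
    "associate_frame",
    "update_belief",
    "identify_track",
]


@dataclass
class GuessRegion:
    """Gating disk within which a detection may join a track."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def contains(self, point: tuple[float, float]) -> bool:
        dr = point[0] - self.center[0]
        dc = point[1] - self.center[1]
        return float(np.hypot(dr, dc)) <= self.radius


@dataclass
class TrackerParams:
    """Tracker configuration.

    ``radius`` is the gate in pixels (default 190, the maximum positional
    uncertainty tolerated between consecutive frames); ``max_missed`` is the
    number of missing points a track survives (default 3); tracks with at
    most ``min_track_points`` members are flagged unidentified for
    evaluation (default 5, i.e. a track needs more than five points).
    """

    radius: float = 190.0
    max_missed: int = 3
    min_track_points: int = 5
    prior: float = 0.5
    clamp_bounds: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie strictly inside (0, 1)")


@dataclass
class TrackMember:
    frame_index: int
    centroid: tuple[float, float]
    g_a: float
    label: str
    belief: float


@dataclass
class Track:
    """Linked detections with a belief history."""

    id: int
    members: list[TrackMember] = field(default_factory=list)
    missed: int = 0
    status: str = "active"
    final_label: str | None = None
    identified: bool = True

    @property
    def belief(self) -> float:
        return self.members[-1].belief

    @property
    def belief_history(self) -> list[float]:
        return [m.belief for m in self.members]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "members": [
                {
                    "frame": m.frame_index,
                    "row": m.centroid[0],
                    "col": m.centroid[1],
                    "g_a": m.g_a,
                    "belief": m.belief,
                    "label": m.label,
                }
                for m in self.members
            ],
            "final_label": self.final_label,
            "status": self.status,
            "identified": self.identified,
        }


def update_belief(bel_prev: float, g_a: float) -> float:
    """One Bayes step combining the previous belief with a new likelihood."""
    num = bel_prev * g_a
    return num / (num + (1.0 - bel_prev) * (1.0 - g_a))


def predict_guess_region(track: Track, params: TrackerParams) -> GuessRegion:
    """Extrapolate the last movement; a one-member track predicts in place."""
    if not track.members:
        raise ValueError("track has no members")
    last = np.asarray(track.members[-1].centroid, dtype=float)
    if len(track.members) >= 2:
        prev = np.asarray(track.members[-2].centroid, dtype=float)
        center = last + (last - prev)
    else:
        center = last
    return GuessRegion(center=(float(center[0]), float(center[1])),
                       radius=params.radius)


def _append_detection(
    track: Track, frame_index: int, centroid, g_a: float, params: TrackerParams
) -> None:
    lo, hi = params.clamp_bounds
    g = clamp_likelihood(g_a, lo, hi)
    prev = track.members[-1].belief if track.members else params.prior
    bel = update_belief(prev, g)
    label = ANIMAL if g_a > 0.5 else NON_ANIMAL
    track.members.append(
        TrackMember(frame_index=frame_index, centroid=tuple(map(float, centroid)),
                    g_a=float(g_a), label=label, belief=bel)
    )
    track.missed = 0


def associate_frame(
    tracks: list[Track],
    frame_index: int,
    detections: Sequence[tuple[tuple[float, float], float]],
    params: TrackerParams | None = None,
    next_id: int | None = None,
) -> list[Track]:
    """Assign one frame's detections to tracks and age the rest.

    Detections are (centroid, g_A) pairs from a single frame later than all
    existing members. Greedy nearest-pair assignment: among all
    (track, detection) pairs with distance from the track's predicted center
    at most the gate radius, repeatedly commit the globally closest pair,
    one detection per track per frame. Unmatched detections open new tracks
    at the prior belief; tracks receiving nothing increment their missed
    counter and terminate once it exceeds ``max_missed``. Returns ``tracks``
    with any new tracks appended.
    """
    params = params or TrackerParams()
    active = [t for t in tracks if t.status == "active"]
    for t in active:
        if t.members and t.members[-1].frame_index >= frame_index:
            raise ValueError("detections must come from a frame after every track")

    centers = [predict_guess_region(t, params).center for t in active]
    pairs = []
    for ti, center in enumerate(centers):
        for di, (centroid, _g) in enumerate(detections):
            d = float(np.hypot(centroid[0] - center[0], centroid[1] - center[1]))
            if d <= params.radius:
                pairs.append((d, ti, di))
    pairs.sort()  # distance, then track order, then detection order

    used_tracks: set[int] = set()
    used_dets: set[int] = set()
    for d, ti, di in pairs:
        if ti in used_tracks or di in used_dets:
            continue
        used_tracks.add(ti)
        used_dets.add(di)
        centroid, g_a = detections[di]
        _append_detection(active[ti], frame_index, centroid, g_a, params)

    for ti, t in enumerate(active):
        if ti not in used_tracks:
            t.missed += 1
            if t.missed > params.max_missed:
                t.status = "terminated"

    if next_id is None:
        next_id = max((t.id for t in tracks), default=-1) + 1
    for di, (centroid, g_a) in enumerate(detections):
        if di in used_dets:
            continue
        t = Track(id=next_id)
        next_id += 1
        _append_detection(t, frame_index, centroid, g_a, params)
        tracks.append(t)
    return tracks


def identify_track(track: Track, params: TrackerParams | None = None) -> str:
    """Finalize a track's label from its last belief and relabel members.

    Animal iff the final belief strictly exceeds 0.5. Tracks with at most
    ``min_track_points`` members are flagged unidentified (their label is
    still computed, but evaluation may exclude them).
    """
    params = params or TrackerParams()
    label = ANIMAL if track.belief > 0.5 else NON_ANIMAL
    track.final_label = label
    for m in track.members:
        m.label = label
    track.identified = len(track.members) > params.min_track_points
    return label


class Tracker:
    """Stateful frame-by-frame tracker over a whole recording."""

    def __init__(self, params: TrackerParams | None = None):
        self.params = params or TrackerParams()
        self.tracks: list[Track] = []
        self._next_id = 0

    def step(
        self,
        frame_index: int,
        detections: Sequence[tuple[tuple[float, float], float]],
    ) -> None:
        associate_frame(self.tracks, frame_index, detections, self.params,
                        next_id=self._next_id)
        self._next_id = max((t.id for t in self.tracks), default=-1) + 1

    def finalize(self) -> list[Track]:
        """End the recording: terminate and identify every track."""
        for t in self.tracks:
            t.status = "terminated"
            identify_track(t, self.params)
        return self.tracks
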