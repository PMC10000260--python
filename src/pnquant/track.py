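"""Pronucleus tracking: frame filtering, sexing, and label stability.

Raw per-frame detections become two sex-labelled area trajectories per
embryo in four steps, mirroring how an embryologist audits a time-lapse
sequence:

1. *Abandonment* — frames whose detection count differs from exactly two
   (0, 1, 3 or more pronuclei) are discarded; vacuole overcalls and
   overlap-merged frames fall out here.
2. *Identity linking* — the two detections are linked across frames by
   nearest-centroid matching (per-frame PN displacement is much smaller
   than the inter-PN distance).
3. *Sexing* — the male pronucleus appears earlier than the female; when
   appearance times cannot separate them, the male is the larger one in
   the early zygote stage.  Embryos where both rules tie are excluded as
   indistinguishable.
4. *Label stability* — for each consecutive frame pair the cosine of the
   angle between the female->male centre vectors must stay positive
   (cos(theta) > 0); a non-positive cosine means the labels flipped, and
   the later frame's labels are swapped (or the frame discarded if both
   labelings fail, e.g. exactly perpendicular vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import PNDetection

__all__ = [
    "TrackFrame",
    "EmbryoTrack",
    "Trajectory",
    "IndistinguishablePNError",
    "filter_two_pn_frames",
    "assign_sex",
    "enforce_label_stability",
    "build_area_trajectories",
    "track_embryo",
    "track_to_frame",
]


class IndistinguishablePNError(ValueError):
    """Neither appearance time nor early size separates the two PNs."""


@dataclass
class TrackFrame:
    """One retained frame holding exactly two linked detections.

    ``detections`` is ordered by track identity: after sexing, index 0 is
    the female PN and index 1 the male PN.
    """

    frame_index: int
    time_h: float
    detections: list[PNDetection]

    def __post_init__(self) -> None:
        if len(self.detections) != 2:
            raise ValueError("a retained frame must hold exactly 2 detections")


@dataclass
class EmbryoTrack:
    embryo_id: str
    frames: list[TrackFrame] = field(default_factory=list)
    discarded_frames: list[tuple[int, str]] = field(default_factory=list)
    sexed: bool = False
    swap_events: list[int] = field(default_factory=list)
    analyzable: bool = True


@dataclass
class Trajectory:
    """Time-ordered area series (um^2) for one pronucleus of one embryo."""

    embryo_id: str
    sex: str
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")
        if any(a <= 0 for _, a in self.points):
            raise ValueError("trajectory areas must be positive")

    @property
    def times_h(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([a for _, a in self.points])

    def __len__(self) -> int:
        return len(self.points)


def _center(d: PNDetection) -> np.ndarray:
    return np.asarray(d.center_px, dtype=float)


def filter_two_pn_frames(
    detections: Sequence[PNDetection], *, min_retained_frames: int = 4
) -> EmbryoTrack:
    """Apply the abandonment rule and link PN identities across frames.

    Frames with a PN count other than 2 are logged to
    ``discarded_frames`` with the count as the reason (e.g. ``"3PN"``).
    The two detections of each retained frame are ordered consistently
    across frames by nearest-centroid matching.  Embryos with fewer than
    ``min_retained_frames`` retained frames are flagged unanalyzable.

    If every retained frame carries provisional female/male labels (one
    of each, e.g. from an upstream per-frame sexing model or a manual
    ``sex_override`` column), those labels define the per-frame order
    (female first) and the track comes back already ``sexed`` — the
    cosine-stability step then audits the provisional labels.
    """
    if not detections:
        return EmbryoTrack(embryo_id="", analyzable=False)
    embryo_id = detections[0].embryo_id
    by_frame: dict[int, list[PNDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame_index, []).append(d)

    track = EmbryoTrack(embryo_id=embryo_id)
    prev: list[np.ndarray] | None = None
    n_labelled = 0
    for fi in sorted(by_frame):
        dets = by_frame[fi]
        if len(dets) != 2:
            track.discarded_frames.append((fi, f"{len(dets)}PN"))
            continue
        if {d.sex for d in dets} == {"female", "male"}:
            dets = sorted(dets, key=lambda d: d.sex)  # female before male
            n_labelled += 1
        else:
            # canonical initial order (sorted by centre) keeps the outcome
            # independent of detection input order
            dets = sorted(dets, key=lambda d: d.center_px)
            if prev is not None:
                straight = np.linalg.norm(_center(dets[0]) - prev[0]) + np.linalg.norm(
                    _center(dets[1]) - prev[1]
                )
                crossed = np.linalg.norm(_center(dets[0]) - prev[1]) + np.linalg.norm(
                    _center(dets[1]) - prev[0]
                )
                if crossed < straight:
                    dets = [dets[1], dets[0]]
        track.frames.append(TrackFrame(fi, dets[0].time_h, list(dets)))
        prev = [_center(dets[0]), _center(dets[1])]

    if len(track.frames) < min_retained_frames:
        track.analyzable = False
    if track.frames and n_labelled == len(track.frames):
        track.sexed = True
    return track


def assign_sex(
    track: EmbryoTrack,
    appearance_times_h: tuple[float, float] | None = None,
    *,
    early_window: int = 3,
    frame_interval_h: float = 0.25,
) -> EmbryoTrack:
    """Label the two PN identities female/male.

    ``appearance_times_h`` gives the first-seen time of track identity 0
    and 1 (typically derived from the pre-2PN frames).  If the appearance
    times differ by at least one frame interval, the earlier PN is male;
    otherwise the PN with the larger mean area over the first
    ``early_window`` retained frames is male.  A tie on both rules raises
    :class:`IndistinguishablePNError` (such embryos are excluded).
    """
    if not track.frames:
        raise ValueError("cannot sex an empty track")

    male_idx: int | None = None
    if appearance_times_h is not None:
        t0, t1 = appearance_times_h
        if abs(t0 - t1) >= frame_interval_h:
            male_idx = 0 if t0 < t1 else 1
    if male_idx is None:
        early = track.frames[:early_window]
        mean0 = float(np.mean([f.detections[0].area_um2 for f in early]))
        mean1 = float(np.mean([f.detections[1].area_um2 for f in early]))
        if mean0 == mean1:
            raise IndistinguishablePNError(
                f"embryo {track.embryo_id}: equal appearance times and equal "
                f"early mean areas ({mean0:.3f} um^2)"
            )
        male_idx = 0 if mean0 > mean1 else 1

    for frame in track.frames:
        if male_idx == 0:
            frame.detections = [frame.detections[1], frame.detections[0]]
        frame.detections[0].sex = "female"
        frame.detections[1].sex = "male"
    track.sexed = True
    return track


def _female_to_male(frame: TrackFrame) -> np.ndarray:
    return _center(frame.detections[1]) - _center(frame.detections[0])


def _cos(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    return float(np.dot(u, v) / (nu * nv))


def enforce_label_stability(track: EmbryoTrack) -> EmbryoTrack:
    """Enforce cos(theta) > 0 between consecutive female->male vectors.

    Walks the retained frames in order; whenever the cosine between the
    previous frame's female->male vector and the current one is not
    strictly positive, the current frame's labels are swapped and the pair
    re-evaluated.  Frames that fail under both labelings (cosine exactly
    zero) are discarded with reason ``"stability"``; frames with
    coincident PN centres are discarded with reason ``"coincident"``.
    Swapped frame indices are recorded in ``swap_events``.
    """
    if not track.sexed:
        raise ValueError("track must be sexed before stability enforcement")
    if len(track.frames) < 2:
        return track

    kept: list[TrackFrame] = []
    prev_vec: np.ndarray | None = None
    for frame in track.frames:
        vec = _female_to_male(frame)
        if np.linalg.norm(vec) == 0:
            track.discarded_frames.append((frame.frame_index, "coincident"))
            continue
        if prev_vec is None:
            kept.append(frame)
            prev_vec = vec
            continue
        c = _cos(prev_vec, vec)
        if c <= 0:
            # swapping the frame's labels negates the vector
            if -c > 0:
                frame.detections = [frame.detections[1], frame.detections[0]]
                frame.detections[0].sex = "female"
                frame.detections[1].sex = "male"
                track.swap_events.append(frame.frame_index)
                vec = -vec
            else:  # cos(theta) == 0 under both labelings
                track.discarded_frames.append((frame.frame_index, "stability"))
                continue
        kept.append(frame)
        prev_vec = vec
    track.frames = kept
    return track


def build_area_trajectories(track: EmbryoTrack) -> tuple[Trajectory, Trajectory]:
    """Emit (female, male) area trajectories from a sexed, stable track."""
    if not track.frames:
        raise ValueError(f"embryo {track.embryo_id}: no retained frames")
    if not track.sexed:
        raise ValueError("track must be sexed")
    female = Trajectory(
        track.embryo_id,
        "female",
        [(f.time_h, f.detections[0].area_um2) for f in track.frames],
    )
    male = Trajectory(
        track.embryo_id,
        "male",
        [(f.time_h, f.detections[1].area_um2) for f in track.frames],
    )
    return female, male


def track_embryo(
    detections: Sequence[PNDetection],
    appearance_times_h: tuple[float, float] | None = None,
    *,
    min_retained_frames: int = 4,
    early_window: int = 3,
    frame_interval_h: float = 0.25,
) -> tuple[EmbryoTrack, Trajectory, Trajectory]:
    """Run the full tracking chain on one embryo's detections."""
    track = filter_two_pn_frames(detections, min_retained_frames=min_retained_frames)
    if not track.analyzable:
        raise ValueError(
            f"embryo {track.embryo_id or '?'}: fewer than {min_retained_frames} "
            "retained 2PN frames; unanalyzable"
        )
    if not track.sexed:  # provisionally labelled tracks arrive sexed
        assign_sex(
            track,
            appearance_times_h,
            early_window=early_window,
            frame_interval_h=frame_interval_h,
        )
    enforce_label_stability(track)
    female, male = build_area_trajectories(track)
    return track, female, male


def track_to_frame(track: EmbryoTrack) -> pd.DataFrame:
    """Tabulate a track (one row per PN per retained frame)."""
    rows = []
    for f in track.frames:
        for d in f.detections:
            rows.append(
                {
                    "embryo_id": track.embryo_id,
                    "frame_index": f.frame_index,
                    "time_h": f.time_h,
                    "sex": d.sex,
                    "x_px": d.center_px[0],
                    "y_px": d.center_px[1],
                    "area_um2": d.area_um2,
                    "swapped": f.frame_index in track.swap_events,
                }
            )
    return pd.DataFrame(rows)
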