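"""Contact-phase kinetics of tracked cells.

A tracked cell's trajectory is split into three behavioral phases around a
contact episode with a partner cell: Ph1 before contact, Ph2 during direct
contact, Ph3 after the contact ends. Per-phase velocities (total
displacement over elapsed time, um/s) yield a deceleration ratio
v(Ph2) / v(Ph1); a ratio <= 0.2 marks a >= 5-fold slow-down on engagement,
the signature of stable immune-synapse formation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from tnkit.config import ConfigurationError

logger = logging.getLogger(__name__)

CellType = Literal["T", "NK"]


@dataclass(frozen=True)
class TrackPoint:
    frame: int
    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)
                and math.isfinite(self.t)):
            raise ValueError("track point coordinates and time must be finite")


@dataclass(frozen=True)
class Track:
    """Time-ordered positions of one cell."""

    track_id: str
    cell_type: str
    points: tuple[TrackPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"track {self.track_id} needs >= 2 points")
        frames = [p.frame for p in self.points]
        times = [p.t for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(f"track {self.track_id}: frames must increase")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.track_id}: times must increase")

    @property
    def frames(self) -> list[int]:
        return [p.frame for p in self.points]

    def point_at(self, frame: int) -> TrackPoint:
        for p in self.points:
            if p.frame == frame:
                return p
        raise KeyError(f"track {self.track_id} has no frame {frame}")

    def index_of(self, frame: int) -> int:
        for i, p in enumerate(self.points):
            if p.frame == frame:
                return i
        raise KeyError(f"track {self.track_id} has no frame {frame}")


@dataclass(frozen=True)
class ContactInterval:
    """Inclusive frame range over which two cells are in direct contact."""

    focal_id: str
    partner_id: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("contact interval start must be <= end")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


FrameRange = Optional[tuple[int, int]]  # inclusive (start, end), None = empty


@dataclass(frozen=True)
class PhaseSegmentation:
    """Ph1/Ph2/Ph3 frame ranges for one track (inclusive ends).

    ph1 and ph3 may be None (empty) when the contact touches the track's
    first or last frame; such segmentations are flagged for exclusion from
    ratio statistics.
    """

    ph1: FrameRange
    ph2: tuple[int, int]
    ph3: FrameRange

    @property
    def ph1_empty(self) -> bool:
        return self.ph1 is None

    @property
    def ph3_empty(self) -> bool:
        return self.ph3 is None


@dataclass(frozen=True)
class KineticsResult:
    track_id: str
    v_ph1: Optional[float]
    v_ph2: float
    v_ph3: Optional[float]
    deceleration_ratio: Optional[float]


def detect_contacts(
    track_a: Track,
    track_b: Track,
    contact_distance: float,
    min_frames: int = 2,
) -> list[ContactInterval]:
    """Find maximal runs of consecutive common frames within contact range.

    Two cells are in contact at a frame when their centroid distance is at
    most ``contact_distance``. Runs shorter than ``min_frames`` are
    discarded; runs separated by any non-contact frame are distinct.
    """
    if min_frames < 1:
        raise ConfigurationError("min_frames must be >= 1")
    common = sorted(set(track_a.frames) & set(track_b.frames))
    if not common:
        raise ValueError(
            f"tracks {track_a.track_id} and {track_b.track_id} share no frames")

    intervals: list[ContactInterval] = []
    run_start: Optional[int] = None
    prev_frame: Optional[int] = None

    def close_run(end: int) -> None:
        if run_start is not None and end - run_start + 1 >= min_frames:
            intervals.append(ContactInterval(
                track_a.track_id, track_b.track_id, run_start, end))

    for f in common:
        pa, pb = track_a.point_at(f), track_b.point_at(f)
        in_contact = math.hypot(pa.x - pb.x, pa.y - pb.y) <= contact_distance
        contiguous = prev_frame is not None and f == prev_frame + 1
        if in_contact:
            if run_start is None or not contiguous:
                if run_start is not None:
                    close_run(prev_frame)  # type: ignore[arg-type]
                run_start = f
        else:
            if run_start is not None:
                close_run(prev_frame)  # type: ignore[arg-type]
                run_start = None
        prev_frame = f
    if run_start is not None:
        close_run(prev_frame)  # type: ignore[arg-type]
    return intervals


def segment_phases(track: Track, interval: ContactInterval) -> PhaseSegmentation:
    """Partition a track's frame span into Ph1 / Ph2 / Ph3 around a contact.

    Ph1 covers frames strictly before the contact, Ph2 the contact interval
    itself, Ph3 frames strictly after; together they tile the track span
    contiguously. A Ph1 (or Ph3) touching the span boundary comes back as
    None and the cell is flagged for exclusion from ratio statistics.
    """
    frames = track.frames
    first, last = frames[0], frames[-1]
    if interval.start_frame < first or interval.end_frame > last:
        raise ValueError("contact interval lies outside the track span")
    ph1 = (first, interval.start_frame - 1) if interval.start_frame > first else None
    ph3 = (interval.end_frame + 1, last) if interval.end_frame < last else None
    if ph1 is None:
        logger.info("track %s: contact starts at first frame; Ph1 empty",
                    track.track_id)
    return PhaseSegmentation(ph1=ph1, ph2=(interval.start_frame,
                                           interval.end_frame), ph3=ph3)


class PhaseTooShortError(ValueError):
    """Phase has fewer than two frames, so no velocity is defined."""


def phase_velocity(
    track: Track,
    phase: tuple[int, int],
    mode: str = "path",
) -> float:
    """Mean velocity over a phase: total displacement / elapsed time (um/s).

    ``mode='path'`` (default) accumulates successive step displacements;
    ``mode='net'`` uses the straight-line start-to-end displacement.
    """
    if mode not in ("path", "net"):
        raise ConfigurationError(f"unknown velocity mode {mode!r}")
    start, end = phase
    pts = [p for p in track.points if start <= p.frame <= end]
    if len(pts) < 2:
        raise PhaseTooShortError(
            f"phase ({start}, {end}) of track {track.track_id} has "
            f"{len(pts)} point(s); velocity undefined")
    elapsed = pts[-1].t - pts[0].t
    if mode == "path":
        disp = sum(math.hypot(b.x - a.x, b.y - a.y)
                   for a, b in zip(pts, pts[1:]))
    else:
        disp = math.hypot(pts[-1].x - pts[0].x, pts[-1].y - pts[0].y)
    return disp / elapsed


def deceleration_ratio(v_ph1: float, v_ph2: float) -> float:
    """Contact-phase over pre-contact mean velocity; <= 0.2 means >= 5-fold
    slow-down."""
    if v_ph1 <= 0:
        raise ValueError("deceleration ratio undefined for v_ph1 <= 0")
    if v_ph2 < 0:
        raise ValueError("velocities must be non-negative")
    return v_ph2 / v_ph1


def rank_by_deceleration(
    results: Iterable[KineticsResult],
) -> list[tuple[int, KineticsResult]]:
    """Order results by ascending ratio (ties by track_id); 1-based index."""
    results = list(results)
    if any(r.deceleration_ratio is None for r in results):
        raise ValueError("all deceleration ratios must be defined for ranking")
    ordered = sorted(results,
                     key=lambda r: (r.deceleration_ratio, r.track_id))
    return [(i + 1, r) for i, r in enumerate(ordered)]


def analyze_track(
    focal: Track,
    partners: Sequence[Track],
    contact_distance: float,
    min_contact_frames: int = 2,
    mode: str = "path",
) -> Optional[KineticsResult]:
    """Kinetics of one focal cell against a set of candidate partners.

    All contact episodes with any partner are pooled; Ph2 is the longest
    episode (ties broken by earliest start, then partner id). Returns None
    when the cell never makes contact, or when Ph1 is empty / has zero
    velocity (ratio undefined; logged and excluded upstream).
    """
    episodes: list[ContactInterval] = []
    for partner in partners:
        if not set(focal.frames) & set(partner.frames):
            continue
        episodes.extend(detect_contacts(focal, partner, contact_distance,
                                        min_contact_frames))
    if not episodes:
        return None
    episodes.sort(key=lambda e: (-e.n_frames, e.start_frame, e.partner_id))
    seg = segment_phases(focal, episodes[0])

    v_ph2 = phase_velocity(focal, seg.ph2, mode)
    v_ph1 = v_ph3 = None
    if seg.ph1 is not None:
        try:
            v_ph1 = phase_velocity(focal, seg.ph1, mode)
        except PhaseTooShortError:
            v_ph1 = None
    if seg.ph3 is not None:
        try:
            v_ph3 = phase_velocity(focal, seg.ph3, mode)
        except PhaseTooShortError:
            v_ph3 = None

    ratio = None
    if v_ph1 is None or v_ph1 == 0:
        logger.info("track %s excluded from ratio statistics (Ph1 %s)",
                    focal.track_id,
                    "empty" if v_ph1 is None else "has zero velocity")
    else:
        ratio = deceleration_ratio(v_ph1, v_ph2)
    return KineticsResult(focal.track_id, v_ph1, v_ph2, v_ph3, ratio)


def analyze_cohort(
    tracks: Sequence[Track],
    contact_distance: float,
    min_contact_frames: int = 2,
    mode: str = "path",
    focal_type: str = "T",
    partner_type: str = "NK",
) -> pd.DataFrame:
    """Full kinetics pipeline over a cohort of tracks.

    For every focal-type track, detects contact episodes with all
    partner-type tracks, segments phases around the longest episode,
    computes per-phase velocities and the deceleration ratio, and ranks
    cells by increasing ratio.

    Returns a DataFrame (track_id, v_ph1, v_ph2, v_ph3, ratio, rank) with
    NaN ratio/rank for excluded cells, sorted by rank then track_id.
    """
    focals = [t for t in tracks if t.cell_type == focal_type]
    partners = [t for t in tracks if t.cell_type == partner_type]
    rows = []
    for focal in focals:
        res = analyze_track(focal, partners, contact_distance,
                            min_contact_frames, mode)
        if res is not None:
            rows.append(res)
    ranked = rank_by_deceleration(
        [r for r in rows if r.deceleration_ratio is not None])
    rank_of = {r.track_id: i for i, r in ranked}
    df = pd.DataFrame(
        [{
            "track_id": r.track_id,
            "v_ph1": np.nan if r.v_ph1 is None else r.v_ph1,
            "v_ph2": r.v_ph2,
            "v_ph3": np.nan if r.v_ph3 is None else r.v_ph3,
            "ratio": (np.nan if r.deceleration_ratio is None
                      else r.deceleration_ratio),
            "rank": rank_of.get(r.track_id, np.nan),
        } for r in rows],
        columns=["track_id", "v_ph1", "v_ph2", "v_ph3", "ratio", "rank"],
    )
    return df.sort_values(["rank", "track_id"],
                          na_position="last").reset_index(drop=True)
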