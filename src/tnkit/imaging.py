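"""Segmentation, centroid tracking, and membrane-transfer quantification.

Cell boundaries are defined from each population's fluorescence channel by
thresholding (Otsu by default) followed by 8-connected component labeling.
Centroids are linked across frames by a greedy nearest-first assignment to
recover tracks, and membrane transfer is quantified as the count of
above-threshold donor-channel pixels falling inside each recipient cell's
mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential

from tnkit.config import ConfigurationError
from tnkit.tracking import Track, TrackPoint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelImage:
    """Integer-labeled segmentation of one frame (0 = background)."""

    labels: np.ndarray  # int array, H x W

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def areas(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels[self.labels > 0],
                                 return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass(frozen=True)
class TransferQuant:
    """Per-recipient transferred-pixel counts for one frame."""

    counts: dict[int, int]      # label -> above-threshold donor pixels
    areas: dict[int, int]       # label -> recipient area (px)

    def total(self) -> int:
        return sum(self.counts.values())


def segment_channel(
    frame: np.ndarray,
    threshold_method: str = "otsu",
    min_area: int = 0,
    fixed_threshold: Optional[float] = None,
) -> LabelImage:
    """Threshold one channel and label 8-connected components.

    Components smaller than ``min_area`` pixels are discarded, and the
    survivors are relabeled 1..n in raster-scan order of first occurrence.
    A blank (constant) frame yields zero labels.
    """
    if frame.ndim != 2:
        raise ValueError("segment_channel expects a single 2D channel")
    if threshold_method == "otsu":
        if np.all(frame == frame.flat[0]):
            return LabelImage(np.zeros(frame.shape, dtype=np.int32))
        thr = threshold_otsu(frame)
        mask = frame > thr
    elif threshold_method == "fixed":
        if fixed_threshold is None:
            raise ConfigurationError(
                "fixed threshold_method requires fixed_threshold")
        mask = frame >= fixed_threshold
    else:
        raise ConfigurationError(
            f"unknown threshold_method {threshold_method!r}")
    lab = cc_label(mask, connectivity=2)
    if min_area > 0:
        areas = np.bincount(lab.ravel())
        kill = np.flatnonzero(areas < min_area)
        lab[np.isin(lab, kill)] = 0
    lab, _, _ = relabel_sequential(lab)
    return LabelImage(lab.astype(np.int32))


def centroids(label_image: LabelImage) -> list[tuple[int, float, float]]:
    """Unweighted pixel-mean centroid per label, as (label, x, y).

    x is the column coordinate, y the row coordinate, matching the
    image-origin convention (origin top-left, y downward).
    """
    out = []
    for prop in regionprops(label_image.labels):
        cy, cx = prop.centroid
        out.append((int(prop.label), float(cx), float(cy)))
    out.sort(key=lambda r: r[0])
    return out


def link_frames(
    centroid_lists: Sequence[Sequence[tuple[int, float, float]]],
    max_displacement: float,
    frame_interval: float = 1.0,
    cell_type: str = "T",
) -> list[Track]:
    """Link per-frame detections into tracks, greedy nearest-first.

    Candidate links between consecutive frames are taken in order of
    increasing distance (ties by earlier-frame label, then later-frame
    label); links longer than ``max_displacement`` are forbidden, and any
    unlinked detection starts a new track.
    """
    if max_displacement <= 0:
        raise ConfigurationError("max_displacement must be > 0")
    if len(centroid_lists) < 2:
        raise ValueError("need >= 2 frames to link")

    next_track = 0
    # active: track name -> list of (frame, x, y); keyed by detection in
    # the latest frame
    points: dict[int, list[tuple[int, float, float]]] = {}
    current: dict[int, int] = {}  # label in current frame -> track index
    for lab, x, y in centroid_lists[0]:
        points[next_track] = [(0, x, y)]
        current[lab] = next_track
        next_track += 1

    for f in range(1, len(centroid_lists)):
        prev_dets = centroid_lists[f - 1]
        dets = centroid_lists[f]
        candidates = []
        for pl, px, py in prev_dets:
            for nl, nx, ny in dets:
                d = float(np.hypot(nx - px, ny - py))
                if d <= max_displacement:
                    candidates.append((d, pl, nl))
        candidates.sort()
        used_prev: set[int] = set()
        used_next: set[int] = set()
        assignment: dict[int, int] = {}
        for d, pl, nl in candidates:
            if pl in used_prev or nl in used_next:
                continue
            used_prev.add(pl)
            used_next.add(nl)
            assignment[nl] = current[pl]
        new_current: dict[int, int] = {}
        for lab, x, y in dets:
            if lab in assignment:
                ti = assignment[lab]
            else:
                ti = next_track
                points[ti] = []
                next_track += 1
            points[ti].append((f, x, y))
            new_current[lab] = ti
        current = new_current

    tracks = []
    for ti in sorted(points):
        pts = points[ti]
        if len(pts) < 2:
            logger.info("dropping single-point track %d", ti)
            continue
        tracks.append(Track(
            track_id=f"{cell_type}{ti:03d}",
            cell_type=cell_type,
            points=tuple(TrackPoint(frame=f, t=f * frame_interval, x=x, y=y)
                         for f, x, y in pts)))
    return tracks


def quantify_transfer(
    recipient_labels: LabelImage,
    transfer_channel: np.ndarray,
    threshold: float,
) -> TransferQuant:
    """Count above-threshold transfer-channel pixels inside each recipient.

    The sum over recipients equals the total number of above-threshold
    transfer pixels lying inside any mask (conservation).
    """
    if transfer_channel.shape != recipient_labels.labels.shape:
        raise ValueError("transfer channel and label image shapes differ")
    hot = transfer_channel >= threshold
    lab = recipient_labels.labels
    counts: dict[int, int] = {}
    areas = recipient_labels.areas()
    for label in areas:
        counts[label] = int(np.count_nonzero(hot & (lab == label)))
    return TransferQuant(counts=counts, areas=areas)


def average_transfer_by_type(
    quants: Sequence[TransferQuant],
    label_to_type: Sequence[dict[int, str]],
    granularity: str = "per_cell_frame",
) -> dict[str, float]:
    """Average transferred pixel count per recipient cell type.

    ``per_cell_frame`` averages over every (cell, frame) observation;
    ``per_frame`` first sums within a frame and averages frame totals per
    type; ``per_video`` reports the grand total per type over all frames.
    """
    if granularity not in ("per_cell_frame", "per_frame", "per_video"):
        raise ValueError(f"unknown granularity {granularity!r}")
    obs: dict[str, list[float]] = {}
    frame_totals: dict[str, list[float]] = {}
    totals: dict[str, float] = {}
    for q, l2t in zip(quants, label_to_type):
        per_type_frame: dict[str, float] = {}
        for label, count in q.counts.items():
            ctype = l2t[label]
            obs.setdefault(ctype, []).append(count)
            per_type_frame[ctype] = per_type_frame.get(ctype, 0) + count
            totals[ctype] = totals.get(ctype, 0) + count
        for ctype, tot in per_type_frame.items():
            frame_totals.setdefault(ctype, []).append(tot)
    if granularity == "per_cell_frame":
        return {ct: float(np.mean(v)) for ct, v in obs.items()}
    if granularity == "per_frame":
        return {ct: float(np.mean(v)) for ct, v in frame_totals.items()}
    return {ct: float(v) for ct, v in totals.items()}
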