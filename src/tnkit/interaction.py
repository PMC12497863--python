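"""Pairwise interaction metrics: Speed-Distance Index and proximity.

The Speed-Distance Index (SDI) of a cell pair at time t is

    SDI(t) = v_rel(t) / (d(t) + eps)

where v_rel is the magnitude of the difference of the two cells' velocity
vectors, d their centroid Euclidean distance, and eps a small constant that
keeps the quotient finite at zero distance. High SDI marks fast, directed
approach at close range; a sustained elevated SDI between an NK and a T
cell is the kinetic signature of synapse-forming interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from tnkit.tracking import Track, TrackPoint

DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class SDISample:
    t: float
    v_rel: float
    d: float
    sdi: float


@dataclass(frozen=True)
class SDISeries:
    pair: tuple[str, str]
    modality: str  # "NK-NK", "NK-T", "T-T"
    samples: tuple[SDISample, ...]
    epsilon: float


@dataclass(frozen=True)
class SDIBinSummary:
    bin_index: int
    bin_start: float
    bin_end: float
    modality: str
    median: float
    q1: float
    q3: float
    n_pairs: int


@dataclass(frozen=True)
class ProximityResult:
    """Close/distant labels and a fixed-width distance histogram (pixels)."""

    distances: tuple[float, ...]
    labels: tuple[str, ...]
    threshold: float
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]


def euclidean_distance(a: TrackPoint, b: TrackPoint) -> float:
    """Euclidean distance between two same-frame positions."""
    if a.frame != b.frame:
        raise ValueError(f"frames differ: {a.frame} vs {b.frame}")
    return math.hypot(a.x - b.x, a.y - b.y)


def _velocity_at(track: Track, frame: int) -> Optional[tuple[float, float]]:
    """Backward-difference velocity vector at a frame; None at track start."""
    idx = track.index_of(frame)
    if idx == 0:
        return None
    p0, p1 = track.points[idx - 1], track.points[idx]
    if p1.frame != p0.frame + 1:
        return None  # gap: no single-step predecessor
    dt = p1.t - p0.t
    return ((p1.x - p0.x) / dt, (p1.y - p0.y) / dt)


def relative_speed(track_a: Track, track_b: Track, frame: int) -> float:
    """Norm of the difference of the two cells' velocity vectors at a frame.

    Velocities are backward finite differences, so the first frame of
    either track has no defined relative speed.
    """
    va = _velocity_at(track_a, frame)
    vb = _velocity_at(track_b, frame)
    if va is None or vb is None:
        raise ValueError(f"no predecessor frame for frame {frame}")
    return math.hypot(va[0] - vb[0], va[1] - vb[1])


def sdi(v_rel: float, d: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Speed-Distance Index v_rel / (d + eps)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if v_rel < 0 or d < 0:
        raise ValueError("v_rel and d must be non-negative")
    return v_rel / (d + epsilon)


def modality_of(type_a: str, type_b: str) -> str:
    """Canonical interaction-modality label (NK-NK, NK-T, T-T)."""
    return "-".join(sorted((type_a, type_b)))


def sdi_series(
    track_a: Track,
    track_b: Track,
    epsilon: float = DEFAULT_EPSILON,
) -> SDISeries:
    """Per-frame SDI samples over all common frames of a pair.

    A sample exists at each common frame where both cells have a defined
    backward-difference velocity; v_rel and d are symmetric in the two
    tracks, so the series is orientation-independent.
    """
    common = sorted(set(track_a.frames) & set(track_b.frames))
    if len(common) < 2:
        raise ValueError("need >= 2 common frames for an SDI series")
    samples = []
    for f in common:
        try:
            v_rel = relative_speed(track_a, track_b, f)
        except ValueError:
            continue
        d = euclidean_distance(track_a.point_at(f), track_b.point_at(f))
        samples.append(SDISample(t=track_a.point_at(f).t, v_rel=v_rel, d=d,
                                 sdi=sdi(v_rel, d, epsilon)))
    return SDISeries(
        pair=(track_a.track_id, track_b.track_id),
        modality=modality_of(track_a.cell_type, track_b.cell_type),
        samples=tuple(samples),
        epsilon=epsilon,
    )


def aggregate_sdi(
    series: Sequence[SDISeries],
    bin_width: float,
    origin: str = "absolute",
) -> list[SDIBinSummary]:
    """Median and IQR of SDI per time bin and interaction modality.

    Samples fall into half-open bins [k*w, (k+1)*w). Within a bin each
    pair contributes its mean SDI once, so long series do not dominate;
    the median/quartiles are then taken across pairs. With
    ``origin='first_contact'`` each pair's clock starts at its first
    sample instead of absolute time.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if origin not in ("absolute", "first_contact"):
        raise ValueError("origin must be 'absolute' or 'first_contact'")
    rows = []
    for s in series:
        if not s.samples:
            continue
        t0 = s.samples[0].t if origin == "first_contact" else 0.0
        for sample in s.samples:
            rows.append({
                "pair": s.pair,
                "modality": s.modality,
                "bin": int((sample.t - t0) // bin_width),
                "sdi": sample.sdi,
            })
    if not rows:
        return []
    df = pd.DataFrame(rows)
    per_pair = (df.groupby(["modality", "bin", "pair"])["sdi"]
                  .mean().reset_index())
    out = []
    for (modality, b), grp in per_pair.groupby(["modality", "bin"]):
        q1, med, q3 = np.percentile(grp["sdi"].to_numpy(), [25, 50, 75])
        out.append(SDIBinSummary(
            bin_index=int(b), bin_start=b * bin_width,
            bin_end=(b + 1) * bin_width, modality=modality,
            median=float(med), q1=float(q1), q3=float(q3),
            n_pairs=len(grp)))
    out.sort(key=lambda s: (s.bin_index, s.modality))
    return out


def classify_proximity(
    distances: Sequence[float],
    threshold: float = 250.0,
    bin_width: float = 10.0,
) -> ProximityResult:
    """Label pair distances close (<= threshold) vs distant, with histogram.

    The histogram uses fixed-width half-open bins [k*w, (k+1)*w) in pixels
    (default 10 px), with the final bin closed so every distance is
    counted exactly once.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size and d.min() < 0:
        raise ValueError("distances must be non-negative")
    labels = tuple("close" if x <= threshold else "distant" for x in d)
    if d.size:
        n_bins = max(1, int(math.floor(d.max() / bin_width)) + 1)
        edges = np.arange(n_bins + 1) * bin_width
        counts, _ = np.histogram(d, bins=edges)
    else:
        edges = np.array([0.0, bin_width])
        counts = np.array([0])
    return ProximityResult(
        distances=tuple(d.tolist()),
        labels=labels,
        threshold=threshold,
        bin_edges=tuple(edges.tolist()),
        counts=tuple(int(c) for c in counts),
    )


def pair_distances(
    track_a: Track,
    track_b: Track,
    pixel_size: float = 1.0,
) -> list[float]:
    """Per-common-frame centroid distances of a pair, converted to pixels."""
    common = sorted(set(track_a.frames) & set(track_b.frames))
    return [euclidean_distance(track_a.point_at(f), track_b.point_at(f))
            / pixel_size for f in common]
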