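"""Synthetic data with ground truth for every analysis stage.

Emulates the statistical structure of a two-population live-cell imaging
experiment: T and NK cells perform isotropic stepwise random walks in a
closed square arena (reflecting boundaries, matching an imaging chamber);
each T cell is scripted into one contact window during which an NK partner
is steered alongside it and the T cell's speed is scaled by a per-cell
deceleration factor. Contact windows, per-cell factors, rendered masks and
painted transfer-pixel counts are all returned as ground truth, so the
downstream kinetics, SDI, segmentation and transfer-quantification stages
can be validated without any external data.

Also provides generators for ligand-receptor TPM expression tables that
realize a prescribed pass/fail design, and for phospho-flow percentage
tables with known fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as disk_pixels

from tnkit.config import ConfigurationError, SimConfig
from tnkit.lr_screen import ExpressionTable, LRPair
from tnkit.tracking import ContactInterval, Track, TrackPoint


@dataclass(frozen=True)
class TransferEvent:
    """One membrane-transfer event: donor pixels painted into a recipient."""

    donor_id: str
    recipient_id: str
    start_frame: int
    end_frame: int
    pixels_per_frame: int


@dataclass
class GroundTruth:
    tracks: list[Track]
    contact_intervals: list[ContactInterval]
    factors: dict[str, float]
    transfer_events: list[TransferEvent]


def _reflect(v: float, size: float) -> float:
    """Fold a coordinate back into [0, size] (closed chamber walls)."""
    period = 2 * size
    v = v % period
    return period - v if v > size else v


def _random_step(
    rng: np.random.Generator,
    pos: np.ndarray,
    step_len: float,
    size: float,
) -> np.ndarray:
    """One fixed-length step in a uniformly random admissible direction.

    Directions whose endpoint would leave the arena are rejected and
    redrawn, so the recorded displacement always equals the step length
    exactly (closed-chamber walls without distorting speeds). Falls back to
    coordinate folding in the (unreachable for step < arena) case where no
    admissible direction is found.
    """
    for _ in range(1000):
        theta = rng.uniform(0, 2 * math.pi)
        p = pos + step_len * np.array([math.cos(theta), math.sin(theta)])
        if 0 <= p[0] <= size and 0 <= p[1] <= size:
            return p
    return np.array([_reflect(p[0], size), _reflect(p[1], size)])


def simulate_tracks(config: SimConfig) -> GroundTruth:
    """Simulate T and NK cell trajectories with scripted contact windows.

    Each cell takes per-frame steps of length speed * dt in a uniformly
    random direction, with Gaussian step-speed noise of sd
    noise_sd_frac * speed (truncated at zero). T cell i is paired with NK
    cell (i mod n_nk) for one contact window: the NK partner is placed at
    0.9 * contact_radius from the T cell each window frame and the T cell's
    speed is multiplied by its deceleration factor. Identical seed and
    config reproduce the output bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    factors = config.factor_list()
    dt = config.frame_interval
    n_frames = config.n_frames

    t_ids = [f"T{i:03d}" for i in range(config.n_t)]
    nk_ids = [f"NK{i:03d}" for i in range(config.n_nk)]

    # Scripted contact windows: start in the second quarter of the movie,
    # 15-25 frames long, leaving a long Ph1 and a non-empty Ph3.
    windows: dict[str, tuple[int, int, str]] = {}
    if config.n_nk > 0:
        lo = max(1, n_frames // 4)
        hi = max(lo + 1, n_frames // 2)
        for i, tid in enumerate(t_ids):
            start = int(rng.integers(lo, hi))
            dur = int(rng.integers(15, 26))
            end = min(start + dur - 1, n_frames - 2)
            windows[tid] = (start, end, nk_ids[i % config.n_nk])

    pos = {
        cid: np.array([rng.uniform(0, config.arena_size),
                       rng.uniform(0, config.arena_size)])
        for cid in t_ids + nk_ids
    }
    coords: dict[str, list[tuple[float, float]]] = {
        cid: [tuple(p)] for cid, p in pos.items()}

    steered_nk: dict[int, dict[str, str]] = {}
    escaping_nk: dict[int, dict[str, str]] = {}
    ESCAPE_FRAMES = 3
    ESCAPE_SPEED_FACTOR = 3.0
    for tid, (s, e, nk) in windows.items():
        for f in range(s, e + 1):
            steered_nk.setdefault(f, {})[nk] = tid
        # Post-contact disengagement: the partner moves directly away for a
        # few frames so the pair's distance leaves contact range at e + 1,
        # keeping the ground-truth Ph2 boundary exact.
        for f in range(e + 1, min(e + 1 + ESCAPE_FRAMES, n_frames)):
            escaping_nk.setdefault(f, {})[nk] = tid

    for f in range(1, n_frames):
        steered = steered_nk.get(f, {})
        # T cells first (NK steering follows their new positions).
        for i, cid in enumerate(t_ids):
            base = config.base_speed_t
            if cid in windows:
                s, e, _ = windows[cid]
                if s <= f <= e:
                    base *= factors[i]
            speed = base
            if config.noise_sd_frac > 0:
                speed = max(0.0, speed + rng.normal(0, config.noise_sd_frac
                                                    * base))
            pos[cid] = _random_step(rng, pos[cid], speed * dt,
                                    config.arena_size)
            coords[cid].append(tuple(pos[cid]))
        escaping = escaping_nk.get(f, {})
        for cid in nk_ids:
            if cid in steered:
                anchor = pos[steered[cid]]
                phi = rng.uniform(0, 2 * math.pi)
                offset = 0.9 * config.contact_radius
                p = anchor + offset * np.array([math.cos(phi), math.sin(phi)])
                pos[cid] = np.array([_reflect(p[0], config.arena_size),
                                     _reflect(p[1], config.arena_size)])
            elif cid in escaping:
                anchor = pos[escaping[cid]]
                away = pos[cid] - anchor
                norm = float(np.hypot(*away))
                if norm == 0:
                    phi = rng.uniform(0, 2 * math.pi)
                    away = np.array([math.cos(phi), math.sin(phi)])
                else:
                    away = away / norm
                step = ESCAPE_SPEED_FACTOR * config.base_speed_nk * dt
                p = pos[cid] + step * away
                pos[cid] = np.array([_reflect(p[0], config.arena_size),
                                     _reflect(p[1], config.arena_size)])
            else:
                base = config.base_speed_nk
                speed = base
                if config.noise_sd_frac > 0:
                    speed = max(0.0, speed + rng.normal(
                        0, config.noise_sd_frac * base))
                pos[cid] = _random_step(rng, pos[cid], speed * dt,
                                        config.arena_size)
            coords[cid].append(tuple(pos[cid]))

    def build(cid: str, ctype: str) -> Track:
        return Track(cid, ctype, tuple(
            TrackPoint(frame=f, t=f * dt, x=x, y=y)
            for f, (x, y) in enumerate(coords[cid])))

    tracks = ([build(cid, "T") for cid in t_ids]
              + [build(cid, "NK") for cid in nk_ids])
    intervals = [ContactInterval(tid, nk, s, e)
                 for tid, (s, e, nk) in windows.items()]
    transfers = [TransferEvent(donor_id=tid, recipient_id=nk, start_frame=s,
                               end_frame=e,
                               pixels_per_frame=config.transfer_pixels)
                 for tid, (s, e, nk) in windows.items()]
    return GroundTruth(
        tracks=tracks,
        contact_intervals=intervals,
        factors={tid: factors[i] for i, tid in enumerate(t_ids)},
        transfer_events=transfers,
    )


@dataclass
class RenderedStack:
    """Two-channel rendered movie plus per-frame ground-truth label images.

    stack: (n_frames, 2, H, W) uint16, channel 0 = T, channel 1 = NK.
    labels: per frame, per cell type, an integer label image where label k
    marks the k-th cell of that type (raster order of creation).
    """

    stack: np.ndarray
    labels: list[dict[str, np.ndarray]]
    pixel_size: float
    frame_interval: float
    channel_roles: dict[str, int]
    label_to_id: dict[str, dict[int, str]]


CELL_INTENSITY = 1000
TRANSFER_INTENSITY = 800


def render_frames(truth: GroundTruth, config: SimConfig) -> RenderedStack:
    """Rasterize tracks into a two-channel stack with transfer painting.

    Each cell becomes a filled disk of radius cell_radius_um in its type's
    channel. During a transfer event, ``transfer_pixels`` donor-channel
    pixels are painted inside the recipient mask (deterministic raster
    order, skipping any pixel already covered by a donor-type disk), per
    frame of the event.
    """
    size_px = int(round(config.arena_size / config.pixel_size))
    r_px = config.cell_radius_um / config.pixel_size
    if 2 * r_px >= size_px:
        raise ConfigurationError("cell radius exceeds arena in pixels")

    n_frames = config.n_frames
    stack = np.zeros((n_frames, 2, size_px, size_px), dtype=np.uint16)
    roles = {"T": 0, "NK": 1}
    labels: list[dict[str, np.ndarray]] = []
    label_to_id: dict[str, dict[int, str]] = {"T": {}, "NK": {}}

    by_type: dict[str, list[Track]] = {"T": [], "NK": []}
    for tr in truth.tracks:
        by_type.setdefault(tr.cell_type, []).append(tr)
    for ctype in ("T", "NK"):
        for k, tr in enumerate(by_type[ctype]):
            label_to_id[ctype][k + 1] = tr.track_id

    events_by_frame: dict[int, list] = {}
    for ev in truth.transfer_events:
        for f in range(ev.start_frame, ev.end_frame + 1):
            events_by_frame.setdefault(f, []).append(ev)

    track_by_id = {tr.track_id: tr for tr in truth.tracks}

    for f in range(n_frames):
        frame_labels: dict[str, np.ndarray] = {}
        for ctype in ("T", "NK"):
            lab = np.zeros((size_px, size_px), dtype=np.int32)
            ch = roles[ctype]
            for k, tr in enumerate(by_type[ctype]):
                try:
                    p = tr.point_at(f)
                except KeyError:
                    continue
                rr, cc = disk_pixels(
                    (p.y / config.pixel_size, p.x / config.pixel_size),
                    r_px, shape=(size_px, size_px))
                stack[f, ch, rr, cc] = CELL_INTENSITY
                lab[rr, cc] = k + 1
            frame_labels[ctype] = lab
        for ev in events_by_frame.get(f, []):
            donor = track_by_id[ev.donor_id]
            recipient = track_by_id[ev.recipient_id]
            donor_ch = roles[donor.cell_type]
            rec_lab = frame_labels[recipient.cell_type]
            rp = recipient.point_at(f)
            rr, cc = disk_pixels(
                (rp.y / config.pixel_size, rp.x / config.pixel_size),
                r_px, shape=(size_px, size_px))
            donor_lab = frame_labels[donor.cell_type]
            # paint only pixels inside the recipient and free of donor disks
            inside = (rec_lab[rr, cc] > 0) & (donor_lab[rr, cc] == 0)
            rr, cc = rr[inside], cc[inside]
            n = min(ev.pixels_per_frame, rr.size)
            stack[f, donor_ch, rr[:n], cc[:n]] = TRANSFER_INTENSITY
        labels.append(frame_labels)

    return RenderedStack(stack=stack, labels=labels,
                         pixel_size=config.pixel_size,
                         frame_interval=config.frame_interval,
                         channel_roles=roles, label_to_id=label_to_id)


# --- expression-table synthesis -------------------------------------------

Assignment = Literal["pass10", "pass2_only", "fail"]


class DesignError(ValueError):
    """A pass/fail design imposes contradictory bands on one gene."""


def synth_expression(
    pairs: Sequence[LRPair],
    design: Mapping[str, Assignment] | Sequence[Assignment],
    seed: int,
    cell_types: tuple[str, str] = ("activated CD8 T", "NK"),
) -> ExpressionTable:
    """Draw a TPM table that realizes a prescribed screen outcome per pair.

    Assignments: ``pass10`` puts every subunit in [10, 100]; ``pass2_only``
    puts one limiting subunit in [2, 10) and the rest in [2, 100];
    ``fail`` puts one limiting subunit in [0, 2) and the rest anywhere in
    [0, 100]. Each gene gets one TPM value used for both cell types, so the
    realized outcome is direction-independent. Genes shared between pairs
    accumulate interval constraints; an empty intersection raises
    DesignError naming the gene.
    """
    if not isinstance(design, Mapping):
        if len(design) != len(pairs):
            raise DesignError("design length must match number of pairs")
        design = {p.key(): a for p, a in zip(pairs, design)}

    # Interval constraint per gene; limiting subunits chosen greedily.
    intervals: dict[str, tuple[float, float]] = {}

    def constrain(gene: str, lo: float, hi: float) -> bool:
        cur = intervals.get(gene, (0.0, 100.0))
        new = (max(cur[0], lo), min(cur[1], hi))
        if new[0] >= new[1]:
            return False
        intervals[gene] = new
        return True

    for pair in pairs:
        assignment = design[pair.key()]
        subunits = list(pair.ligand_subunits) + list(pair.receptor_subunits)
        if assignment == "pass10":
            for g in subunits:
                if not constrain(g, 10.0, 100.0):
                    raise DesignError(
                        f"gene {g} cannot satisfy conflicting bands")
        elif assignment == "pass2_only":
            for g in subunits:
                if not constrain(g, 2.0, 100.0):
                    raise DesignError(
                        f"gene {g} cannot satisfy conflicting bands")
            for g in subunits:  # one subunit must stay below 10
                cur = intervals[g]
                if cur[0] < 10.0:
                    intervals[g] = (cur[0], min(cur[1], 10.0))
                    break
            else:
                raise DesignError(
                    f"pair {pair.key()}: no subunit can stay below 10 TPM")
        elif assignment == "fail":
            for g in subunits:  # one subunit must fall below 2
                cur = intervals.get(g, (0.0, 100.0))
                if cur[0] < 2.0:
                    intervals[g] = (cur[0], min(cur[1], 2.0))
                    break
            else:
                raise DesignError(
                    f"pair {pair.key()}: no subunit can fall below 2 TPM")
        else:
            raise DesignError(f"unknown assignment {assignment!r}")

    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted({g for p in pairs
                        for g in list(p.ligand_subunits)
                        + list(p.receptor_subunits)}):
        lo, hi = intervals.get(gene, (0.0, 100.0))
        tpm = float(rng.uniform(lo, hi))
        for ct in cell_types:
            rows.append({"gene": gene, "cell_type": ct, "tpm": tpm})
    return ExpressionTable.from_frame(pd.DataFrame(rows))


def synth_flow(
    true_fold_changes: Mapping[str, float],
    noise_sd: float,
    seed: int,
    population: str = "NK",
) -> pd.DataFrame:
    """Generate a phospho-flow table with known per-marker fold changes.

    Monoculture phospho (pX) and total (X) percent-positive fractions are
    drawn per marker; co-culture pX is set to pX_mono * fold change (same
    total), then every percentage gets multiplicative Gaussian noise of sd
    ``noise_sd`` (resampled until it lands in (0, 100]). Fold-change
    recovery error shrinks to zero with noise_sd.
    """
    if any(fc <= 0 for fc in true_fold_changes.values()):
        raise ValueError("fold changes must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    def noisy(value: float) -> float:
        if noise_sd == 0:
            return value
        for _ in range(1000):
            v = value * (1 + rng.normal(0, noise_sd))
            if 0 < v <= 100:
                return v
        raise RuntimeError("could not draw a percentage inside (0, 100]")

    rows = []
    for marker in sorted(true_fold_changes):
        fc = true_fold_changes[marker]
        px_mono = rng.uniform(5, 30)
        x_mono = rng.uniform(40, 90)
        px_co = min(px_mono * fc, 100.0)
        x_co = x_mono
        for cond, px, x in (("monoculture", px_mono, x_mono),
                            ("co-culture", px_co, x_co)):
            rows.append({"marker": marker, "population": population,
                         "condition": cond, "pX": noisy(px), "X": noisy(x)})
    return pd.DataFrame(rows)
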