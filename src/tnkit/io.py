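"""Readers and writers for the package's on-disk formats.

Tracks travel as CSV (track_id, cell_type, frame, t_s, x_um, y_um), image
stacks as multi-page TIFF, ground truth and run summaries as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from tnkit.simulate import GroundTruth, RenderedStack
from tnkit.tracking import Track, TrackPoint

TRACK_COLUMNS = ["track_id", "cell_type", "frame", "t_s", "x_um", "y_um"]


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = [
        {"track_id": tr.track_id, "cell_type": tr.cell_type,
         "frame": p.frame, "t_s": p.t, "x_um": p.x, "y_um": p.y}
        for tr in tracks for p in tr.points
    ]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(tracks: Sequence[Track], path: Path | str) -> None:
    # %.17g keeps the round-trip lossless at double precision
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.17g")


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        ctypes = grp["cell_type"].unique()
        if len(ctypes) != 1:
            raise ValueError(f"track {tid} has multiple cell types")
        tracks.append(Track(
            track_id=str(tid), cell_type=str(ctypes[0]),
            points=tuple(TrackPoint(frame=int(r.frame), t=float(r.t_s),
                                    x=float(r.x_um), y=float(r.y_um))
                         for r in grp.itertuples())))
    return tracks


def read_tracks(path: Path | str) -> list[Track]:
    return frame_to_tracks(pd.read_csv(path, float_precision="round_trip"))


def write_stack(stack: RenderedStack, path: Path | str) -> None:
    """Write a (frames, channels, H, W) stack as multi-page TIFF."""
    tifffile.imwrite(path, stack.stack, metadata={
        "axes": "TCYX",
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "channel_roles": stack.channel_roles,
    })


def read_stack(path: Path | str) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 3:  # single frame, channels first
        arr = arr[None]
    return arr


def write_ground_truth(truth: GroundTruth, path: Path | str) -> None:
    """JSON sidecar with contact intervals, factors, and transfer events."""
    payload = {
        "contact_intervals": [dataclasses.asdict(ci)
                              for ci in truth.contact_intervals],
        "factors": truth.factors,
        "transfer_events": [dataclasses.asdict(ev)
                            for ev in truth.transfer_events],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_summary(path: Path | str, **fields) -> None:
    """Machine-readable run summary (config echo, seed, counts)."""
    import tnkit
    fields.setdefault("tnkit_version", tnkit.__version__)
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True,
                                     default=str))
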