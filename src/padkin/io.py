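"""Trajectory and label tables as CSV; movies as TIFF."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import Detection, ImageStack, Trajectory

__all__ = ["tracks_to_frame", "write_tracks", "read_tracks",
           "write_context", "read_context", "read_stack", "write_stack"]


def tracks_to_frame(tracks: list[Trajectory], pixel_size: float, dt: float) -> pd.DataFrame:
    """Long-format table: track_id, frame, t_s, x_um, y_um."""
    rows = [(tr.track_id, d.frame, d.frame * dt, d.x * pixel_size, d.y * pixel_size)
            for tr in tracks for d in tr.detections]
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x_um", "y_um"])


def write_tracks(tracks: list[Trajectory], path: str | Path,
                 pixel_size: float, dt: float) -> None:
    tracks_to_frame(tracks, pixel_size, dt).to_csv(path, index=False)


def read_tracks(path: str | Path, pixel_size: float = 1.0) -> list[Trajectory]:
    """Read a trajectory CSV back into Trajectory objects (positions in px)."""
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        dets = [Detection(frame=int(f), x=x / pixel_size, y=y / pixel_size)
                for f, x, y in zip(grp["frame"], grp["x_um"], grp["y_um"])]
        out.append(Trajectory(track_id=int(tid), detections=dets))
    return out


def write_context(labels, path: str | Path) -> None:
    pd.DataFrame([{"track_id": l.track_id, "frame": l.frame, "label": l.label,
                   "confidence": l.confidence} for l in labels]).to_csv(path, index=False)


def read_context(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_stack(path: str | Path, pixel_size: float, dt: float) -> ImageStack:
    return ImageStack(tifffile.imread(path), pixel_size, dt)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack.pixels, dtype=np.float32),
                     photometric="minisblack")
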