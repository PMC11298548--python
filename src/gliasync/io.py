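"""Plain-format I/O: trace/angle/track CSVs and two-channel TIFF stacks.

Every image or table file travels with a JSON sidecar (``<name>.json``)
carrying the physical metadata the file format itself cannot hold (pixel
size in µm, frame interval, seed, ground truth when synthetic).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .calcium import FluorescenceTrace
from .errors import DataError
from .interaction import AngleSample, ProcessTrack

__all__ = [
    "sidecar_path",
    "write_traces_csv",
    "read_traces_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_angles_csv",
    "read_angles_csv",
    "write_tracks_csv",
    "read_tracks_csv",
]


def sidecar_path(path: Path | str) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path | str, payload: dict) -> Path:
    sp = sidecar_path(path)
    sp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sp


def _read_sidecar(path: Path | str) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        raise DataError(f"missing metadata sidecar {sp}")
    return json.loads(sp.read_text())


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_traces_csv(
    path: Path | str,
    traces: Sequence[FluorescenceTrace],
    seed: int | None = None,
    extra_metadata: dict | None = None,
) -> Path:
    """Write traces as a frame × ROI CSV plus a JSON sidecar with the frame interval."""
    path = Path(path)
    if not traces:
        raise DataError("no traces to write")
    intervals = {t.frame_interval for t in traces}
    if len(intervals) != 1:
        raise DataError("traces have inconsistent frame intervals")
    frame = pd.DataFrame({t.roi_id: t.values for t in traces})
    frame.insert(0, "frame", np.arange(len(frame)))
    frame.to_csv(path, index=False)
    meta = {"frame_interval_s": traces[0].frame_interval, "seed": seed}
    if extra_metadata:
        meta.update(extra_metadata)
    _write_sidecar(path, meta)
    return path


def read_traces_csv(path: Path | str) -> list[FluorescenceTrace]:
    path = Path(path)
    meta = _read_sidecar(path)
    table = pd.read_csv(path)
    if "frame" in table.columns:
        table = table.drop(columns="frame")
    interval = float(meta["frame_interval_s"])
    return [
        FluorescenceTrace(values=table[col].to_numpy(float), frame_interval=interval,
                          roi_id=str(col))
        for col in table.columns
    ]


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack_tiff(
    path: Path | str,
    stack: np.ndarray,
    pixel_size_um: float,
    frame_interval_min: float,
    truth: dict | None = None,
) -> Path:
    """Write a (frames, 2, rows, cols) stack as a channel-interleaved TIFF.

    Pages alternate frame0/ch0, frame0/ch1, frame1/ch0, ...; the sidecar
    records pixel size, frame interval, channel order and (optionally) the
    generator ground truth.
    """
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise DataError("stack must be 4-D (frames, 2 channels, rows, cols)")
    pages = stack.reshape(stack.shape[0] * 2, *stack.shape[2:]).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "pixel_size_um": pixel_size_um,
        "frame_interval_min": frame_interval_min,
        "n_frames": int(stack.shape[0]),
        "channel_order": ["microglia", "axon"],
    }
    if truth is not None:
        meta["truth"] = truth
    _write_sidecar(path, meta)
    return path


def read_stack_tiff(path: Path | str) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = _read_sidecar(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] % 2:
        raise DataError("expected an even number of single-channel pages")
    stack = pages.reshape(pages.shape[0] // 2, 2, *pages.shape[1:])
    return stack, meta


# ---------------------------------------------------------------------------
# angles and tracks
# ---------------------------------------------------------------------------

def write_angles_csv(path: Path | str, samples: Sequence[AngleSample]) -> Path:
    path = Path(path)
    rows = pd.concat(
        [pd.DataFrame({"group": s.group, "angle_deg": s.angles_deg}) for s in samples],
        ignore_index=True,
    )
    rows.to_csv(path, index=False)
    return path


def read_angles_csv(path: Path | str) -> list[AngleSample]:
    table = pd.read_csv(path)
    for col in ("group", "angle_deg"):
        if col not in table.columns:
            raise DataError(f"angles CSV missing column {col!r}")
    return [
        AngleSample(sub["angle_deg"].to_numpy(float), group=str(group))
        for group, sub in table.groupby("group", sort=False)
    ]


def write_tracks_csv(path: Path | str, tracks: Sequence[ProcessTrack]) -> Path:
    path = Path(path)
    rows = pd.concat(
        [
            pd.DataFrame(
                {"track_id": t.track_id, "time_min": t.times_min,
                 "x_um": t.x_um, "y_um": t.y_um}
            )
            for t in tracks
        ],
        ignore_index=True,
    )
    rows.to_csv(path, index=False)
    return path


def read_tracks_csv(path: Path | str) -> list[ProcessTrack]:
    table = pd.read_csv(path)
    for col in ("track_id", "time_min", "x_um", "y_um"):
        if col not in table.columns:
            raise DataError(f"tracks CSV missing column {col!r}")
    return [
        ProcessTrack(
            times_min=sub["time_min"].to_numpy(float),
            x_um=sub["x_um"].to_numpy(float),
            y_um=sub["y_um"].to_numpy(float),
            track_id=str(tid),
        )
        for tid, sub in table.groupby("track_id", sort=False)
    ]
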