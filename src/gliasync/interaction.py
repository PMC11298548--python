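"""Microglia–axon spatial interaction analytics.

Covers the colocalization workflow (per-channel Otsu binarisation of SD
time-projections, merged-area / axon-area ratio) and the process-polarity
workflow (moving vectors of tracked process tips, axial angle folding to
[0°, 90°], empirical CDFs of folded angles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DataError, DegenerateDataError, ParameterError
from .morpho import ProjectedImage, sd_projection

__all__ = [
    "BinaryMask",
    "ColocalizationResult",
    "ProcessTrack",
    "MovingVector",
    "AngleSample",
    "otsu_binarize",
    "colocalization_ratio",
    "colocalization_from_stack",
    "moving_vector",
    "fold_angle_difference",
    "axon_axis",
    "angle_cdf",
    "process_axon_angles",
    "pairwise_process_angles",
]


@dataclass(frozen=True)
class BinaryMask:
    """A thresholded channel image: boolean foreground plus the threshold used."""

    mask: np.ndarray
    channel: str
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def foreground_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ColocalizationResult:
    """Merged (AND) area of the two channels relative to the axon area."""

    axon_area_px: int
    microglia_area_px: int
    merged_area_px: int
    ratio: float


@dataclass(frozen=True)
class ProcessTrack:
    """Tip coordinates (µm) of one microglial process over time (minutes)."""

    times_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    track_id: str = "track_0"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise DataError("track arrays must be equal-length 1-D")
        if t.size < 2:
            raise DataError("a track needs >= 2 time points")
        if not np.all(np.diff(t) > 0):
            raise DataError("track timestamps must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.times_min.size)


@dataclass(frozen=True)
class MovingVector:
    """Displacement from a track's start to its farthest in-window point."""

    vector_um: tuple[float, float]
    magnitude_um: float
    angle_deg: float | None  # None for zero displacement
    zero_displacement: bool
    track_id: str


@dataclass(frozen=True)
class AngleSample:
    """A labelled set of angles in degrees (circular [0, 360) or folded [0, 90])."""

    angles_deg: np.ndarray
    group: str = "group"

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "angles_deg", a)
        if a.ndim != 1:
            raise DataError("angles must be 1-D")
        if not np.all(np.isfinite(a)):
            raise DataError("angles must be finite")

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def otsu_binarize(image: ProjectedImage | np.ndarray, channel: str = "channel") -> BinaryMask:
    """Binarise a channel with Otsu's threshold on a 256-bin histogram.

    The threshold maximises the between-class variance of the 256-bin
    histogram over the observed min–max range (images may be more than
    8-bit); pixels strictly above the threshold are foreground.
    """
    values = image.values if isinstance(image, ProjectedImage) else np.asarray(image, float)
    if values.ndim != 2:
        raise DataError("image must be 2-D")
    if float(values.min()) == float(values.max()):
        raise DegenerateDataError("constant image: no Otsu threshold exists")
    threshold = float(threshold_otsu(values, nbins=256))
    return BinaryMask(mask=values > threshold, channel=channel, threshold=threshold)


def colocalization_ratio(microglia: BinaryMask, axon: BinaryMask) -> ColocalizationResult:
    """Fraction of the axon foreground overlapped by the microglia foreground."""
    if microglia.mask.shape != axon.mask.shape:
        raise DataError("masks must have the same shape")
    axon_px = axon.foreground_px
    if axon_px == 0:
        raise DataError("empty axon mask: colocalization ratio undefined")
    merged = int(np.logical_and(microglia.mask, axon.mask).sum())
    return ColocalizationResult(
        axon_area_px=axon_px,
        microglia_area_px=microglia.foreground_px,
        merged_area_px=merged,
        ratio=merged / axon_px,
    )


def colocalization_from_stack(
    stack: np.ndarray,
    pixel_size_um: float,
    mode: Literal["projection", "per_frame"] = "projection",
) -> ColocalizationResult | list[ColocalizationResult]:
    """Colocalization from a two-channel time stack (frames, 2, rows, cols).

    ``projection`` (default) binarises the SD time-projection of each channel
    and returns one ratio for the session; ``per_frame`` binarises each frame
    pair and returns one result per frame.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise DataError("stack must be 4-D (frames, 2 channels, rows, cols)")
    if mode == "projection":
        mg = otsu_binarize(sd_projection(stack[:, 0], pixel_size_um), channel="microglia")
        ax = otsu_binarize(sd_projection(stack[:, 1], pixel_size_um), channel="axon")
        return colocalization_ratio(mg, ax)
    if mode == "per_frame":
        out = []
        for f in range(stack.shape[0]):
            mg = otsu_binarize(stack[f, 0], channel="microglia")
            ax = otsu_binarize(stack[f, 1], channel="axon")
            out.append(colocalization_ratio(mg, ax))
        return out
    raise ParameterError(f"unknown colocalization mode {mode!r}")


# ---------------------------------------------------------------------------
# process polarity
# ---------------------------------------------------------------------------

def moving_vector(track: ProcessTrack, window_minutes: float = 60.0) -> MovingVector:
    """Moving vector of a process tip over an observation window.

    Among the positions within ``window_minutes`` of the first timestamp, the
    point at maximum Euclidean distance from the start defines the vector
    (earliest such point on ties).  The angle is atan2(y, x) in degrees,
    mapped to [0°, 360°) in image coordinates (+x rightward, +y downward,
    counter-clockwise positive).  A track whose farthest point coincides with
    the start is flagged as zero displacement; its angle is undefined and the
    track is excluded from angle samples.
    """
    if not (window_minutes > 0):
        raise ParameterError("window_minutes must be > 0")
    t0 = track.times_min[0]
    in_window = track.times_min <= t0 + window_minutes
    if int(in_window.sum()) < 2:
        raise DataError("need >= 2 track points inside the window")
    dx = track.x_um[in_window] - track.x_um[0]
    dy = track.y_um[in_window] - track.y_um[0]
    dist = np.hypot(dx, dy)
    best = int(np.argmax(dist))  # argmax returns the earliest maximum on ties
    vec = (float(dx[best]), float(dy[best]))
    mag = float(dist[best])
    if mag == 0.0:
        return MovingVector(vec, 0.0, None, True, track.track_id)
    angle = float(np.degrees(np.arctan2(vec[1], vec[0])) % 360.0)
    return MovingVector(vec, mag, angle, False, track.track_id)


def fold_angle_difference(theta1_deg: float, theta2_deg: float) -> float:
    """Absolute angular difference folded to [0°, 90°].

    Directions are treated axially (θ and θ+180° identified), so the result
    is the acute angle between the two axes: d = |θ₁ − θ₂| mod 180, then
    min(d, 180 − d).
    """
    if not (np.isfinite(theta1_deg) and np.isfinite(theta2_deg)):
        raise DataError("angles must be finite")
    d = abs(float(theta1_deg) - float(theta2_deg)) % 180.0
    return d if d <= 90.0 else 180.0 - d


def axon_axis(endpoint_a: Sequence[float], endpoint_b: Sequence[float]) -> float:
    """Axial orientation (degrees in [0, 180)) of the chord joining two boutons."""
    ax, ay = float(endpoint_a[0]), float(endpoint_a[1])
    bx, by = float(endpoint_b[0]), float(endpoint_b[1])
    if ax == bx and ay == by:
        raise ParameterError("axon endpoints coincide; orientation undefined")
    return float(np.degrees(np.arctan2(by - ay, bx - ax)) % 180.0)


def angle_cdf(sample: AngleSample | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF of a folded angle sample on [0, 90].

    Returns the sorted unique angles and the cumulative proportion at each;
    the final value is exactly 1.
    """
    angles = sample.angles_deg if isinstance(sample, AngleSample) else np.asarray(sample, float)
    if angles.size < 1:
        raise DataError("empty angle sample")
    xs, counts = np.unique(angles, return_counts=True)
    return xs, np.cumsum(counts) / angles.size


def process_axon_angles(
    tracks: Sequence[ProcessTrack],
    axon_angle_deg: float,
    window_minutes: float = 60.0,
    group: str = "process-axon",
) -> tuple[AngleSample, int]:
    """Folded angles between process moving vectors and the axon axis.

    Zero-displacement tracks are excluded (their direction is undefined);
    the number excluded is returned alongside the sample.
    """
    folded = []
    n_excluded = 0
    for track in tracks:
        mv = moving_vector(track, window_minutes)
        if mv.zero_displacement:
            n_excluded += 1
            continue
        folded.append(fold_angle_difference(mv.angle_deg, axon_angle_deg))
    return AngleSample(np.array(folded), group=group), n_excluded


def pairwise_process_angles(
    angles_deg: Sequence[float],
    group: str = "process-process",
) -> AngleSample:
    """Folded angles between every unordered pair of process directions."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 2:
        raise DataError("need >= 2 process angles for pairwise differences")
    out = [
        fold_angle_difference(angles[i], angles[j])
        for i in range(angles.size)
        for j in range(i + 1, angles.size)
    ]
    return AngleSample(np.array(out), group=group)
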