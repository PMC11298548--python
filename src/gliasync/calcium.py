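"""Calcium-trace analytics for two-photon population imaging.

Implements the per-ROI pipeline used for layer-5 motor-cortex recordings:
percentile baseline, ΔF/F₀ normalisation, threshold-based transient detection,
transient frequency and power, pairwise Pearson and cosine (non-centred)
correlations, and session synchrony standardised to a pre-operation baseline.

The cosine correlation

    r_c = Σ xᵢyᵢ / (√Σ xᵢ² · √Σ yᵢ²)

is used instead of Pearson's r for synchrony because calcium transients are
non-negative and sparse: centring turns long mutual silences into correlated
negative excursions and inflates r_p, while r_c stays near zero unless the two
neurons actually co-fire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import DataError, ParameterError, UndefinedCorrelationError

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "TransientEvent",
    "SynchronyMatrix",
    "StandardizedSynchrony",
    "compute_baseline",
    "estimate_noise_sd",
    "compute_dff",
    "detect_transients",
    "transient_frequency",
    "transient_power",
    "pearson_correlation",
    "cosine_correlation",
    "pairwise_synchrony",
    "standardize_to_pre",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw fluorescence of one ROI, in arbitrary units, sampled at a fixed interval."""

    values: np.ndarray
    frame_interval: float  # seconds per frame
    roi_id: str = "roi_0"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise DataError(f"trace {self.roi_id!r} needs >= 2 frames in one dimension")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise DataError(f"trace {self.roi_id!r} has a non-finite value at frame {bad}")
        if not (self.frame_interval > 0):
            raise ParameterError("frame_interval must be > 0 seconds")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Total recorded time covered by the frames."""
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class DffTrace:
    """A baseline-normalised trace: ΔF/F₀ with the F₀ and noise SD used downstream."""

    values: np.ndarray
    baseline: float
    noise_sd: float
    frame_interval: float
    roi_id: str = "roi_0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not (self.baseline > 0):
            raise ParameterError("baseline F0 must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class TransientEvent:
    """One detected transient over the half-open frame range [onset, offset)."""

    onset_frame: int
    offset_frame: int
    peak: float
    power: float

    def __post_init__(self) -> None:
        if self.offset_frame <= self.onset_frame:
            raise DataError("transient offset must be after onset")

    @property
    def duration_frames(self) -> int:
        return self.offset_frame - self.onset_frame


@dataclass(frozen=True)
class SynchronyMatrix:
    """Symmetric pairwise correlation matrix over ROIs; undefined pairs are NaN."""

    values: np.ndarray
    kind: Literal["cosine", "pearson"]
    roi_ids: tuple[str, ...]
    n_undefined_pairs: int = 0

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def mean_offdiagonal(self) -> float:
        """Mean correlation over defined unordered ROI pairs (the session synchrony)."""
        iu = np.triu_indices(self.n_rois, k=1)
        vals = self.values[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise UndefinedCorrelationError("no defined ROI pairs to average")
        return float(vals.mean())


@dataclass(frozen=True)
class StandardizedSynchrony:
    """Session synchrony expressed relative to the pre-operation session."""

    session: str
    mean_correlation: float
    standardized: float


# ---------------------------------------------------------------------------
# baseline and normalisation
# ---------------------------------------------------------------------------

def compute_baseline(trace: FluorescenceTrace | np.ndarray, percentile: float = 35.0) -> float:
    """Baseline F₀ as a percentile of the whole-session intensity histogram.

    Uses linear interpolation between order statistics, matching
    ``numpy.percentile``'s default convention.
    """
    if not (0 < percentile < 100):
        raise ParameterError("percentile must be strictly between 0 and 100")
    values = trace.values if isinstance(trace, FluorescenceTrace) else np.asarray(trace, float)
    if values.size == 0:
        raise DataError("cannot take a percentile of an empty trace")
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise DataError(f"non-finite value at frame {bad}")
    return float(np.percentile(values, percentile))


def estimate_noise_sd(
    dff_values: np.ndarray,
    method: Literal["half_sample", "full"] = "half_sample",
) -> float:
    """Estimate the noise SD of a ΔF/F₀ trace.

    ``half_sample`` (default) uses only frames at or below the trace median —
    which excludes transient-dominated frames — and takes the RMS deviation
    about the median.  For symmetric noise this is unbiased for the full noise
    SD (E[X² | X ≤ 0] = σ² when X ~ N(0, σ)), unlike the plain SD of the lower
    half-sample, which would come out ≈ 0.60σ.  ``full`` is the plain SD of
    all frames; it over-estimates the noise when transients are present.
    """
    x = np.asarray(dff_values, dtype=float)
    if method == "full":
        return float(np.std(x))
    if method != "half_sample":
        raise ParameterError(f"unknown noise method {method!r}")
    med = float(np.median(x))
    lower = x[x <= med]
    if lower.size == 0:  # cannot happen for finite input, guard anyway
        raise DataError("no frames at or below the median")
    return float(np.sqrt(np.mean((lower - med) ** 2)))


def compute_dff(
    trace: FluorescenceTrace,
    f0: float | None = None,
    percentile: float = 35.0,
    noise_method: Literal["half_sample", "full"] = "half_sample",
) -> DffTrace:
    """ΔF/F₀ = (F − F₀)/F₀ framewise, with the noise SD used for thresholding.

    If ``f0`` is not given it is computed with :func:`compute_baseline`.
    """
    if f0 is None:
        f0 = compute_baseline(trace, percentile)
    if not (f0 > 0):
        raise ParameterError(
            f"baseline F0={f0!r} is not positive; trace {trace.roi_id!r} cannot be "
            "ratiometrically normalised"
        )
    dff = (trace.values - f0) / f0
    noise_sd = estimate_noise_sd(dff, noise_method)
    return DffTrace(
        values=dff,
        baseline=float(f0),
        noise_sd=noise_sd,
        frame_interval=trace.frame_interval,
        roi_id=trace.roi_id,
    )


# ---------------------------------------------------------------------------
# transient detection and summary statistics
# ---------------------------------------------------------------------------

def transient_power(segment: np.ndarray) -> float:
    """Mean squared ΔF/F₀ amplitude over a transient: p = (1/T) Σ xᵢ²."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise DataError("transient power is undefined for an empty segment")
    return float(np.mean(x**2))


def detect_transients(
    dff: DffTrace,
    sd_multiplier: float = 2.0,
    min_duration_frames: int = 2,
) -> list[TransientEvent]:
    """Detect calcium transients as suprathreshold runs of ΔF/F₀.

    A transient is a maximal run of consecutive frames with
    ΔF/F₀ > ``sd_multiplier`` × noise SD, at least ``min_duration_frames``
    long.  Events are disjoint, ordered by onset, and carry their peak and
    mean-squared power.  ``min_duration_frames`` rejects isolated noise
    spikes; under white noise the expected number of spurious runs of length
    m in an N-frame trace is ≈ N·P(Z > sd_multiplier)^m.
    """
    if not (dff.noise_sd > 0):
        raise ParameterError("dff.noise_sd must be > 0 for threshold detection")
    if min_duration_frames < 1:
        raise ParameterError("min_duration_frames must be >= 1")
    threshold = sd_multiplier * dff.noise_sd
    above = dff.values > threshold
    if not above.any():
        return []
    # run-length encode the boolean mask
    edges = np.diff(above.astype(np.int8))
    onsets = list(np.flatnonzero(edges == 1) + 1)
    offsets = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(above.size)
    events = []
    for onset, offset in zip(onsets, offsets):
        if offset - onset < min_duration_frames:
            continue
        seg = dff.values[onset:offset]
        events.append(
            TransientEvent(
                onset_frame=int(onset),
                offset_frame=int(offset),
                peak=float(seg.max()),
                power=transient_power(seg),
            )
        )
    return events


def transient_frequency(events: Sequence[TransientEvent], duration_s: float) -> float:
    """Transient rate: number of detected events divided by session duration (s)."""
    if not (duration_s > 0):
        raise ParameterError("duration_s must be > 0")
    return len(events) / duration_s


# ---------------------------------------------------------------------------
# pairwise correlations
# ---------------------------------------------------------------------------

def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Centred correlation r_p between two equal-length activity vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        raise DataError("Pearson correlation needs >= 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(np.sum(xc**2))
    ny = np.sqrt(np.sum(yc**2))
    if nx == 0 or ny == 0:
        raise UndefinedCorrelationError("Pearson correlation undefined for a constant vector")
    return float(np.clip(np.dot(xc, yc) / (nx * ny), -1.0, 1.0))


def cosine_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Non-centred correlation r_c = Σxᵢyᵢ / (‖x‖·‖y‖)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("inputs must be equal-length 1-D vectors")
    if x.size < 1:
        raise DataError("cosine correlation needs >= 1 sample")
    nx = np.sqrt(np.sum(x**2))
    ny = np.sqrt(np.sum(y**2))
    if nx == 0 or ny == 0:
        raise UndefinedCorrelationError("cosine correlation undefined for a zero-norm vector")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def pairwise_synchrony(
    traces: Sequence[DffTrace] | np.ndarray,
    kind: Literal["cosine", "pearson"] = "cosine",
) -> SynchronyMatrix:
    """All unordered pairwise correlations over a set of ΔF/F₀ traces.

    Correlations are computed on ΔF/F₀ (not raw F).  Pairs whose correlation
    is undefined (zero-norm or constant trace) are stored as NaN, excluded
    from :meth:`SynchronyMatrix.mean_offdiagonal`, and counted in
    ``n_undefined_pairs``.
    """
    if kind not in ("cosine", "pearson"):
        raise ParameterError(f"unknown correlation kind {kind!r}")
    if isinstance(traces, np.ndarray):
        data = np.asarray(traces, dtype=float)
        if data.ndim != 2:
            raise DataError("trace array must be 2-D (n_rois, n_frames)")
        roi_ids = tuple(f"roi_{i}" for i in range(data.shape[0]))
    else:
        lengths = {t.n_frames for t in traces}
        if len(lengths) > 1:
            raise DataError("all traces must have the same number of frames")
        data = np.stack([t.values for t in traces])
        roi_ids = tuple(t.roi_id for t in traces)
    n = data.shape[0]
    if n < 2:
        raise ParameterError("pairwise synchrony needs >= 2 ROIs")
    corr = cosine_correlation if kind == "cosine" else pearson_correlation
    mat = np.full((n, n), np.nan)
    n_undefined = 0
    for i in range(n):
        # diagonal: 1 where the self-correlation is defined
        try:
            mat[i, i] = corr(data[i], data[i])
        except UndefinedCorrelationError:
            n_undefined += 0  # diagonal does not count as a pair
        for j in range(i + 1, n):
            try:
                mat[i, j] = mat[j, i] = corr(data[i], data[j])
            except UndefinedCorrelationError:
                n_undefined += 1
    return SynchronyMatrix(values=mat, kind=kind, roi_ids=roi_ids, n_undefined_pairs=n_undefined)


def standardize_to_pre(
    session_means: Mapping[str, float],
    pre_label: str = "Pre",
    mode: Literal["ratio", "difference"] = "ratio",
) -> list[StandardizedSynchrony]:
    """Express each session's mean synchrony relative to the pre session.

    ``ratio`` (default) divides by the pre-session mean so the pre session
    maps to exactly 1; ``difference`` subtracts it so the pre session maps
    to 0.  Session order of the input mapping is preserved.
    """
    if pre_label not in session_means:
        raise ParameterError(f"pre-session label {pre_label!r} missing from session means")
    pre = float(session_means[pre_label])
    if mode == "ratio" and pre == 0:
        raise ParameterError("pre-session mean synchrony is 0; ratio standardisation undefined")
    if mode not in ("ratio", "difference"):
        raise ParameterError(f"unknown standardisation mode {mode!r}")
    out = []
    for label, value in session_means.items():
        value = float(value)
        std = value / pre if mode == "ratio" else value - pre
        out.append(StandardizedSynchrony(session=label, mean_correlation=value, standardized=std))
    return out
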