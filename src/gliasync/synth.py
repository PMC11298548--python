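"""Ground-truth synthetic data emulating two-photon SCI imaging sessions.

Three generators mirror the acquisition geometry of the study system:

* :func:`simulate_traces` — per-ROI GCaMP-style fluorescence with shared
  (population-synchronous) and private Poisson events convolved with an
  instantaneous-rise / exponential-decay kernel, plus Gaussian noise.  The
  shared-to-total event-rate ratio is the ground-truth synchrony fraction.
* :func:`simulate_stack` — a two-channel time-lapse field (channel 0
  microglia: elliptical somas with straight processes; channel 1 axons:
  straight bright bands) with intensity-dependent Gaussian noise, a known
  microglia/axon overlap fraction and full ground-truth masks.
* :func:`simulate_angle_samples` / :func:`simulate_tracks` — von Mises angle
  samples and drifting process-tip trajectories for the polarity pipeline.

Every generator takes an explicit seed and a single ``numpy`` Generator
drives all randomness of a call; identical configs and seeds reproduce
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import line as draw_line

from .calcium import FluorescenceTrace
from .errors import ParameterError
from .interaction import AngleSample, ProcessTrack

__all__ = [
    "TraceSimConfig",
    "StackSimConfig",
    "SynthTruth",
    "simulate_traces",
    "simulate_stack",
    "simulate_angle_samples",
    "simulate_tracks",
]

# rendered intensity levels (arbitrary fluorescence units)
_BG_LEVEL = 0.05
_SOMA_LEVEL = 1.0
_SOMA_EDGE_FALLOFF = 0.15  # soma profile: 1.0 at centre -> 0.85 at the edge
_PROCESS_LEVEL = 0.45      # below the soma half-max so the wand stays on the soma
_AXON_LEVEL = 0.9


# ---------------------------------------------------------------------------
# configs and truth record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSimConfig:
    """Conditions for a simulated population-imaging session.

    Defaults emulate one 558-frame session at 4 Hz (139.5 s) with ten ROIs,
    a fast indicator (1 s decay), unit-ΔF/F₀ events at SNR 10 and equal
    shared/private event rates (synchrony fraction 0.5).
    """

    n_rois: int = 10
    n_frames: int = 558
    frame_interval: float = 0.25   # seconds
    shared_rate: float = 0.025     # population-wide events / s
    private_rate: float = 0.025    # per-ROI events / s
    amplitude: float = 1.0         # event peak, ΔF/F₀ units
    decay_tau: float = 1.0         # seconds
    noise_sd: float = 0.1          # ΔF/F₀ units
    baseline_level: float = 100.0  # arbitrary fluorescence units
    amplitude_jitter_sd: float = 0.0  # log-normal sigma; 0 = constant amplitudes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ParameterError("n_rois must be >= 1")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if not (self.frame_interval > 0):
            raise ParameterError("frame_interval must be > 0")
        if self.shared_rate < 0 or self.private_rate < 0:
            raise ParameterError("event rates must be >= 0")
        if not (self.decay_tau > 0):
            raise ParameterError("decay_tau must be > 0")
        for name in ("noise_sd", "amplitude"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if not (self.baseline_level > 0):
            raise ParameterError("baseline_level must be > 0")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def synchrony_fraction(self) -> float:
        total = self.shared_rate + self.private_rate
        return self.shared_rate / total if total > 0 else float("nan")


@dataclass(frozen=True)
class StackSimConfig:
    """Conditions for a simulated two-channel spinal time-lapse stack.

    Defaults match the spinal acquisition geometry: a 264.90 µm square field
    at 512 × 512 px (0.517 µm pixels), 90 frames at one frame per 2 min
    (a 3-h session), ten microglia and three pyramidal-tract axon bands.
    """

    field_size_um: float = 264.90
    resolution: int = 512
    n_frames: int = 90
    frame_interval_min: float = 2.0
    n_cells: int = 10
    soma_major_um: float = 14.0
    soma_minor_um: float = 10.0
    n_processes_per_cell: int = 4
    process_length_um: float = 12.0
    axon_orientation_deg: float = 30.0
    process_kappa: float = 2.0
    axon_count: int = 3
    axon_width_um: float = 2.0
    overlap_fraction_target: float = 0.3
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ParameterError("resolution must be > 0")
        if not (self.field_size_um > 0):
            raise ParameterError("field_size_um must be > 0")
        if not (self.soma_major_um >= self.soma_minor_um > 0):
            raise ParameterError("need soma_major_um >= soma_minor_um > 0")
        if self.process_kappa < 0:
            raise ParameterError("process_kappa must be >= 0")
        if not (0 <= self.overlap_fraction_target <= 1):
            raise ParameterError("overlap_fraction_target must be in [0, 1]")
        if not (self.snr > 0):
            raise ParameterError("snr must be > 0 (use math.inf for noise-free)")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.n_cells < 0 or self.axon_count < 0 or self.n_processes_per_cell < 0:
            raise ParameterError("counts must be >= 0")

    @property
    def pixel_size_um(self) -> float:
        return self.field_size_um / self.resolution


@dataclass
class SynthTruth:
    """Ground truth emitted by every generator, enabling recovery tests.

    Only the fields relevant to the generating call are populated.  Angles
    are stored in [0, 360) degrees; coordinates and axes in µm.  Boolean
    ground-truth masks (``soma_mask``, ``microglia_mask``, ``axon_mask``) are
    kept in memory but omitted from :meth:`to_json_dict`.
    """

    event_times_s: dict | None = None          # roi_id -> sorted event times (s)
    shared_event_times_s: np.ndarray | None = None
    synchrony_fraction: float | None = None
    soma_centers_um: np.ndarray | None = None  # (n_cells, 2) as (x, y)
    soma_axes_um: np.ndarray | None = None     # (n_cells, 2) as (major, minor)
    soma_orientations_deg: np.ndarray | None = None
    process_angles_deg: np.ndarray | None = None
    axon_orientation_deg: float | None = None
    axon_endpoints_um: list | None = None      # [((x0,y0),(x1,y1)), ...]
    true_overlap_fraction: float | None = None
    pixel_size_um: float | None = None
    frame_interval: float | None = None
    track_directions_deg: np.ndarray | None = None
    soma_mask: np.ndarray | None = None
    microglia_mask: np.ndarray | None = None
    axon_mask: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        """JSON-serialisable view of the truth (masks omitted)."""
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        out = {}
        for name, value in self.__dict__.items():
            if name.endswith("_mask") or value is None:
                continue
            out[name] = conv(value)
        return out


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

def _event_signal(frame_times: np.ndarray, event_times: np.ndarray,
                  amplitudes: np.ndarray, tau: float) -> np.ndarray:
    """Sum of causal exponential-decay kernels sampled at the frame times."""
    signal = np.zeros_like(frame_times)
    for t_e, a in zip(event_times, amplitudes):
        causal = frame_times >= t_e
        signal[causal] += a * np.exp(-(frame_times[causal] - t_e) / tau)
    return signal


def simulate_traces(config: TraceSimConfig) -> tuple[list[FluorescenceTrace], SynthTruth]:
    """Simulate per-ROI fluorescence traces with known event times.

    Each ROI's trace is ``baseline_level × (1 + Σ events + noise)`` where
    events are instantaneous-rise, exponential-decay kernels of height
    ``amplitude`` (optionally log-normally jittered) and the noise is i.i.d.
    Gaussian in ΔF/F₀ units.  Shared events occur in every ROI at the same
    times; private events in a single ROI.  The truth records every event
    time per ROI plus the shared times and the synchrony fraction
    ``shared_rate / (shared_rate + private_rate)``.
    """
    rng = np.random.default_rng(config.seed)
    duration = config.duration_s
    frame_times = np.arange(config.n_frames) * config.frame_interval

    def draw_events(rate: float) -> np.ndarray:
        n = rng.poisson(rate * duration)
        return np.sort(rng.uniform(0.0, duration, size=n))

    def draw_amplitudes(n: int) -> np.ndarray:
        if config.amplitude_jitter_sd > 0:
            return config.amplitude * rng.lognormal(0.0, config.amplitude_jitter_sd, size=n)
        return np.full(n, config.amplitude)

    shared_times = draw_events(config.shared_rate)
    shared_amps = draw_amplitudes(shared_times.size)

    traces: list[FluorescenceTrace] = []
    event_times: dict[str, np.ndarray] = {}
    for i in range(config.n_rois):
        roi = f"roi_{i}"
        private_times = draw_events(config.private_rate)
        private_amps = draw_amplitudes(private_times.size)
        all_times = np.concatenate([shared_times, private_times])
        all_amps = np.concatenate([shared_amps, private_amps])
        order = np.argsort(all_times, kind="stable")
        signal = _event_signal(frame_times, all_times[order], all_amps[order], config.decay_tau)
        noise = rng.normal(0.0, config.noise_sd, size=config.n_frames) if config.noise_sd > 0 \
            else np.zeros(config.n_frames)
        values = config.baseline_level * (1.0 + signal + noise)
        traces.append(FluorescenceTrace(values=values, frame_interval=config.frame_interval,
                                        roi_id=roi))
        event_times[roi] = all_times[order]

    truth = SynthTruth(
        event_times_s=event_times,
        shared_event_times_s=shared_times,
        synchrony_fraction=config.synchrony_fraction,
        frame_interval=config.frame_interval,
    )
    return traces, truth


# ---------------------------------------------------------------------------
# two-channel image stacks
# ---------------------------------------------------------------------------

def _render_soma(canvas: np.ndarray, center_px: tuple[float, float],
                 semi_axes_px: tuple[float, float], orientation_deg: float) -> np.ndarray:
    """Paint one elliptical soma with a mild radial falloff; return its mask."""
    h, w = canvas.shape
    a, b = semi_axes_px
    cx, cy = center_px
    theta = np.deg2rad(orientation_deg)
    r0 = max(0, int(cy - a - 2)); r1 = min(h, int(cy + a + 3))
    c0 = max(0, int(cx - a - 2)); c1 = min(w, int(cx + a + 3))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    inside = rho2 <= 1.0
    profile = _SOMA_LEVEL * (1.0 - _SOMA_EDGE_FALLOFF * rho2)
    sub = canvas[r0:r1, c0:c1]
    np.copyto(sub, np.maximum(sub, np.where(inside, profile, 0.0)))
    mask = np.zeros_like(canvas, dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def _render_segment(shape: tuple[int, int], start_px: tuple[float, float],
                    angle_deg: float, length_px: float) -> np.ndarray:
    """Boolean mask of a ~2 px wide straight segment clipped to the field."""
    h, w = shape
    theta = np.deg2rad(angle_deg)
    x0, y0 = start_px
    x1 = x0 + length_px * np.cos(theta)
    y1 = y0 + length_px * np.sin(theta)
    r0, c0 = int(round(np.clip(y0, 0, h - 1))), int(round(np.clip(x0, 0, w - 1)))
    r1, c1 = int(round(np.clip(y1, 0, h - 1))), int(round(np.clip(x1, 0, w - 1)))
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_line(r0, c0, r1, c1)
    mask[rr, cc] = True
    return binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


def simulate_stack(config: StackSimConfig) -> tuple[np.ndarray, SynthTruth]:
    """Simulate a two-channel time-lapse stack with ground-truth masks.

    Returns a float32 array of shape (n_frames, 2, resolution, resolution);
    channel 0 is the microglia channel, channel 1 the axon channel.  The
    scene is static across frames; each frame adds Gaussian noise with
    per-pixel SD = intensity / snr (intensity-dependent, Poisson-like), so
    an SD time-projection reproduces the scene scaled by 1/snr.

    Somas are placed fully inside the field and pairwise non-overlapping
    (bounded retries, then a :class:`ParameterError`).  Process orientations
    are von Mises around ``axon_orientation_deg`` with concentration
    ``process_kappa``.  After rendering, axon pixels are added to the
    microglia channel as a contiguous patch until the microglia∩axon overlap
    reaches ``overlap_fraction_target`` of the axon area; the truth records
    the achieved fraction (which cannot drop below the incidental overlap of
    somas and processes).
    """
    rng = np.random.default_rng(config.seed)
    n = config.resolution
    px = config.pixel_size_um
    a_px = 0.5 * config.soma_major_um / px
    b_px = 0.5 * config.soma_minor_um / px

    # --- place somas: inside the field, pairwise separated -----------------
    margin = a_px + 3
    if 2 * margin >= n and config.n_cells > 0:
        raise ParameterError("somas cannot fit inside the field")
    centers: list[tuple[float, float]] = []
    max_tries = 400 * max(config.n_cells, 1)
    tries = 0
    min_sep = 2.4 * a_px
    while len(centers) < config.n_cells:
        if tries >= max_tries:
            raise ParameterError(
                f"could not place {config.n_cells} non-overlapping somas in the field "
                f"after {max_tries} attempts"
            )
        tries += 1
        cand = (rng.uniform(margin, n - margin), rng.uniform(margin, n - margin))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep for c in centers):
            centers.append(cand)

    mg = np.full((n, n), _BG_LEVEL, dtype=float)
    ax = np.full((n, n), _BG_LEVEL, dtype=float)

    soma_mask = np.zeros((n, n), dtype=bool)
    orientations = rng.uniform(0.0, 180.0, size=config.n_cells)
    for (cx, cy), ori in zip(centers, orientations):
        soma_mask |= _render_soma(mg, (cx, cy), (a_px, b_px), ori)

    # --- processes ---------------------------------------------------------
    process_mask = np.zeros((n, n), dtype=bool)
    process_angles = []
    mu = np.deg2rad(config.axon_orientation_deg)
    for (cx, cy), ori in zip(centers, orientations):
        for _ in range(config.n_processes_per_cell):
            theta = float(np.rad2deg(rng.vonmises(mu, config.process_kappa))) % 360.0
            process_angles.append(theta)
            # start on the soma boundary in the direction of travel
            th = np.deg2rad(theta)
            ori_r = np.deg2rad(ori)
            u = np.cos(th - ori_r)
            v = np.sin(th - ori_r)
            r_boundary = 1.0 / np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)
            sx = cx + r_boundary * np.cos(th)
            sy = cy + r_boundary * np.sin(th)
            process_mask |= _render_segment((n, n), (sx, sy), theta,
                                            config.process_length_um / px)
    process_mask &= ~soma_mask
    mg[process_mask] = np.maximum(mg[process_mask], _PROCESS_LEVEL)

    # --- axon bands --------------------------------------------------------
    axon_mask = np.zeros((n, n), dtype=bool)
    theta = np.deg2rad(config.axon_orientation_deg)
    direction = np.array([np.cos(theta), np.sin(theta)])
    normal = np.array([-np.sin(theta), np.cos(theta)])
    rr, cc = np.mgrid[0:n, 0:n]
    endpoints = []
    half_w = 0.5 * config.axon_width_um / px
    for _ in range(config.axon_count):
        anchor = np.array([rng.uniform(0.15 * n, 0.85 * n), rng.uniform(0.15 * n, 0.85 * n)])
        dist = np.abs((cc - anchor[0]) * normal[0] + (rr - anchor[1]) * normal[1])
        axon_mask |= dist <= half_w
        # chord endpoints where the centre line meets the field border (µm)
        ts = []
        for comp, base in ((direction[0], anchor[0]), (direction[1], anchor[1])):
            if abs(comp) > 1e-12:
                ts.extend([(0 - base) / comp, (n - 1 - base) / comp])
        ts = sorted(t for t in ts
                    if -1e-9 <= (p := anchor + t * direction)[0] <= n - 1 + 1e-9
                    and -1e-9 <= p[1] <= n - 1 + 1e-9)
        if len(ts) >= 2:
            p0 = (anchor + ts[0] * direction) * px
            p1 = (anchor + ts[-1] * direction) * px
            endpoints.append(((float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1]))))
    ax[axon_mask] = _AXON_LEVEL

    # --- drive the overlap to the target -----------------------------------
    mg_mask = soma_mask | process_mask
    axon_px_total = int(axon_mask.sum())
    if axon_px_total > 0 and config.overlap_fraction_target > 0:
        want = int(round(config.overlap_fraction_target * axon_px_total))
        have = int((mg_mask & axon_mask).sum())
        if want > have:
            cand = np.argwhere(axon_mask & ~mg_mask)
            proj = cand[:, 1] * direction[0] + cand[:, 0] * direction[1]
            order = np.argsort(proj, kind="stable")
            chosen = cand[order[: want - have]]
            patch = np.zeros((n, n), dtype=bool)
            patch[chosen[:, 0], chosen[:, 1]] = True
            mg_mask |= patch
            mg[patch] = np.maximum(mg[patch], _PROCESS_LEVEL)
    true_overlap = float((mg_mask & axon_mask).sum() / axon_px_total) if axon_px_total else 0.0

    # --- assemble noisy frames ---------------------------------------------
    stack = np.empty((config.n_frames, 2, n, n), dtype=np.float32)
    for ch, base in enumerate((mg, ax)):
        sd = base / config.snr if np.isfinite(config.snr) else None
        for f in range(config.n_frames):
            frame = base if sd is None else base + rng.normal(0.0, 1.0, size=base.shape) * sd
            stack[f, ch] = frame

    truth = SynthTruth(
        soma_centers_um=np.array(centers) * px,
        soma_axes_um=np.tile([config.soma_major_um, config.soma_minor_um],
                             (config.n_cells, 1)),
        soma_orientations_deg=orientations % 360.0,
        process_angles_deg=np.array(process_angles) % 360.0,
        axon_orientation_deg=config.axon_orientation_deg % 360.0,
        axon_endpoints_um=endpoints,
        true_overlap_fraction=true_overlap,
        pixel_size_um=px,
        frame_interval=config.frame_interval_min,
        soma_mask=soma_mask,
        microglia_mask=mg_mask,
        axon_mask=axon_mask,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# angle samples and tip trajectories
# ---------------------------------------------------------------------------

def simulate_angle_samples(
    group_specs: Sequence[tuple[int, float, float] | dict],
    seed: int | np.random.Generator | None = None,
) -> list[AngleSample]:
    """Draw one von Mises angle sample per group spec.

    Each spec is ``(n, mean_direction_deg, kappa)`` or a dict with keys
    ``n``, ``mean_deg``, ``kappa`` and optional ``group``.  κ = 0 draws from
    the circular uniform distribution.  Angles are returned in [0, 360)
    degrees.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = []
    for idx, spec in enumerate(group_specs):
        if isinstance(spec, dict):
            n, mean_deg, kappa = spec["n"], spec["mean_deg"], spec["kappa"]
            group = spec.get("group", f"group_{idx}")
        else:
            n, mean_deg, kappa = spec
            group = f"group_{idx}"
        if n < 2:
            raise ParameterError("each group needs n >= 2")
        if kappa < 0:
            raise ParameterError("kappa must be >= 0")
        draws = rng.vonmises(np.deg2rad(mean_deg), kappa, size=int(n))
        samples.append(AngleSample(np.rad2deg(draws) % 360.0, group=group))
    return samples


def simulate_tracks(
    n_tracks: int,
    direction_mean_deg: float,
    direction_kappa: float,
    speed_um_per_min: float = 0.3,
    duration_min: float = 60.0,
    dt_min: float = 2.0,
    jitter_sd_um: float = 0.2,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[ProcessTrack], SynthTruth]:
    """Simulate drifting process-tip trajectories with known directions.

    Each tip starts at the origin and drifts at ``speed_um_per_min`` along a
    von Mises direction, with i.i.d. Gaussian positional jitter per sample.
    ``speed_um_per_min = 0`` produces (jittered or exactly stationary)
    zero-drift tracks for exercising the zero-displacement exclusion.
    """
    if n_tracks < 1:
        raise ParameterError("n_tracks must be >= 1")
    if direction_kappa < 0:
        raise ParameterError("direction_kappa must be >= 0")
    if not (dt_min > 0 and duration_min >= dt_min):
        raise ParameterError("need dt_min > 0 and duration_min >= dt_min")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 0.5 * dt_min, dt_min)
    directions = np.rad2deg(
        rng.vonmises(np.deg2rad(direction_mean_deg), direction_kappa, size=n_tracks)
    ) % 360.0
    tracks = []
    for i, theta in enumerate(directions):
        th = np.deg2rad(theta)
        x = speed_um_per_min * times * np.cos(th)
        y = speed_um_per_min * times * np.sin(th)
        if jitter_sd_um > 0:
            x = x + rng.normal(0.0, jitter_sd_um, size=times.size)
            y = y + rng.normal(0.0, jitter_sd_um, size=times.size)
            x[0] = y[0] = 0.0  # the start point is the tracking anchor
        tracks.append(ProcessTrack(times_min=times, x_um=x, y_um=y, track_id=f"track_{i}"))
    truth = SynthTruth(track_directions_deg=directions)
    return tracks, truth
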