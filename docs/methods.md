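# Methods

This note records the models, conventions and numerical choices behind each
stage of the package, the reasoning for defaults, and what the synthetic
generators do and do not emulate. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Calcium-trace analytics

**Baseline.** F₀ is a percentile (default 35) of the whole-session
fluorescence histogram, computed with linear interpolation between order
statistics (the `numpy.percentile` convention). A percentile below the
median is deliberate for calcium data: activity only adds fluorescence, so a
low percentile tracks the quiescent level. A consequence worth keeping in
mind (it drives the detection choices below) is that for the noise-dominated
portion of a trace the 35th percentile sits z(0.35) ≈ 0.385 noise-SD below
the noise median, so ΔF/F₀ noise is centred slightly above zero.

**Noise SD.** The detection threshold needs the SD of the baseline noise,
which the recording itself must supply. The default estimator uses only
frames at or below the trace median — transient-dominated frames are above
it — and takes the RMS deviation about the median. For symmetric noise this
is unbiased for the full noise SD (E[X² | X ≤ 0] = σ² for X ~ N(0, σ)); the
plain SD of a below-median half-sample would come out ≈ 0.60σ and place a
"2 SD" threshold at ~1.2σ, which is unusable. A full-trace SD is available
(`noise_method="full"`); it overestimates σ in proportion to event density.

**Transient detection.** A transient is a maximal run of frames with
ΔF/F₀ > `sd_multiplier` (default 2) × noise SD, at least
`min_duration_frames` long. The API default of 2 frames rejects isolated
single-frame spikes. For long sessions a stricter run length is advisable,
and the recovery analyses in the test suite and acceptance script use
4 frames: with the baseline offset above, the effective threshold margin is
≈ 1.67σ, and the expected number of spurious runs per 558-frame session is
≈ 1.3 for 2-frame runs, ≈ 0.06 for 3-frame and ≈ 0.003 for 4-frame runs,
while a real event at the default simulation settings (amplitude 10× noise,
decay 1 s, 0.25 s frames) stays suprathreshold for ~7 frames. Four frames
is therefore essentially free in sensitivity and makes per-trace event
counts reliable.

**Frequency and power.** Frequency is event count divided by session
duration in seconds. Power is the mean squared ΔF/F₀ over the transient's
frames, p = (1/T)Σxᵢ².

**Correlations.** Pearson's r centres both vectors; the cosine correlation
does not. Both are computed on ΔF/F₀, clamped to [−1, 1] against rounding.
Undefined pairs (a zero-norm trace for r_c, a constant trace for r_p) are
recorded as missing, excluded from the session mean and counted — never
imputed. Standardization to a pre session is a ratio by default (the pre
session maps to exactly 1); a difference mode exists for cohorts whose pre
mean is near zero.

## Microglial morphometry

**Projection.** SD time-projections (population SD, divisor N). Under
intensity-dependent noise the projection is proportional to local
brightness, so static and motile structures both appear (see the noise
model below).

**Soma extraction.** Seeds are local intensity maxima above a configurable
floor (`peak_local_max` with a minimum separation, default 20 px ≈ 10 µm at
the spinal pixel size), or an explicit list for manually curated workflows.
The region is the 8-connected component of pixels at least half the seed
intensity containing the seed — the wand-tool rule with the tolerance set at
half the maximum-intensity point. "Half the seed intensity" (not halfway
between seed and background) is the default reading; `half_max_mode=
"midpoint"` gives the alternative. Regions capturing more than one accepted
seed cannot be attributed to a single cell and are excluded
("indistinguishable neighbors"), as are regions touching the field border,
whose truncated shapes would bias the ellipse fit. An optional Gaussian
pre-smoothing (σ = 1 px in the CLI pipeline) stabilises seeding and growth
against pixel noise.

**Shape metrics.** The equivalent ellipse comes from second-order central
moments of the pixel set (a filled ellipse recovers its own axes). Aspect
ratio = major/minor; roundness = 4A/(π·major²); circularity = 4πA/P²
clamped at 1. The perimeter is the 4-direction Crofton estimate: measured on
a rasterised radius-20 disc it yields circularity ≈ 1.0 and is
rotation-stable to ~3%, whereas the weighted chain-code estimate
(1/√2 weights) undershoots a disc to circularity ≈ 0.95 and would make the
clamp meaningless. Densities are the included-cell count per field and per
mm² (count / (field/1000)²).

## Microglia–axon interaction

**Binarization.** Otsu's threshold on a 256-bin histogram spanning the
observed min–max range (inputs may exceed 8 bits); foreground is strictly
above the threshold. A constant image has no threshold and is an error.
Note that when the histogram valley between classes is empty the
between-class variance is flat there, so two implementations can return
different thresholds that induce the same partition; tests therefore compare
achieved between-class variance, not threshold location.

**Colocalization.** The merged mask is the pixelwise AND; the ratio is
merged area / axon foreground area. The session-level mode binarises the SD
time-projection of each channel (a per-frame mode exists). The ratio is
undefined for an empty axon mask.

**Process polarity.** A tip track's moving vector runs from its first
position to the in-window position farthest from it (earliest on ties;
window default 60 min). The angle convention is image coordinates: +x
rightward, +y downward, counter-clockwise degrees in [0, 360). Tracks whose
farthest point coincides with the start are flagged and excluded from angle
samples rather than assigned 0° (which would bias the polarity
distribution). Differences between directions — process vs process or
process vs axon axis — are folded axially: d = |θ₁−θ₂| mod 180, then
min(d, 180−d) ∈ [0°, 90°]. The axon axis is the orientation (mod 180°) of
the chord joining the visible segment's endpoints, which are supplied (by
the generator or a config), not auto-detected.

## Uniform-scores (Mardia–Watson–Wheeler) test

Pooled angles are ranked (average ranks on ties), mapped to circular scores
βᵢ = 2πRᵢ/N, and W = 2Σⱼ(Cⱼ²+Sⱼ²)/nⱼ is referred to χ² with 2(k−1) df.
Folded [0°, 90°] inputs are mapped onto the full circle by ×4 before ranking
— the axial-to-circular doubling applied twice for quarter-circle data. The
map is strictly monotone on [0, 90], so ranks and W are identical with or
without it; the flag exists for interpretability and input validation.
Method `auto` switches to label permutation when any group has fewer than 10
angles (the asymptotic null is unreliable there); permutation p-values carry
the +1 correction and are never exactly 0; an exact method enumerates all
label assignments for two small groups. When more than 10% of pooled angles
are tied a warning recommends the permutation method, since heavy ties
degrade the asymptotic null.

## Synthetic data: what it emulates, and what it does not

**Traces.** Events are homogeneous Poisson processes — one shared stream
injected into every ROI plus an independent private stream per ROI — passed
through an instantaneous-rise, single-exponential-decay kernel (the simplest
shape consistent with a fast indicator). Noise is i.i.d. Gaussian in ΔF/F₀
units; the trace is baseline × (1 + signal + noise). The ground-truth
synchrony fraction is shared_rate/(shared_rate+private_rate). Defaults: 10
ROIs, 558 frames at 0.25 s (139.5 s session), amplitude 1.0 ΔF/F₀, decay
1 s, noise SD 0.1 (SNR 10), baseline 100 a.u. The event rates and SNR are
free parameters of the generator, documented here as the package's chosen
simulation conditions — not claims about any particular recording.

**Stacks.** A static scene: elliptical somas (major 14 µm, minor 10 µm by
default) with a mild radial intensity falloff (1.0 at the centre to 0.85 at
the edge — a flat profile would have no unique maximum-intensity point for
seeding), straight ~2 px processes at von Mises orientations about the axon
direction, and straight axon bands. Noise is Gaussian with per-pixel
SD = intensity/SNR — a Poisson-like, intensity-dependent model chosen so SD
time-projections reveal structure the way they do for real shot-noise-
limited recordings. Process intensity is 0.45 of the soma peak: bright
enough that the microglia channel's histogram stays effectively bimodal for
Otsu, yet below the soma half-max so wand growth never leaks into
processes. The microglia∩axon overlap is driven to a target fraction by
adding a contiguous patch of axon pixels to the microglia channel; the
achieved fraction (recorded in the truth) cannot fall below the incidental
soma/process overlap. Field geometry defaults to the spinal acquisition:
264.90 µm square at 512 px (0.517 µm pixels), 90 frames at 2 min.

Not emulated: optical PSF blur, motion artifacts (inputs are assumed
registered), process tortuosity and remodelling, 3-D structure (frames are
2-D projections), photobleaching, and spatially correlated noise. Passing
recovery tests on this generator therefore demonstrates correctness of the
measurement pipeline, not robustness to every property of real data.

**Angles and tracks.** Angle samples are von Mises draws (κ = 0 is the
circular uniform). Tip tracks drift at constant speed along a von Mises
direction with i.i.d. positional jitter; zero-speed tracks exercise the
zero-displacement exclusion.

All generators draw every random quantity from a single seeded
`numpy.random.Generator` per call; identical configs and seeds give
bit-identical outputs.

## Problem sizes used by the test suite and acceptance script

Chosen to make recovery statistics stable: synchrony ordering uses 20
replicate sessions per synchrony fraction (10 ROIs, 558 frames); transient
count recovery uses 20 single-ROI sessions at 0.01 events/s and rate
recovery pools 20 sessions × 20 ROIs at 0.02 events/s; stack recovery uses
one 512 px, 40-frame stack at SNR 10; the test calibration uses 2000
uniform-null replicates (type-I), 200 replicates of 9999 permutations
(asymptotic agreement), and full enumeration at n₁ = n₂ = 3; polarity uses
500 tracks at κ = 20 (aligned) and κ = 0 (uniform).

## Known limitations

- The half-max wand rule assumes one dominant intensity maximum per cell;
  heavily overlapping cells are excluded rather than split.
- Otsu binarization assumes an (effectively) bimodal channel histogram; a
  channel whose foreground splits into very different brightness classes can
  threshold between them.
- The moving-vector angle is undefined for stationary tips; sessions with
  many stationary processes yield small angle samples.
- The asymptotic MWW null degrades under heavy ties (warned) and for groups
  under ~10 angles (auto-switches to permutation).
- CLI `simulate` applies shared config keys (e.g. `n_frames`, `seed`) to
  both the trace and stack generators.
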