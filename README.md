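# gliasync

Analytics for two-photon imaging studies of cortical neuron populations and
spinal microglia: calcium-transient detection and cosine-correlation
synchrony for layer-5 motor-cortex recordings, microglial soma morphometry,
microglia–axon colocalization, and process-polarity circular statistics —
together with synthetic-data generators that emit full ground truth, so every
stage of the pipeline can be validated by parameter recovery.

The package is aimed at labs quantifying how cortical population activity
relates to microglial behaviour after spinal cord injury (or under
neuromodulation such as tDCS), and at anyone who needs a tested, scriptable
replacement for the usual ImageJ + MATLAB patchwork for these measurements.

## What it computes

**Calcium traces.** For each ROI's raw fluorescence F, the baseline F₀ is the
35th percentile of the whole-session intensity histogram, and activity is
ΔF/F₀ = (F − F₀)/F₀. A transient is a suprathreshold run of frames with
ΔF/F₀ > 2·SD of the baseline noise; each transient is summarised by its peak
and its power

&nbsp;&nbsp;&nbsp;&nbsp; p<sub>x</sub> = (1/T) Σᵢ xᵢ² ,

the mean squared ΔF/F₀ over the transient. Population synchrony uses the
**cosine correlation**

&nbsp;&nbsp;&nbsp;&nbsp; r<sub>c</sub> = Σᵢ xᵢyᵢ / (√Σᵢ xᵢ² · √Σᵢ yᵢ²)

instead of Pearson's r<sub>p</sub>: calcium transients are non-negative and
sparse, so centring turns long mutual silences into spuriously correlated
negative excursions, whereas r<sub>c</sub> stays near zero unless the two
neurons co-fire. Session synchrony (the mean of r<sub>c</sub> over ROI
pairs) can be standardized to a pre-operation session.

**Microglial morphometry.** SD time-projections of the microglia channel,
wand-style soma extraction (8-connected growth from an intensity maximum
down to half the maximum-intensity point), and equivalent-ellipse shape
descriptors: area, aspect ratio (major/minor), circularity (4πA/P²) and
roundness (4A/(π·major²)), plus cell densities per field and per mm².

**Microglia–axon interaction.** Per-channel Otsu binarization (256-bin
histogram) and the colocalization ratio = merged area / axon area; moving
vectors of tracked process tips (displacement to the farthest in-window
point), angles folded axially to [0°, 90°] against the axon axis, and
empirical CDFs of folded angles.

**Circular statistics.** The k-sample Mardia–Watson–Wheeler uniform-scores
test: pooled angles are replaced by circular ranks βᵢ = 2πRᵢ/N and

&nbsp;&nbsp;&nbsp;&nbsp; W = 2 Σⱼ (Cⱼ² + Sⱼ²)/nⱼ ,  Cⱼ = Σ cos βᵢ, Sⱼ = Σ sin βᵢ over group j,

with an asymptotic χ²(2(k−1)) p-value, a label-permutation p-value, or exact
enumeration for small two-group designs.

**Synthetic data.** Generators for correlated calcium traces (shared vs
private Poisson events through an exponential-decay kernel), two-channel
time-lapse stacks (elliptical somas, straight processes with von Mises
orientations, axon bands, intensity-dependent noise, controlled overlap
fraction), von Mises angle samples and drifting tip trajectories — each
returning a `SynthTruth` record with every event time, soma axis, process
angle and overlap fraction.

## Worked example

```python
import numpy as np
import gliasync as g

cfg = g.TraceSimConfig(n_rois=10, shared_rate=0.03, private_rate=0.02, seed=42)
traces, truth = g.simulate_traces(cfg)
dffs = [g.compute_dff(t) for t in traces]
events = [g.detect_transients(d, min_duration_frames=4) for d in dffs]
freq = np.mean([g.transient_frequency(e, t.duration_s) for e, t in zip(events, traces)])
power = np.mean([ev.power for e in events for ev in e])
sync = g.pairwise_synchrony(dffs)
print(f"true synchrony fraction : {truth.synchrony_fraction:.2f}")
print(f"mean transient frequency: {freq:.4f} events/s")
print(f"mean transient power    : {power:.3f} (dF/F0)^2")
print(f"mean cosine correlation : {sync.mean_offdiagonal():.3f}")
sessions = {"Pre": sync.mean_offdiagonal(), "POD2": 0.21, "POD4": 0.30, "POD7": 0.38}
for s in g.standardize_to_pre(sessions):
    print(f"{s.session:>5}: r_c={s.mean_correlation:.3f}  standardized={s.standardized:.2f}")
```

prints

```
true synchrony fraction : 0.60
mean transient frequency: 0.0573 events/s
mean transient power    : 0.388 (dF/F0)^2
mean cosine correlation : 0.574
  Pre: r_c=0.574  standardized=1.00
 POD2: r_c=0.210  standardized=0.37
 POD4: r_c=0.300  standardized=0.52
 POD7: r_c=0.380  standardized=0.66
```

The simulated session mixes shared (population-wide) and private events in a
3:2 rate ratio, so the ground-truth synchrony fraction is 0.60; the mean
pairwise cosine correlation of 0.574 reflects that co-firing, and the
standardized rows show how later sessions would read relative to this
pre-operation baseline (here with illustrative later-session means).

The same analyses run from the shell:

```bash
gliasync all --out-dir run1 --seed 7         # simulate + every stage
gliasync calcium --traces run1/sim/traces.csv --out-dir run1/calcium
gliasync mww --angles run1/mww_input.csv --out-dir run1/mww
```

Each stage writes its tables (CSV), the resolved configuration and a
`report.json`; runs are deterministic for a fixed seed.

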