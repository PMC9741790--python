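# gaitent

Sample-entropy analysis of treadmill gait signals: how regular is a person's
walking pattern, and how does that answer depend on the way the signals are
preprocessed and on the entropy parameters?

During instrumented-treadmill walking, three time series summarize the
interaction between the feet and the ground: the center-of-pressure
displacement in the anterio-posterior (COPap) and medio-lateral (COPml)
directions, and the resultant vertical ground reaction force (vGRF), sampled
here at 100 Hz. Sample Entropy (SampEn) is a popular regularity index for
such signals, but it is known to be sensitive to its template length *m* and
to how the signal was segmented, resampled and detrended before analysis.
`gaitent` is a tested pipeline for studying exactly that sensitivity, and
for comparing walking conditions (preferred vs. maximum tolerated speed)
once the preprocessing is fixed. It is aimed at movement scientists and
biomechanists who want the whole chain — from raw (or synthetic) recordings
to ANOVA tables — reproducible from one seed.

## The statistic

For a series of N points, template length m and tolerance r,

```
SampEn(m, r, N) = −ln [ A^{m+1}(r) / B^m(r) ]
```

where B counts pairs of m-length subsequences whose Chebyshev distance is
≤ r (self-matches excluded), and A counts the same pairs still matching when
extended to m+1 samples, both over template indices 0 … N−m−1. A perfectly
repetitive series gives 0; irregular series give larger values. Here r is
0.2 × the series' SD by default and m ranges over {2, 4, 6, 8, 10}.

Four signal forms are analyzed per channel:

| form  | meaning |
|-------|---------|
| WHOLE | raw series truncated to a common length (default 2200 points) |
| SEGM  | each stride resampled to 100 points and concatenated |
| NORM  | SEGM, each cycle additionally rescaled to span [0, 1] (COP only) |
| ZERO  | SEGM, each cycle translated to start at (0, 0) (COP only) |

Strides are detected from the vGRF alone: its two per-stride single-support
valleys are phase-stable landmarks, and every second valley marks a stride
of the same leg. A synthetic generator produces quasi-periodic recordings
(mean stride time 1.06 s, configurable stride-time variability, per-stride
waveform jitter, noise and treadmill drift) with ground-truth boundaries, so
every stage is testable without measured data.

## Worked example

```python
from gaitent import (GaitParams, generate_recording, segment_strides,
                     trim_first_last, segment_resample, zero_cycles,
                     sampen_grid, template_time_span, min_neuromotor_interval)

params = GaitParams(seed=42, n_strides=30)
rec = generate_recording(params)
seg = segment_strides(rec)
print(f"{seg.n_strides} strides, mean duration {seg.stride_durations.mean():.3f} s")

rec_t, seg_t = trim_first_last(rec, seg)
ap = segment_resample(rec_t, seg_t, "copap", samples_per_cycle=100)
z_ap, _ = zero_cycles(ap, segment_resample(rec_t, seg_t, "copml", 100))
for name, sig in (("SEGM", ap), ("ZERO", z_ap)):
    for cell in sampen_grid(sig, [2, 6], [0.2]):
        print(f"COPap {name} m={cell.m}: SampEn = {cell.result.value:.3f} "
              f"(A={cell.result.A}, B={cell.result.B}, r={cell.result.effective_r:.3f})")
print("template span m=6:", template_time_span(6, 1.06, 100), "s")
print("minimal neuromotor interval at 16 Hz:", min_neuromotor_interval(16), "s")
```

prints

```
28 strides, mean duration 1.064 s
COPap SEGM m=2: SampEn = 0.200 (A=312106, B=381341, r=2.447)
COPap SEGM m=6: SampEn = 0.085 (A=190388, B=207250, r=2.447)
COPap ZERO m=2: SampEn = 0.202 (A=306082, B=374541, r=2.461)
COPap ZERO m=6: SampEn = 0.084 (A=185238, B=201443, r=2.461)
template span m=6: 0.064 s
minimal neuromotor interval at 16 Hz: 0.063 s
```

The fore-aft COP is quite regular (low SampEn), entropy drops as the
template lengthens from 2 to 6 samples, and zeroing barely changes it in
the absence of drift. The last two lines are the biological-relevance
arithmetic behind choosing m = 6: a 6-sample template on a 1.06 s stride
resampled to 100 points spans 0.064 s, just above the ≈0.063 s (1/16 Hz)
interval below which gait force signals carry little neuromotor content.

The same steps are available from a shell:

```
gait synth --out rec.csv --seed 42
gait segment rec.csv --out bounds.json
gait preprocess rec.csv --boundaries bounds.json --type zero --variable copap --out zero.csv
gait sampen zero.csv --m 6 --r-factor 0.2
gait run --out results/ --seed 0        # full experiment: tables + ANOVAs
```

`gait run` synthesizes a cohort (default 23 subjects × 2 walking
conditions), computes the SampEn grid for every subject, channel and signal
form, and writes `sensitivity.csv`, per-condition Type × m ANOVA JSONs, the
mixed (velocity within-subject) ANOVA at m = 6 and a velocity-comparison
table with 0.95 confidence intervals.

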