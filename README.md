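# beatkit

Quantification toolkit for time-lapse microscopy of the larval zebrafish
heart. It turns raw acquisitions plus light manual annotation into the
numbers a valve-development study runs on:

* **AV flow profile** — per-cycle percentages of anterograde (atrium →
  ventricle), retrograde, and no-flow blood movement through the
  atrioventricular (AV) canal, averaged over three beating cycles, plus the
  heart rate, from brightfield movies (240 frames/s, 1.92 µm/px).
* **Heart midline segmentation** — a mid-distance midline between two
  manually traced heart walls, computed independently per chamber, cut into
  100 segments with per-segment diameter and mean fluorescence intensity.
* **4D calcium assembly** — retrospective phase alignment of 50 plane-wise
  GCaMP6s movies (50 frames/s, 4 µm z-step), maximum z-projection, and
  atrial diastole/systole frame selection feeding the midline profiler.
* **Valve morphometry** — superior-leaflet length and binary elongation
  calls per z-stack, and deduplicated valve-cell counts by linking nucleus
  detections across planes.
* **Statistics** — two-sided Fisher exact test (exact integer enumeration),
  two-sided Student's *t*, group summaries with inclusive-median quartiles,
  and 2^−ΔΔCt qPCR fold changes against a reference gene (*eef1b2*).

Because such datasets are rarely shareable, the package ships a seeded
**synthetic beating-heart generator** (`beatkit.synthetic`): a two-chambered
contracting tube with advected blood speckle following a configurable
anterograde/retrograde/no-flow schedule, plane-wise endocardial fluorescence
with unknown per-plane acquisition phase, and static expression stacks —
each returning the ground truth that every analysis stage is tested
against.

## The core quantities

For a kymograph sampled along the midline through the AV canal, the
displacement between consecutive lines is estimated by normalized
cross-correlation with parabolic sub-sample refinement; frame pairs are
classified by a speed threshold *v*₀:

    |d|·f  <  v₀            →  no-flow
    d > 0  (toward ventricle) →  anterograde
    d < 0                    →  retrograde

with *d* the displacement (µm/frame) and *f* the frame rate. Percentages are
computed per beating cycle (cycles delimited by atrial-diastole peaks of the
atrial diameter trace) and averaged over the first three complete cycles.

The midline between wall traces *A* and *B* is the curve with
d(x, A) = d(x, B), initialized by per-chamber arc-length pairing and refined
by mid-distance projection; diameters are wall-to-wall chords normal to the
midline. The Fisher *p* is Σ P(T) over all tables *T* with the observed
margins and P(T) ≤ P(observed); fold changes are 2^−ΔΔCt with
ΔCt = Ct_gene − Ct_ref and ΔΔCt = ΔCt_test − mean(ΔCt_control).

## Worked example

```python
import beatkit
from beatkit import flow

config = beatkit.HeartSimConfig(seed=1)   # 70/20/10 schedule, 2.5 Hz, 240 fps
movie, truth = beatkit.simulate_brightfield_movie(config)
annotation = beatkit.synthetic_annotation(config)

profile = flow.analyze_movie(movie, annotation)
print(profile.as_series().round(2))
```

```
anterograde_pct     71.23
retrograde_pct      19.52
no_flow_pct          9.25
heart_rate_bpm     149.92
n_cycles_used        3.00
dtype: float64
```

The simulated schedule spends 70% of each cycle in anterograde flow, 20%
retrograde and 10% with no flow at 2.5 Hz (150 beats/min); the recovered
3-cycle-averaged percentages land within ~1 point of that and the heart rate
within 0.5%. The same movie's annotation, reversed end-to-end, swaps the
anterograde and retrograde percentages exactly.

The same stages are exposed on the command line:

```bash
beatkit simulate brightfield --seed 1 --out sim/
beatkit flowprofile --movie sim/brightfield.tif \
    --annotation sim/brightfield.annotation.json --out profile.csv
beatkit stats fisher --table 32,2,5,8
```

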