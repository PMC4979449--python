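# conemosaic

Cone photoreceptor mosaic morphometry for adaptive-optics scanning laser
ophthalmoscopy (AO-SLO) images.

In confocal AO-SLO the parafoveal cone mosaic appears as a quasi-hexagonal
array of bright spots, one per cone, each approximately Gaussian in profile.
In healthy eyes at 1.0 mm eccentricity the spot diameters concentrate in a
3.5–5.0 μm band; in degenerating retinas (retinitis pigmentosa, RP) a small
population of abnormally large spots (≥6.0 μm) appears, consistent with
necrotic cone swelling. This package implements the full measurement chain
needed to quantify that signal, for researchers analyzing AO-SLO frame
stacks or validating cone-sizing methodology on synthetic data:

1. **Frame processing** — translation registration (phase correlation) and
   averaging of the ~32 frames acquired per retinal region.
2. **Cone labeling** — eccentricity-tuned low-pass filtering followed by
   greedy local-maximum detection with sub-pixel refinement, plus merge of
   manual add/remove edits.
3. **Spot sizing** — per-cone scale selection: the scale-normalized
   Laplacian of Gaussian

   $$R(\mathbf{x},\sigma) = -\sigma^2\,\nabla^2 (G_\sigma * I)(\mathbf{x})$$

   is maximized over σ at each labeled cone; for a Gaussian spot of width
   σ₀ the extremum falls exactly at σ = σ₀ with value A/2. The physical
   spot diameter is d = 2√2·σ_max·(pixel scale), the full width at 1/e of
   the peak; spots with d ≥ 6.0 μm are classed as enlarged.
4. **Cohort statistics** — per-eye pooling over four regions, size
   histograms, the enlarged-spot percentage, Welch/Student t tests, Pearson
   χ², and one-way ANOVA with Tukey–Kramer pairwise adjustment.
5. **Synthetic mosaics** — a generator of AO-SLO-like frame stacks
   (340×340 μm at 0.85 μm/px) with full per-spot ground truth, so every
   stage is testable without patient images.

## Worked example

`examples/` contains one short script per capability. Detecting and sizing
the spots of a synthetic degenerating mosaic (`examples/04_measure_spot_sizes.py`):

```python
import numpy as np
import conemosaic as cm

mosaic, truth = cm.generate_mosaic(cm.rp_profile(seed=4))
cones = cm.detect(mosaic)
measurements = cm.measure_all(mosaic, cones)
diam = np.array([m.diameter_um for m in measurements if m.ok])
```

prints

```
measured 1217 spots, 1026 pass QC
median diameter: 4.24 um (healthy band: 3.5-5.0 um)
enlarged (>=6.0 um): measured 4.39 % vs truth 5.48 %
modal bin: 4.0-4.5 um (58.0 % of spots)
```

i.e. the median spot sits inside the healthy band, the modal histogram bin
is 4.0–4.5 μm, and the measured enlarged-spot percentage tracks the
generator's truth within about one percentage point (spots near the image
border or without a clean scale-space extremum are QC-flagged and
excluded). The cohort layer (`examples/05_cohort_statistics.py`) then
summarizes the bundled ten-case RP reference table (enlarged spots
5.3 ± 2.7 %, range 0.5–10.3) and shows that a 7-control vs 10-RP cohort
with 0.5% vs 5% true enlarged fractions separates decisively under
Welch's t (p ≈ 1e-10).

A thin CLI mirrors the library:
`conemosaic simulate | average | detect | measure | cohort | run | report`.

## Layout

- `src/conemosaic/` — `synthetic`, `frames`, `labeling`, `sizing`,
  `cohort`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `tests/` — unit, property and end-to-end acceptance tests
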