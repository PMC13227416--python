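# cardiodyn

Quantification of heart-tube formation dynamics in *Drosophila* embryos:
luminal closure kinetics and shape, cardioblast oscillatory migration, and
female-vs-male group comparison — with a ground-truth synthetic-data
generator for validating every estimator.

During *Drosophila* cardiogenesis, two contralateral rows of 52 cardiac
progenitors (cardioblasts) migrate toward the dorsal midline and seal a
tube. The migration is not smooth: cardioblasts take cyclic medial
(forward) and lateral (backward) steps whose difference — the net medial
step — drives closure. This package takes the outputs of image annotation
(luminal outlines as polygons, nuclear centroid tracks as tables, both in
μm) and computes the field's standard measurements:

* **Closure kinetics** — luminal area a(t) is registered in time at the
  last frame where the outline's medial-lateral extent exceeds 80 μm, and
  fitted with a decaying exponential

      a(t) = A e^(−kt)

  giving the closure rate constant k in hr⁻¹.
* **Lumen morphometrics** — per-frame area, perimeter, circularity
  c = 4πa/p², and the maximum AP/ML luminal lengths obtained by rotating
  the outline so its longest (maximum-caliper) axis is vertical.
* **Cardioblast dynamics** — contralateral pairing by AP rank,
  nucleus-to-nucleus distance registration at 65 μm, migration speed (slope
  of distance travelled vs time, μm/hr), oscillation period (first
  significant autocorrelation peak of the medial velocity, min), and
  medial/lateral step amplitudes with their difference, the net medial
  step (μm).
* **Group statistics** — per-embryo means compared between females and
  males with an exact two-sided Mann-Whitney U test (full null distribution
  for groups ≤ 10, tie-corrected normal approximation otherwise), with
  mean / s.d. / s.e.m. summaries.
* **Synthetic data** — seeded generators for closing lumens, oscillating
  track cohorts and rendered image stacks with exact ground truth, plus
  kymograph construction.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
from cardiodyn import (closure_rate_pipeline, embryo_oscillation_summary,
                       gen_lumen_series, gen_tracks)
from cardiodyn.simulate import LumenSimParams, TrackSimParams

# a lumen closing at k = 1.4 /hr with 5% area noise
params = LumenSimParams(A0=1000.0, k_true=1.4, area_noise_frac=0.05, seed=42)
fit = closure_rate_pipeline(gen_lumen_series(params))
print(f"k = {fit.k:.3f} /hr, A = {fit.A:.1f} um^2")

# an embryo of 104 oscillating cardioblasts
tracks = gen_tracks(TrackSimParams(seed=42))
s = embryo_oscillation_summary(tracks)
print(f"speed = {s['speed']:.1f} um/hr, period = {s['period']:.2f} min")
```

prints

```
k = 1.386 /hr, A = 992.9 um^2
speed = 22.8 um/hr, period = 1.70 min
```

The recovered rate constant sits within the 5% noise of the generating
1.4 hr⁻¹, the amplitude near the generating 1000 μm², and the embryo mean
speed and period recover the generating drift (23 μm/hr) and oscillation
period (1.7 min).

## Command line

The same analysis runs as a four-stage CLI over a shared YAML config:

```sh
cardiodyn simulate --config config.yaml --out data/
cardiodyn quantify --data data/ --config config.yaml --out metrics/
cardiodyn compare  --metrics metrics/ --out results/
cardiodyn kymograph --stack movie.tif --rect 10,20,200,40 \
    --axis horizontal --out kymo.tif
```

`simulate` writes a two-group cohort (7 + 8 lumen embryos, 6 + 6 track
embryos by default) with its ground-truth table; `quantify` emits per-frame
lumen metrics, per-embryo closure fits, and per-cardioblast/per-embryo
oscillation tables; `compare` emits one Mann-Whitney comparison row per
metric. Every output directory carries a `manifest.json` with the config
snapshot, input checksums, seed and all warnings. Fixed seeds give
byte-identical tables across runs.

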