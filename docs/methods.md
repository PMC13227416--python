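# Methods

cardiodyn quantifies two aspects of *Drosophila* heart-tube formation from
time-lapse annotations: the kinetics and shape of luminal closure, and the
oscillatory migration of the cardioblasts that build the tube. This note
documents the models, the numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Coordinate and time conventions

All positions are in micrometres with x along the medial-lateral (ML) axis
and y along the anterior-posterior (AP) axis. The origin is arbitrary per
embryo; every computation uses differences only. Frames are integer indices
sampled at a fixed interval (15 s by default, matching spinning-disk
acquisition cadence); physical time is `frame_index * frame_interval`.

## Luminal closure

**Registration.** Embryos are aligned in time at t0, the *last* frame at
which the ML extent of the luminal outline exceeds 80 μm. The biological
definition is the distance between the contralateral F-actin cables; since
the lumen is bounded by those cables, the outline's ML extent is used as its
proxy. Whether cable distance and lumen extent coincide exactly at every
frame cannot be established from annotations alone — this is a documented
operationalization. If no frame exceeds the threshold, t0 falls back to the
first frame with a logged warning. An analogous rule registers nuclear
tracks at the last frame where the mean contralateral nucleus-to-nucleus
distance exceeds 65 μm.

**Kinetics.** The registered luminal area is fitted with a decaying
exponential, a(t) = A·e^(−kt), by damped nonlinear least squares
(trust-region reflective) initialised from the log-linear regression of
ln(a) on t, with k constrained non-negative. Only frames with registered
t ≥ 0 enter the fit: pre-origin frames are plateau, not decay. A is a free
parameter rather than pinned to a(0); freeing it absorbs registration noise
in the first post-origin frame. k is reported in hr⁻¹. A non-converged
optimizer sets `converged=False` rather than raising.

**Morphometrics.** Area and perimeter come from the polygon itself (the
closing edge is always included; a repeated final vertex is deduplicated at
load). Circularity is 4πa/p², which is 1 for a circle and below 1 otherwise;
polygonal discretization keeps it within an isoperimetric slack of 1e−9.
The maximum AP and ML luminal lengths are measured by rotating the outline
about its centroid so that its longest axis is vertical and reading the y-
and x-extents. "Longest axis" is the maximum-caliper diameter of the convex
hull — the literal longest chord — found by pairwise search over hull
vertices; the construction is rotation-invariant and is verified in the test
suite against a 0.01° brute-force rotation grid.

## Cardioblast migration

**Pairing and midline.** Left- and right-row tracks are paired by AP rank
(i-th of each row sorted by mean y). Cardioblast rows are ordered
collectives with preserved neighbour relationships, so rank pairing is used
instead of optimal assignment; surplus tracks on the longer row are logged
and skipped. The midline x is the mean over frames of the midpoint between
the row mean x positions — no absolute reference exists in the annotations.

**Speed.** Migration speed is the ordinary least-squares slope of distance
travelled versus time, in μm/hr, where distance travelled is the
displacement from the track's first position. Cumulative path length would
conflate the ~2 μm oscillation with the ~23 μm/hr net advance; displacement
lets the oscillatory component average out of the slope.

**Medial velocity and period.** The signed medial position
m(t) = −sign(x₀ − midline)·(x(t) − midline) increases toward the midline for
either row, making left and right tracks directly comparable (mirror
symmetry is exact). The oscillation period is the lag of the first peak of
the autocorrelation of the finite-difference medial velocity, using the
biased estimator (normalisation by series length, which guarantees decay
with lag), searched from lag 2 up to half the series length, and refined by
3-point parabolic interpolation. A qualifying peak must be a local maximum
with value above a 3/√n noise band: without the significance band, almost
every white-noise trace would produce some positive local maximum and a
spurious period. Tracks with no qualifying peak get a missing period (never
zero), and are excluded from the embryo period mean only. The period is
computed on medial velocity, not 2-D speed: the oscillation is a medial
back-and-forth, and the AP component is mostly noise.

**Step decomposition.** The medial position is smoothed by a centred moving
average (3 frames = 45 s by default). All alternating turning points of the
smoothed trace are located, each turning index is refined to the raw
extremum within the half-smoothing window (the moving average flattens sharp
step vertices, so the smoothed turning point can sit a sample off the true
one), and excursions smaller than 0.3 μm — measured on the raw positions —
are pruned smallest-first, merging the adjacent runs. This is the classic
turning-point filter; refining *before* pruning matters, since an unrefined
index can make a true 0.8 μm excursion look sub-threshold and silently merge
two step cycles. A medial step is a surviving minimum-to-maximum excursion,
a lateral step the reverse; the reported amplitudes are the means of the
excursion magnitudes and the net medial step is their difference, an exact
identity by construction. A monotone track counts as one step with the
opposite amplitude zero. The 3-frame window and 0.3 μm threshold are
package defaults (configurable); they are small enough to resolve the
~1.7 min, ~1–2 μm steps at 15 s sampling and large enough to reject
0.2 μm-scale centroid noise.

## Group comparison

Embryo means are compared between females and males with a two-sided
Mann-Whitney U test. When both groups have ≤ 10 embryos and the pooled data
are tie-free, the exact null distribution of U is computed by the standard
count recurrence and the two-sided p is twice the smaller tail (capped at
1). Ties or larger groups switch (with a log line) to the normal
approximation with tie correction and a 0.5 continuity correction. Group
summaries report the mean, sample s.d. (n−1) and s.e.m. = s.d./√n. No
multiple-testing correction is applied across metrics, matching per-metric
reporting conventions. Embryos without a female/male label are excluded
from comparisons with a log line; missing metrics are excluded per metric.

## Synthetic data

The generators produce inputs with known ground truth at the study's
conditions; all are pure functions of their parameter object including the
seed.

* **Lumen series** — `plateau_frames` frames of a wide outline (ML extent
  85 μm, above the 80 μm threshold) at area A0, then an elliptical polygon
  (fixed aspect ratio 2) whose noiseless area follows A0·e^(−kt) from the
  last plateau frame. Semiaxes are scaled so the inscribed polygon's area —
  not the continuous ellipse's — hits the target exactly, so noiseless
  recovery of k is exact to optimizer tolerance. Area noise is
  multiplicative (5% default); vertex noise is additive Gaussian. The ML
  extent drops below the threshold at the first decay frame by
  construction, so registration lands exactly on the last plateau frame;
  real lumens shrink through the threshold continuously, which this
  simplification does not emulate (it only relocates t0, not the decay
  shape).
* **Tracks** — two rows at x = ±37.5 μm (75 μm initial separation, crossing
  the 65 μm registration threshold early in the movie), 52 nuclei per row
  spaced 5 μm along AP. `drift_sinusoid` mode: medial displacement
  v·t + B·sin(2πt/T + φ) with per-nucleus random phase — realistic speeds
  with a superimposed oscillation. `ratchet` mode: piecewise-linear advance
  of `medial_step` then retreat of `lateral_step` per cycle — exactly
  controllable step amplitudes. The ratchet cycle is snapped to the
  sampling grid (cycle length = round(period/Δt) samples, the longer
  half-phase assigned to the larger step) so that sampled extrema attain
  the programmed amplitudes; without snapping, vertices of a 1.7 min cycle
  fall between 15 s samples and exact recovery is impossible. The two modes
  are deliberately not unified: sinusoidal tracks have net step = drift ×
  period, while ratchet tracks have speed = net step / period, so no single
  waveform matches both the reported speeds and the reported step
  amplitudes at the reported period. Defaults (speed 23.0 μm/hr, period
  1.7 min, steps 1.9/0.8 μm, noise 0.2 μm) are the study's female-group
  values; male defaults are 22.4, 1.4, 2.0/0.7.
* **Cohorts** — 7 female + 8 male lumen embryos and 6 + 6 track embryos,
  with per-embryo parameters drawn from the group means using the reported
  between-embryo s.d. values, truncated to stay physical (k > 0.1 hr⁻¹,
  speed > 2 μm/hr, period > 0.5 min, steps > 0.35 μm). The ground-truth
  table records every draw.
* **Rendering** — Gaussian spots at nucleus positions (or densely sampled
  outline points) on a zero background; no camera-noise model, since the
  kymograph checks are geometric, not photometric. Kymographs project a
  fixed rectangle of each frame by maximum intensity across the short
  dimension and stack the profiles over time.

What passing these tests shows — and does not. The generators emulate the
statistical structure of the measurements (exponential area decay, drift
plus oscillation, step ratchets, between-embryo spread) but not
segmentation errors, track identity switches, AP-directed motion, nuclear
shape change, or uneven illumination. Recovery on synthetic data therefore
validates the estimators' correctness and calibration, not robustness to
upstream annotation failure modes.

## Numerical choices and scale

* The type-I calibration of the group comparison runs 1000 replicate null
  cohorts at the per-embryo summary level (both groups of 6 drawn from one
  common distribution), which is distributionally identical to running the
  full image-scale pipeline under the null and keeps the check fast; the
  full generate-quantify-compare chain is exercised end-to-end separately.
  The observed rejection rate ≈ 0.04 reflects the exact test's conservatism
  at n = 6 + 6 (the achievable two-sided level below 0.05 is 38/924).
* Recovery suites use 20 lumen series (250 frames each), 50 speed tracks
  (60 min), 50 period traces (40 min) and a 20-cycle ratchet — sizes chosen
  so each suite completes in seconds while the Monte-Carlo error stays an
  order of magnitude below the acceptance tolerance.
* Degenerate inputs raise typed errors: polygons with < 3 vertices,
  self-intersections or zero area; tracks with < 2 samples or non-monotone
  frames; < 3 points for any line fit; < 8 samples for period or step
  analysis. Registration fallbacks (no threshold crossing) warn and use the
  first frame rather than failing, since a movie that starts after closure
  onset is still analyzable.

## Known limitations

* The lumen-extent proxy for cable distance, and free-A fitting, are
  interpretive choices; both are configurable only by editing the code, not
  the config file.
* Step-decomposition parameters (window, threshold) are package defaults,
  not published values; different choices change the absolute amplitudes on
  noisy data by up to ~0.1 μm.
* Pairing assumes rows with preserved order; it will mis-pair if tracks
  cross in AP, which real cardioblasts rarely do but the package does not
  detect.
* The exact Mann-Whitney branch requires tie-free data; measured metrics
  are continuous so ties only arise from duplicated inputs.
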