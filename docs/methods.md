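# Methods

## Scope and model

`jc1screen` quantifies mitochondrial membrane potential in whole *Daphnia
magna* juveniles from multiwell-plate confocal screens stained with the
cationic dye JC-1. In polarized mitochondria JC-1 concentrates and forms
red-emitting J-aggregates (imaged in the Cy3 channel); at low membrane
potential it stays a green monomer (FITC channel). The red/green intensity
ratio over the whole organism therefore indexes mitochondrial health, and
its decline with toxicant concentration is summarized by effect
concentrations (EC10, EC50) from constrained log-logistic models.

The pipeline has four stages:

1. **Segmentation.** Each well holds one organism on a brighter, roughly
   uniform transmitted-light background. Per z-level, the TL image is
   Gaussian-smoothed (default sigma 2 px), the background level is the
   median of an 8-px border band, and pixels whose absolute deviation from
   background exceeds an Otsu threshold on |TL − background| become the
   mask, followed by morphological closing (disk radius 2), hole filling
   and removal of components below 500 px (8-connectivity). The component
   count is reported before any repair: a count ≠ 1 invalidates the layer,
   it is never rescued by largest-component selection, because a count of 0
   means the outline was not found and a count > 1 means an extra animal or
   an artifact was labelled.
2. **Quantification.** Cy3 and FITC means are taken over the mask. Pixels
   with Cy3 ≥ 65000 (counts on the 16-bit scale) are excluded from *both*
   channels, keeping the ratio's pixel set paired; the layer ratio is
   mean(Cy3)/mean(FITC). Per individual, the ratio is the arithmetic mean
   over correct z-levels; the individual is excluded when more than 50% of
   its z-levels are incorrect (a layer with 0 or >1 segments, no usable
   pixels, or a non-positive FITC mean counts as incorrect).
3. **Normalization and floor.** Ratios are divided by the medium-control
   mean of the same experiment and timepoint, so the control group's mean
   normalized ratio is exactly 1. The lower asymptote of the JC-1 model is
   the mean normalized ratio of dead-control individuals; when a plate has
   no dead-control wells the floor must be supplied in the configuration.
4. **Dose-response.** Both families share
   f(x) = c + (d − c)/(1 + exp(b(ln x − ln e))).
   Immobilized fractions are fitted with LL2 (c = 0, d = 1 fixed) by
   binomial maximum likelihood on the counts — responses are counts of
   5–20 animals, and the likelihood handles 0/1 plateaus gracefully; a
   least-squares mode exists for sensitivity checks. Normalized JC-1
   replicate means are fitted with LL4, the lower limit frozen at the
   dead-control floor, by least squares. ECp uses the relative definition,
   EC_p = e·(p/(100 − p))^(1/|b|), the concentration moving the response
   p% of the (d − c) span toward the high-concentration asymptote; EC50
   equals the inflection e identically.

## Numerical choices

* Optimization is over (b, ln e) (and d for LL4) with ln e bounded to the
  design range ±3 log-units and |b| ≤ 50; starts are e₀ = the
  concentration whose response is nearest the midpoint, b₀ = ±1 by
  response direction, d₀ = max response, with two perturbed restarts when
  the first start fails.
* LL2 covariance is the inverse observed information (central finite
  differences); LL4 covariance is residual variance times the inverse
  Gauss-Newton curvature; both are transformed from the ln e scale to the
  e scale.
* **Convergence diagnostics.** Quantal designs with a wide gap in the
  concentration series often show partial response at only one
  concentration. The binomial likelihood is then monotone in |b|: the
  "estimate" sits on the slope boundary and e is pinned just above the
  nearest design concentration instead of being estimated. After each fit
  the slope is steepened by 50% and the remaining parameters re-optimized;
  if the objective does not worsen, the fit is flagged `converged = False`
  ("slope unbounded"). The same check guards LL4 fits whose transition
  falls entirely between two adjacent concentrations. Recovery summaries
  (tests and `scripts/acceptance.py`) take medians over converged fits and
  report the converged count — the standard convention in fit-recovery
  simulation studies. This degeneracy is not hypothetical: real screens
  with a missing decade of concentrations produce exactly these fits, and
  the huge CIs they imply.
* Confidence intervals default to the delta method on the original
  concentration scale. This reproduces a known behavior of published
  EC tables: for poorly determined fits (shallow slope, sparse design) the
  95% lower bound can be negative. `delta_log` (log-scale delta, always
  positive) and `bootstrap` (parametric draws from the free-parameter
  covariance) are available via `ci_method`.
* The medium-vs-solvent control comparison applies Shapiro–Wilk to each
  group and uses Welch's t when both pass at α = 0.05, otherwise the
  Wilcoxon rank-sum. No multiplicity correction is applied anywhere;
  endpoints are compared by 95% CI overlap, reported as a flag in the fit
  table.

## Synthetic plates

Because raw screening images from proprietary instruments are not
redistributable, validation runs on generated plates with known ground
truth at two levels.

**Tabular simulation** draws replicate-mean JC-1 ratios from an LL4 curve
plus Gaussian noise (sd `noise_sd/√n_individuals`) and immobilization
counts from Binomial(n, LL2(x)). Defaults mirror the screening design:
seven CCCP concentrations (0.5–2500 μg/L), five individuals per well
group, three independent experiments, noise sd 0.05 on the normalized
scale, JC-1 truth (b = 2, c = 0.2, d = 1, e = 100) and immobilization
truth (b = −4, e = 500).

**Image phantoms** render 16-bit TL/Cy3/FITC z-stacks (default 10 levels,
256×256 px): a two-ellipse body+head silhouette darker than the TL
background (contrast 12000 on a 30000 background); diffuse FITC monomer
signal on the silhouette (8000 over a 300 background); and a dense
J-aggregate texture in Cy3 built by normalized convolution of ~2 point
deposits per organism pixel (σ 1.5 px), scaled so the in-mask
mean-Cy3/mean-FITC equals the LL4 truth at the well's dose before noise.
The normalized convolution keeps the texture stationary up to the
silhouette border so that excluding a saturated patch leaves the measured
ratio within ~2%; this encodes the biology coarsely — at 4× magnification
individual aggregates are sub-resolution and the staining is even across
the body — rather than resolving mitochondria. Per z-level the texture is
resampled and both channels are attenuated (up to 40%) toward the body
center, mimicking the translucency loss deeper in the organism. Noise is
Poisson shot noise (0.05 photons per intensity unit) plus Gaussian read
noise (sd 120). Artifacts are injected per configured probabilities:
saturated Cy3 patches (65535, ~30% of the footprint), bright
extra-organismal dye aggregates with a sub-threshold TL shadow, empty
wells, and double-occupancy wells (second silhouette kept disjoint).
Dead-control wells are rendered at the floor ratio c; a healthy control
renders at a raw red/green ratio of 2.0.

What the phantoms do **not** emulate: optical sectioning/PSF, anatomical
detail (antennae, gut, eye), spatial dose gradients, well-edge vignetting,
or instrument-specific fixed-pattern noise. Passing the end-to-end tests
therefore demonstrates that the measurement and modelling chain is
self-consistent and recovers known truth under a realistic noise budget —
not that the segmentation would survive arbitrary real-world image
pathology.

## Problem sizes in the test suite

The end-to-end recovery test uses 3 experiments × 8 concentrations × 5
individuals × 10 z-levels at 256×256 px, and recovery/coverage
simulations use 200–500 replicate fits; these sizes give stable medians
and coverage estimates while keeping the default suite fast.

## Known limitations

* Whether the per-individual average should span all z-levels or only
  correct ones (when ≤50% are incorrect) is ambiguous in the underlying
  protocol; the average over correct layers is used.
* The dead-control floor is an input with a documented estimator, not a
  reproduced constant; real screens must either include dead-control
  wells or configure `jc1_floor`.
* Segmentation equivalence with the original vendor tool cannot be
  verified (its algorithm is unpublished); the phantoms establish
  functional adequacy only.
* Immobilization fits pool experiments rather than fitting per experiment.
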