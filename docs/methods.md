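# Methods

`nirscart` reimplements an analysis pipeline for arthroscopic near-infrared
(NIR) diffuse-reflectance spectroscopy of articular cartilage: from raw
two-detector spectra to location-level predictions of five tissue
properties — cartilage thickness (mm), full-thickness and superficial
(first 25% of depth) proteoglycan (PG) content expressed as safranin-O
optical density (OD), and full-thickness and superficial collagen
orientation angle (degrees, 0° parallel to the surface). The original
equine dataset is not publicly deposited, so the package ships a synthetic
cohort generator that reproduces the study design; all quantitative claims
made by the test suite are claims about recovery of the generator's known
ground truth, not about equine cartilage.

## Synthetic cohort

The generator emulates the study design: 7 experimental ponies (chondral
lesions surgically created and repaired) and 3 healthy controls, two legs
per pony, three measurement lines (proximal/central/distal) with four
locations at increasing distance from the lesion; 3 in-vitro repeat spectra
and 15 in-vivo repeat spectra per location; 3.1% of in-vivo repeats are
artifact spectra (the in-vivo outlier rate the study reported). Unlike the
real study, in-vivo spectra are generated for control animals too, so
test-set pooling covers every fold.

Each location carries a latent state: thickness (truncated normal, mean
0.8 mm, sd 0.28, bounds 0.2–1.4 mm, mimicking the reported thickness
range), a PG amplitude (truncated normal, mean 0.95, sd 0.35, bounds
0.15–1.7), a degeneration factor, and a collagen-transition steepness.
Degeneration decreases linearly with distance-from-lesion rank
(0.6 × (4 − location)/3 plus ±0.08 jitter, clipped to [0, 1]) for
experimental animals and is identically zero for controls; this builds in
the reported pattern of significant PG differences only at locations
closest to lesions.

Latents map to 500-point depth profiles in closed form:

* PG: a smoothstep rise from 0.35 at the articular surface to 1 at depth,
  scaled by the PG amplitude, and depleted by degeneration through a
  uniform full-thickness loss (0.25 × degeneration) plus a surface-weighted
  loss (0.45 × degeneration × exp(−d/0.35)). Superficial depletion dominates,
  as in early degeneration, but a full-thickness component is included
  because the study observed full-thickness PG contrasts.
* Collagen angle: a logistic transition from near 0° (surface-parallel) to
  near 90°, whose midpoint and width are controlled by a single steepness
  parameter; degeneration lowers the deep-zone plateau by up to 8°. The
  parameterization guarantees the first profile point is below 10° and the
  last above 80° for every admissible latent state.

The five regression targets are the grid means of these profiles (full
thickness and first 125 points), so the generator's recorded truth agrees
with the reference-extraction module to 1e-6 by construction, and the
sampled profiles agree with adaptive quadrature of the closed-form curves
to the same tolerance.

Spectra come from a deliberately simple forward model: a power-law
scattering baseline (amplitude 1.0 with 12% per-location log-normal jitter,
exponent 1.3) minus six Gaussian absorption bands at 0.92–1.73 µm (placed
in the water/CH overtone windows so the cropped analysis region stays
informative), each band's depth affine in (1, pg_full, pg_sup,
angle_full/90, angle_sup/90, thickness). The affine link matrix is chosen
so every target is identifiable; it makes no claim about real tissue
optics — it is the simplest construction under which the spectra carry
recoverable information about all five targets. Superficial collagen angle
is included as a separate driver (not only a mean angle) because it is
itself a regression target. Repeats add white noise (sd 0.01 in intensity
units in vitro, inflated 2.5-fold in vivo for the noisier surgical-theatre
acquisition) and a multiplicative gain (sd 0.015, representing
fibre-coupling variation, identical for the two modalities). The baseline
jitter is deliberately the largest nuisance: in diffuse reflectance,
coupling and scattering variability dominate over absorption contrasts, so
the leading principal component of the preprocessed spectra is
scattering/coupling scale rather than composition. That structure matters
for the radius sweep: a clean in-vivo repeat's ellipsoid radius is then
driven mostly by prediction-neutral nuisance, so shrinking the ellipsoid
radii discards good spectra and degrades the location averages rather than
filtering bad ones — the behaviour the 105% operating point is chosen
against.

Artifact repeats model loss of probe–tissue contact during arthroscopy: a
strong Gaussian leak from the arthroscopic light source in the visible
region (centre 0.55 µm, amplitude 12, i.e. several times tissue
reflectance), a contact-loss multiplier drawn from U(0.25, 0.65) applied to
the NIR region (≥ 0.75 µm), and a baseline tilt of up to ±0.2 per µm.
Ground-truth artifact flags are recorded so detector sensitivity and
specificity are measurable — the real study had no such truth. The visible
leak itself is cropped away during preprocessing; what makes artifacts
detectable downstream is the contact-loss scaling and tilt of the
derivative spectrum, which is the physically relevant signature.

What the generator does *not* model: radiative transfer or photon
migration, subchondral bone reflectance, wavelength-dependent penetration
depth, instrument drift, and any nonlinear relation between composition and
absorbance. Passing recovery tests therefore demonstrates that the pipeline
is implemented correctly and can recover parameters under the study design
and realistic noise — not that NIR spectra of real cartilage support these
correlations.

## Preprocessing

Each detector segment is filtered separately with a 3rd-degree
Savitzky-Golay first-derivative filter: 139 points (≈ 0.08 µm) on detector
A (0.35–1.1 µm, 0.6 nm steps) and 41 points (≈ 0.26 µm) on detector B
(1.0–2.5 µm, 6.4 nm steps). Derivatives are scaled by each segment's
wavelength spacing so both are in d/dλ units. The derivative is computed in
a single filter pass rather than smooth-then-difference.

Edge handling: output is restricted to positions with a full centred window
— no padded or extrapolated boundary values. The analysis region is cropped
to 0.80–1.90 µm after filtering, with detector A used below 1.0 µm and
detector B above. Because detector B starts at 1.0 µm and its half-window
spans 0.128 µm, the first full-window B position is 1.128 µm; the
concatenated analysis grid therefore has a deliberate uncovered interval
(1.0–1.128 µm, 455 points in total) instead of fabricated edge values. The
handover wavelength is configurable.

## Outlier rejection

In-vitro spectra are always acquired with verified probe contact, so their
first three principal-component scores define the plausible-measurement
region. PCA is fitted once on all preprocessed in-vitro spectra pooled
across animals (mean-centred, three components, each loading's
largest-magnitude element made positive for reproducibility). In-vivo
spectra are projected into that space and classified against the minimum
volume enclosing ellipsoid (MVEE) of the in-vitro scores.

The MVEE is computed with Khachiyan's first-order algorithm (relative
tolerance 1e-6, iteration cap 10⁴) on the lifted point set; after
convergence the shape matrix is rescaled so the farthest fitting point lies
exactly on the unit boundary, guaranteeing enclosure at radius 1 at the
cost of at most a (1+tol) factor in volume. Affinely dependent score sets
raise a degenerate-geometry error with advice to add jitter. Classification
scales the fitted radii uniformly; the pipeline operating point is 105%,
and a radius sweep (default 75–150%) reports outlier counts and test-set
performance per radius. Locations whose in-vivo repeats are all flagged are
recorded as missing and excluded from metrics, with a logged warning.

## Reference properties

Depth profiles measured on histological sections are linearly resampled to
500 points spanning the cartilage depth, averaged within a location, and
summarized as full-thickness and superficial means. "First 25%" is read as
the first ceil(0.25 × 500) = 125 grid points; the alternative reading (124
points) differs below reporting precision. Thickness is taken from the
cohort's latent truth (the study measured it with optical coherence
tomography, which is out of scope here).

## Ensemble regression

Fold plan: for each target, ponies are ranked by their mean target value
(ties broken by pony identifier) and fold k of 5 holds out the ponies of
rank k and k+5 for validation — animal-level splitting, so calibration and
validation never share a pony, and each validation pair spans the value
range. Cohorts with n ≠ 10 ponies generalize with offset ceil(n/2).

Targets are min-max scaled to [0, 1] and spectral features standardized,
with statistics from calibration rows only. Calibration uses every
in-vitro repeat as its own row (3 per location), the study's data
augmentation.

Each fold trains six members: a convolutional network (two valid stride-1
1-D convolutions, kernel 8 with 64 filters then kernel 64 with 16 filters,
ReLU; flatten; dropout 0.75; dense 128, ReLU; linear output) and a dense
network (120 sigmoid, 60 ReLU, dropout 0.2, 15 ReLU, linear output), each
initialized with Glorot-uniform weights from the three fixed seeds 7, 14,
21. Training minimizes mean squared error with Adam, monitors validation
RMSE, restores best-epoch weights at early stop, and halves the learning
rate on plateau. No deep-learning framework is required: the network
engine is a compact numpy/scipy implementation whose convolutions are
evaluated in the frequency domain (real FFT + batched per-frequency matrix
products), verified against direct sliding-window computation in the test
suite. Arithmetic is float32 and fully deterministic under fixed seeds on a
single thread.

Protocol constants that follow the measurement protocol: seeds {7, 14, 21},
early-stop patience 25, learning-rate-reduction patience 20, validation
RMSE as the monitored quantity, six-member mean as the ensemble output.
Constants the protocol leaves open are set to conventional defaults and are
configurable: initial learning rate 1e-3, reduction factor 0.5, minimum
learning rate 1e-5, batch size 32, epoch cap 500, loss MSE, best-weight
restoration on.

Problem sizes: the default end-to-end profile trains 5 targets × 5 folds ×
6 members = 150 networks on 576 calibration rows of 455 features. The
package's default schedule for full runs is an epoch-reduced profile
(epoch cap 10, patience 5/3): on the nearly-linear synthetic forward
model the ensembles are far past the acceptance thresholds within a few
epochs (single-fold validation ρ ≈ 0.99 for thickness and full-thickness
PG), so the long protocol adds runtime, not accuracy, at this problem
scale. The full 500-epoch protocol remains available via `TrainConfig()`.

## Evaluation

Predictions are averaged per location: over the 3 in-vitro repeats for
calibration/validation, over non-outlier repeats for the in-vivo test set.
Calibration metrics are in-sample predictions of each fold's calibration
spectra pooled across folds; validation pools each location exactly once
(the fold holding out its pony), and the same fold predicts the location's
in-vivo spectra for the test set. Metrics per target and set: Spearman's ρ
(mid-ranks), RMSE in target units, and NRMSE = 100 × RMSE / (reference
max − min) using each target's overall reference range — this
normalization reproduces the printed worked-example cells within rounding.

Group contrasts use the two-sided Mann-Whitney U test: exact full
enumeration of group assignments for combined n ≤ 20 (mid-ranks, so ties
are handled; identical groups give p = 1), the tie-corrected normal
approximation otherwise. Measured-vs-predicted contrasts use the Wilcoxon
signed-rank test with zero differences dropped; an all-zero difference
vector is degenerate and reported as p = 1 with a warning.

The radius sweep re-aggregates cached per-repeat test predictions at each
relative radius and reports the across-target average of range-scaled RMSE
and of Spearman's ρ, plus outlier counts. Each metric comes in two
variants: computed on whatever locations retain an inlier repeat at that
radius, and computed on the fixed set of locations surviving at the
tightest swept radius. The second (common-support) variant is the
meaningful comparison across radii — shrinking radii preferentially drop
whole locations at the edge of the calibration range, which are also the
hardest to predict, so the changing-support RMSE is confounded by this
selection (it can even improve as the radius shrinks while the rank
correlation worsens). On common support, aggressive radius reduction (75%)
discards good spectra and degrades the test error relative to the 105%
operating point, with a flat minimum around 100–125%, reproducing the
qualitative behaviour that motivated the slightly-enlarged ellipsoid.

## Design choices where the protocol was open

* "Minimum volume ellipsoid" is read as the minimum volume *enclosing*
  ellipsoid of all in-vitro scores (no robust-subset variant), consistent
  with in-vitro spectra being treated as always valid.
* The 0.80–1.90 µm analysis region is enforced as a single preprocessing
  crop.
* One independent single-output ensemble per reference property.
* NRMSE normalization by the overall reference range; the printed test-set
  thickness cell (17.2%) is not consistent with this normalization
  (0.191/1.22 ≈ 15.7%) and may use a set-specific range — left as a known
  discrepancy rather than guessed.
* Per-location in-vivo aggregation drops outlier repeats; all-outlier
  locations become missing values, excluded from metrics with a warning.

## Known limitations

* The forward model is linear-in-targets; real NIR-composition relations
  are nonlinear and confounded. Recovery correlations here (ρ ≈ 0.9+) are
  accordingly optimistic relative to the ρ ≈ 0.6–0.8 reported on real
  tissue, and are thresholded, not matched.
* The reported real-data outlier count (51 of 1620) depends on the
  undeposited dataset and is not reproducible; the synthetic analogue
  checks sensitivity/specificity against known artifact flags instead.
* With 10 animals the fold plan is fully deterministic; no uncertainty is
  attached to the reported correlations.
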