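# Methods

This note documents the models and procedures implemented in `ocpam`, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Conventions

Volumes are indexed `(z, y, x)`, 0-based; bounding boxes are half-open
index ranges; physical coordinates are `index × spacing` in µm with the
origin at the centre of voxel `(0, 0, 0)`. No stage mutates its input.
Default voxel steps mirror the two acquisition modes being emulated:
2.52 µm for longitudinal organoid imaging and 0.84 µm for spheroid/2D
imaging; the soft-tissue refractive index is 1.38 throughout.

## Synthetic data

The generators provide every input the pipeline consumes, with seeded
randomness (`numpy.random.default_rng`; identical seeds give bit-identical
volumes).

**Organoid time series.** Organoids are ellipsoids placed on a jittered
grid sized so that every organoid stays inside its cell — hence inside the
field of view and non-overlapping — at its final size, with a bounded
random-walk centre drift (default 2 µm/day). Per-day semi-axes follow a
growth-class volume trajectory scaled by the cube root of cumulative
fold-change. The four trajectory classes encode the growth patterns seen
in treated and untreated carboplatin wells imaged every other day from
day 3:

| class | per-interval volume fold-changes (default) | behaviour |
| --- | --- | --- |
| RAPID | 10, 5, 4, 2, 1.8, 1.6, 1.5, 1.4, 1.3 | ten-fold in the first interval, ~200× by the fourth time point, > 3 decades at the end |
| MEDIUM | 3, 2.5, 2, 1.8, 1.6, 1.3, 1.15, 1.1, 1.05 | approaches but stays below two decades |
| WEAK | 1.6, 1.4, 1.2, 1.1, 1.05, 1.02, 1, 1, 1 | well under one decade (safely inside the WEAK class band, away from the one-decade boundary) |
| DTP | 3.5, 3, 1.05, 1.08, 1.05, 6, 5, 4, 3 | ~10× over two intervals, a three-interval plateau, then regrowth past 3 decades |

Each fold is jittered log-normally (σ = 0.02). Voxelised organoid volumes
match the analytic ellipsoid volume within 5% once semi-axes reach ~10
voxels; tests that quantify volume ratios use organoids at that scale.

**Speckle.** Interiors carry multiplicative Rayleigh-distributed texture
(standard fully developed OCT speckle statistics) smoothed to a
class-dependent correlation length and normalised to unit mean. The two
viability regimes are HIGH: mean backscatter 0.55, correlation length 1.2
voxels; LOW: 0.30 and 0.4 voxels — dimmer, finer-grained speckle. These
regimes are plausible stand-ins chosen so that texture separability is
carried by many features at once (level statistics, run lengths, local
correlation), not hard-coded into any single feature; no texture
statistics of real live/dead organoids were available to fit. Classifier
results on this data are therefore parameter-recovery checks, not
reproductions of classification accuracy on real specimens.

**Fluorescence pairs.** Inside each organoid, voxels are live with the
Bernoulli probability of the organoid's class (defaults 0.9 HIGH / 0.15
LOW) and rendered bright (~180 over a ~12 background) in the live channel,
dead voxels in the dead channel; the channels are disjoint per voxel. Real
live/dead microscopy is a separate instrument co-registered to OCM; here
both share the ground-truth geometry, so cross-instrument registration is
deliberately out of scope.

**Spheroids for PAM.** Cell centres are placed by random sequential
adsorption with a minimum separation of one cell diameter inside a sphere
sized from the cell count and a packing fraction (default 0.25). The
melanin-positive subset is the first `round(f·n)` entries of a seed-fixed
permutation, so positive sets are nested across mixing fractions at a
fixed seed — detected counts are then monotone in the fraction by
construction. PAM renders a Gaussian blob per positive cell (σ = half the
cell radius) with a log-normal per-cell melanin load; fraction 0 yields a
pure noise floor. OCM renders the whole spheroid with speckle.

**Phantom.** The same gold-coated pyramid surface is rendered on both
grids; the PAM grid's physical coordinates are `scale · index · spacing +
offset`, which is exactly the transform the calibration must recover.

**Interferograms.** Fringes are `S(λ)·(b + Σ r·cos(2 k z n_medium + φ(k)))`
with a Gaussian source envelope (defaults 845 nm centre, 131 nm FWHM), a
wavelength axis uniform in λ (hence nonlinear in k, so resampling is
exercised) and an optional residual-dispersion phase polynomial starting
at the quadratic term. Depths beyond the Nyquist range are rejected.

## Reconstruction

Per A-line: background subtraction; cubic-spline resampling onto a uniform
wavenumber grid; analytic signal via the Hilbert transform; multiplication
by `exp(-iφ(k))` to cancel residual dispersion; inverse Fourier transform;
magnitude over positive depths. The depth pixel is `π/(Δk·n_medium)`.
Reconstructed peak depth is linear in true reflector depth (fit slope
1.00 ± 0.02 across the unambiguous range) and energy is conserved between
the spectral and depth domains. En-face projections collapse depth by STD
(sample), MAX or MEAN; log compression maps to `20·log10(x/x_max)` clipped
at a display floor (default −40 dB).

## Segmentation

Workflows of this kind typically segment with a trained deep network,
which cannot be shipped in a reusable library without weights and training
data; segmentation is therefore a pluggable backend behind a fixed `LabelMask` contract, so
every downstream stage (tracking, growth, radiomics) is backend-agnostic.
The `external-mask` backend validates and relabels any user-supplied mask;
the default `classical` backend is:

1. **Preprocess** — percentile clip and affine stretch to [0, 1], then
   3×3×3 median denoising. Clip percentiles default to (1, 99.9): organoids
   can occupy well under 1% of the voxels on early imaging days, and a 99th-
   percentile ceiling then saturates organoid voxels and the top percentile
   of background at the same value, destroying the contrast before any
   threshold sees it. The 99.9th-percentile stretch keeps the bright tail
   usable across foreground fractions from ~0.1% to several percent
   (measured precision 1.0, recall 0.73–0.96 over that range).
2. **Threshold** — global Otsu (or a fixed value).
3. **Morphology** — 26-connected closing and hole filling.
4. **Split** — marker-based watershed on the Euclidean distance transform.
   Markers are distance-transform maxima *cores* (regions above 60% of the
   component's peak distance, after light smoothing); cores closer than
   the marker separation (default 20 µm) are merged, keeping the deepest.
   Near-spherical single organoids therefore never over-split, while
   moderately fused pairs separate.
5. **Filter** — components below `min_volume` (default 250 µm³) removed;
   labels renumbered in decreasing size order.

Segmentation is deterministic given volume and parameters. On the
synthetic longitudinal suite (20 organoids, 5 days) mean Dice against
ground truth is ≈ 0.89 on every day past the first. Whether to segment in
2D slices or natively in 3D was open; this implementation is natively 3D.

## Tracking

Identity is established from the median imaging day (the earlier of the
two central days for even-length series) and a dual-branch, day-by-day
chain: adjacent days are matched by a one-to-one assignment (Hungarian
algorithm, deterministic, ties resolved toward smaller labels) on a
combined score

`s = w_d·exp(−d²/2σ_d²) + w_v·min(V)/max(V) + w_b·IoU(bbox)`

with defaults `w = (0.5, 0.3, 0.2)`, `σ_d = 30 µm`, acceptance threshold
`τ = 0.4` — the attribute classes (spatial + morphological) were given,
the functional form was not, so all of it is config-exposed. Chains that
never touch the reference day become additional tracks; tracks absent on
the first/last series day carry `APPEARED`/`LOST` flags. Merges are
flagged when ≥ 2 prior-day labels each overlap ≥ 50% of their own voxels
with one current-day label; the largest participant's track survives. On
well-separated series (≤ 5 µm/day drift, ≥ 50 µm separation) identity
accuracy is 100%.

## Growth

Relative volume is normalised to the **first observed day** (day 3 in the
default every-other-day series — a pre-culture reference volume does not
exist, and normalisation to any single day leaves the analysis invariant
up to a constant). Gaps are never interpolated. Classification: DTP requires a plateau of ≥ 2 consecutive
intervals with fold-change ≤ 1.25, occurring after at least one growth
interval, followed by a cumulative post-plateau fold-change ≥ 10;
otherwise the final relative volume sets the class at one and two decades.
These thresholds match the qualitative behaviours the trajectories encode
(ten-fold early growth that stalls mid-series, regrowth past three decades)
and are config-exposed. Every profile receives exactly one
class, deterministically; generator classes are recovered at 100% when
trajectory folds sit ≥ 2× from the thresholds. Well summaries report the
per-day mean curve, class counts, and the DTP percentage to 3 significant
figures.

## Fluorescence viability

Channels are binarised by contrast-limited adaptive histogram equalisation
followed by a global Otsu threshold. The CLAHE clip limit defaults to
0.005: at 0.01 the permitted amplification of signal-free tiles pushes
equalised background across the global Otsu threshold and background is
marked positive wholesale; 0.005 bounds the amplification while keeping
blob recall at 100% (tile size defaults to 1/8 of each image extent).
The viability score is live/(live+dead) pixels within the organoid region;
voxels positive in both channels count once as dead (dead-stain
dominance, config-exposed); a region with no stained pixel at all is
flagged UNSCORABLE rather than scored. Status: HIGH iff score strictly
above the 50% cut-off — a score of exactly 0.5 is LOW, a documented choice
where the boundary was left open. Scoring uses full 3D stacks by default.

## Radiomics

Exactly 32 features per organoid ROI, computed on the original
(non-preprocessed) OCM intensities: 9 first-order, 13 GLCM, 10 GLRLM, in a
fixed order, with formulas following the pyradiomics documentation
definitions (kurtosis is the un-excess `m₄/m₂²`; entropies are base-2;
a constant ROI yields zero skewness/kurtosis and entropies, uniformity 1,
correlation 1 by the degenerate-variance convention).

Discretisation is equal-width binning over the ROI's own min–max range
into 32 levels — chosen for invariance under positive affine intensity
maps of the ROI; all level-based features (the GLCM/GLRLM blocks, Entropy,
Uniformity) inherit that invariance. GLCM uses symmetric co-occurrence at
distance 1 over the 13 unique 3D directions, feature-averaged over
directions; GLRLM counts maximal same-level runs along the same 13
directions, with runs broken at the ROI boundary (implemented as a
vectorised lockstep chain walk; the tests check it against an exhaustive
per-voxel enumeration to 1e-8). Full-3D computation is the default; a
2D-per-slice mode (4 in-plane directions) is available behind config.
ROIs under 27 voxels are rejected. The chosen 9/13/10 feature sets contain the nine headline descriptors the
pipeline's importance analysis targets (Sum Entropy, Run Percentage, Joint
Entropy, Difference Entropy, Run Length Non-Uniformity Normalized,
Autocorrelation, Joint Average, Gray Level Variance, Run Entropy) plus
standard companions, and are config-overridable.

## Classification

A gradient-boosted tree ensemble (XGBoost; 300 trees, depth 4, learning
rate 0.1 — conventional defaults, all config-exposed) under stratified
10-fold cross-validation, reporting per-fold ROC curves and the mean AUC.
`tree_method="exact"` is used: on the small feature tables involved,
histogram binning places split thresholds on training-data bin edges, so
validation samples inside a wide class margin can fall on the wrong side;
exact midpoint splits do not have that artefact and cost nothing at this
scale. Trees are scale-invariant, so no feature scaling is applied;
missing features are rejected, not imputed. Stratification is by label by
default, with an optional group-by-well mode to avoid leakage across
organoids sharing a well. The learning curve subsamples
stratified fractions 10%…100% in steps of 10%. Importances are
normalised gain. Track scoring assigns HIGH per day iff the positive-class
probability strictly exceeds 0.5, consistent with the viability cut-off;
overall viability is the fraction of observed days HIGH.

On the synthetic texture regimes (n = 200) the classifier reaches mean AUC
≈ 1.0 and permutation-null AUC 0.5 ± 0.1 — parameter recovery on the
generator's own conditions, not a reproduction of results on real data.

## Fusion and rare-cell detection

Calibration is an axis-aligned affine (per-axis offset and scale, no
rotation or shear — exactly the degrees of freedom a scan-geometry
mismatch between the two beams produces). The phantom's top surface is
extracted per lateral position as the intensity-weighted depth centroid of
the above-half-peak samples (lines below half the global peak are
invalid). Lateral scale is the square root of the ratio of
surface-weighted second moments, the offset aligns weighted centroids —
weights are heights above the flat plain (median base) with a 10% floor,
without which plain noise biases the moments because the plain's physical
extent differs between the grids under the unknown scale. Axial
scale/offset come from a least-squares fit of paired surface heights over
the common lateral support; the residual is the RMS height disagreement.
Median recovery error over random transforms is well under 1 voxel and 1%
scale. Flat surfaces make the scale unidentifiable and are rejected.

Absorber detection thresholds each depth line at 87% of its own peak
(per-line is the default scope — it matches how depth profiles are read
out and avoids shadowing bias; a global scope is also implemented). The threshold applies to linear amplitude: on a log
scale 87% of peak would admit nearly everything. Lines whose peak stays
below the noise floor (background mean + 5 SD, background defaulting to a
2-voxel border shell) are skipped; kept voxels form 26-connected
components, and components of ≥ 5 voxels (an optically resolvable absorber
spans several voxels) yield intensity-weighted centroids. Raising the
threshold never increases the count for resolvable, separated absorbers;
with closely packed absorbers, per-line relative thresholding can bridge
neighbouring blobs at low fractions, so raw counts are not globally
monotone — the detector is intended for the rare-cell regime. Overlays
render OCM as a grey STD projection and PAM as a warm-colormap MAX
projection, both log-compressed, alpha-composited where PAM carries
signal.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
scenes sized for a desk machine: fields of a few hundred µm (≤ ~10⁷
voxels), 15–24 organoids per tracking scene, 200 organoids for the
classifier, 400–600 cells per spheroid, 20 random calibration draws,
2048-sample interferograms. These sizes were chosen so the full suite
completes in minutes while every quantitative check retains its margin;
all of them are function arguments, and nothing in the implementation
depends on scale.

## Known limitations

- The classical segmentation backend stands in for the original trained
  network; it is validated on synthetic speckle scenes, not on real OCM.
  Organoids occupying under ~0.1% of the volume approach the limit of the
  histogram-based threshold.
- Synthetic speckle and growth are phenomenological: no light propagation,
  no acoustic modelling, no shadow artefacts, no refractive distortion.
  Passing tests demonstrate that the algorithms recover the generators'
  ground truth under realistic geometry and noise — not performance on
  real data.
- FLM/OCM co-registration is assumed given (shared geometry in synthetic
  mode; co-registered ROIs for real data).
- No complex-conjugate removal or dynamic-contrast (D-OCT) reconstruction;
  no spectroscopic multi-wavelength unmixing; no lineage analysis
  (division/splitting) in tracking.
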