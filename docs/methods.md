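# Methods

## Problem and pipeline

The package classifies individual cucumber leaves as healthy or
spider-mite infested from snapshot hyperspectral cubes. A cube holds a
reflectance spectrum (113 bands, 502–950 nm, 4 nm step) at every pixel
of a 50 × 50 frame. Classification is leaf-level: each snapshot is
reduced to a single spectrum before any model sees it.

The per-snapshot reduction is: NDVI thresholding (default bands 670 and
798 nm, threshold 0.5, strict `>`), 3 × 3 binary erosion with the image
border treated as background (edge pixels mix leaf and plate spectra and
are discarded), Savitzky–Golay smoothing of every remaining pixel
spectrum (window 7, polynomial order 2, terminal windows handled by
polynomial extrapolation so all bands are kept), arithmetic averaging to
the leaf's mean raw spectral signature (MRSS), and the standard normal
variate transform (subtract the spectrum's mean, divide by its sample
standard deviation, n − 1 divisor) giving the mean normalized spectral
signature (MNSS). SNV removes multiplicative scatter and illumination
scale, which is why the downstream classifiers receive MNSS without any
additional per-feature standardization.

Smoothing is applied per pixel *before* averaging. With ~500–900 ROI
pixels the ordering barely matters numerically (both are linear
operators; they differ only through the nonlinear edge handling), but
smoothing-first matches the usual chemometric habit and is fixed here
for determinism.

## Wavelength selection and evaluation

Three selectors score all 113 bands on the training split only, to avoid
selection leakage into the test set (a `select_on_train=False` flag
reproduces whole-dataset selection):

* **FI** — mean impurity decrease of a 100-tree random forest
  (min_samples_split 5, min_samples_leaf 1, balanced class weights,
  unlimited depth); scores are non-negative and sum to 1.
* **SKB** — one-way ANOVA F per band, top-k. With two classes,
  F = MS_between / MS_within; a band with zero within-class variance and
  distinct class means ranks above every finite score.
* **SP** — the same scores, keeping `floor(p · 113 / 100)` bands
  (minimum 1), so a percentile of 9 gives ten bands and 5 gives five.

Ranking ties always resolve to the lower band index. Selected
wavelengths are attributed to half-open regions: blue [400, 500), green
[500, 600), red [600, 690), red edge [690, 740), NIR [740, 1000]. The
conventional red region runs to 700 nm, but the red edge — the steep
reflectance rise at the visible/NIR border — begins at 690 nm; ending
red at 690 keeps the regions disjoint and leaves exactly 22 red band
centers on this grid.

Evaluation uses a stratified 70:30 split (per class,
round-half-up(0.7 · n) training samples), the pairing plan FI→RF,
SKB→SVM (RBF, C = 10, γ = 1), SP→KNN (k = 5, uniform weights), and
confusion counts with *infested* as the positive class. Accuracy,
precision and recall are percentages; F1 is the harmonic mean of the
percentage precision and recall. Ratios with a zero denominator are
reported as 0 and flagged rather than raised. A small grid-search
helper (stratified five-fold, ties to the first grid point) is provided
for hyperparameter tuning, but the default experiments run the fixed
configurations above. Experiments accept a seed list and report
per-seed and median metrics; five seeds is the default.

## Synthetic scene model

Because no public imagery exists for this task at this geometry, the
generator fabricates scenes with the statistical structure the pipeline
assumes. One scene is a 50 × 50 cube containing a randomly placed,
rotated and notched leaf ellipse (semi-axes 17 × 12 px) on a flat dark
background (reflectance 0.05, NDVI ≈ 0).

**Healthy spectrum.** r(λ) = floor + green Gaussian − absorption trough
+ plateau · logistic((λ − 715)/8), with floor 0.05, green bump 0.05
(center 550 nm, σ 30 nm), trough 0.02 (center 680 nm, σ 12 nm) and NIR
plateau 0.40. This reproduces the canonical leaf curve: green local
maximum, 680 nm chlorophyll trough, monotone red-edge rise over
690–740 nm, bright NIR.

**Leaf-to-leaf variability.** Each leaf re-draws the component
amplitudes (relative sd 0.06), shifts the green-peak and red-edge
centers by N(0, 3 nm) and tilts the NIR plateau by a relative slope
N(0, 0.05). These shape changes survive SNV (pure scale changes do
not), which is what gives the red and red-edge bands their
leaf-specific nuisance variance and keeps them out of the selectors'
top ranks.

**Infestation.** An additive reflectance increase confined to green and
NIR: a Gaussian bump (peak 0.032, center 550 nm, σ 20 nm, tapered to
exactly zero above 640 nm) plus a smooth NIR ramp switching on over
740–780 nm (plateau increase 0.035), both scaled by a severity in
[0, 1]. The 680 nm band is untouched. Symptoms are spatially localized:
disks of severity-growing radius are unioned until they cover roughly
(0.20 + 0.60 · severity) of the leaf, mirroring the hotspot growth seen
on real leaves; pixels inside hotspots carry the infested spectrum, the
rest stay healthy. A leaf is labelled infested when any hotspot exists.

**Severity schedule.** Infested leaves draw severity from
0.6 + 0.4·d/14, d = 1…14, emulating visibly symptomatic leaves whose
damage grows steadily over two weeks. The schedule and the hotspot
coverage were calibrated jointly so that the *class-averaged* MRSS
difference between infested and healthy leaves peaks at ≈ 0.018 at the
6-day severity level and ≈ 0.025 at the 12-day level, with off-peak
green differences down at the 0.002–0.005 floor — the reflectance-delta
envelope reported for this pathosystem. Note the envelope constrains
class averages; individual severe leaves deviate more strongly, which
is what makes few-band classification possible at all.

**Sensor effects.** Each leaf pixel is scaled by an illumination gain
~ N(1, 0.05) — multiplicative, hence proportional to reflectance, which
makes raw per-pixel variance largest in the NIR, and is largely removed
by ROI averaging and SNV — and every value receives N(0, 0.005) band
noise before clipping at zero. Cubes are stored as float32, the same
precision as the ENVI dialect, so the in-memory and disk ingest paths
agree bit-exactly.

**Randomness.** A master seed spawns one `SeedSequence` child per
snapshot; scene geometry, leaf parameters, severity, hotspots, gain and
noise all flow from that child. Datasets are therefore bit-reproducible
and individual snapshots are independent of the total count.

## What the generator does and does not emulate

It emulates the reflectance phenomenology (curve shape, green/NIR
infestation response, hotspot localization, illumination variation,
dark background) and the dataset design (220 + 220 balanced classes,
severity progression). It does **not** model radiative transfer
(PROSPECT-class leaf optics), specular highlights, shadows, multi-leaf
scenes, camera pan-sharpening artifacts, or temporal pseudo-replication
of repeatedly imaged leaves. Passing tests therefore demonstrate that
the pipeline's machinery recovers planted structure under controlled
conditions — not field performance on real greenhouse imagery.

## Numerical conventions

* Nearest-band lookup: exact ties go to the lower index; out-of-range
  targets clamp to the grid ends.
* NDVI at zero denominator is 0; mask thresholding is strict (`>`).
* Erosion treats outside-image pixels as background.
* SNV rejects constant spectra; sample (n − 1) standard deviation.
* Selector ties, grid-search ties and percentile rounding are all
  deterministic (lower index / first grid point / floor with minimum 1).
* Pearson correlations involving a zero-variance band are reported as
  NaN (flagged missing), valid diagonal entries are exactly 1.

## Problem sizes

Default experiments use the full study geometry: 440 snapshots of
50 × 50 × 113 cubes per dataset, five master seeds, one stratified
70:30 split per seed. The whole acceptance recomputation (five
datasets, selection, training, evaluation) completes in well under a
minute on one CPU; unit tests use reduced counts (12–80 snapshots)
where the full size adds nothing.

## Known limitations

* The severity→reflectance mapping is phenomenological; severity units
  are arbitrary and only the resulting reflectance deltas are
  calibrated.
* The SVM's fixed kernel scale (γ = 1) makes its accuracy sensitive to
  the absolute spread of the MNSS features; datasets with much weaker
  leaf-to-leaf variability than the defaults will underfit it while
  leaving RF/KNN unaffected.
* Single-leaf scenes only; segmentation has no notion of touching or
  overlapping leaves.
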