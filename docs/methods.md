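# Methods

## The measurement being modeled

A printed glycan microarray element sits on an NHS-activated OEG-disulfide
self-assembled monolayer on gold. Two imaging modalities characterize it:
positive-ion ToF-SIMS (per-pixel mass spectra, *m/z* 1–350, 500 × 500 µm
field rastered at 128 × 128 pixels ⇒ 3.9 µm/pixel, 16 384 spectra) and SPR
imaging (reflectance stacks in pixel-intensity units, 30-frame averaging).
The package implements the full analysis chain for both, plus a synthetic
generator that makes the chain testable against known truth.

One spatial convention is used everywhere: 0-based row-major pixels with the
origin at the field's top-left; pixel (r, c) covers the half-open square
[c·px, (c+1)·px) × [r·px, (r+1)·px) µm; a pixel belongs to an ROI iff its
*center* lies in the half-open ROI rectangle; the grid dimension is
floor(field/pixel) per axis (500/3.9 → 128).

## Synthetic ground truth

The density map composes three features on the pixel grid:

* **disk** — relative glycan density 1 inside a spot of diameter *d*
  (default 200 µm; printed spots run 150–250 µm);
* **ring** ("coffee stain") — the rim annulus of width 10 % of *d* is
  boosted ×(1 + ring_fraction), default ring_fraction 0.5; the composed map
  is rescaled to max 1, leaving the rim at 1 and the interior at
  1/(1 + ring_fraction);
* **tail** (wash artifact) — an exponentially decaying half-strip of width
  *d* along `tail_vector_um` (default (60, 0) µm, i.e. decay length 60 µm)
  at relative amplitude 0.3.

The instruments never report these magnitudes quantitatively, so ring and
tail defaults are illustrative shapes of realistic scale, chosen once; the
recovery tests are insensitive to their exact values because the artifacts
sit well below the spot's Otsu threshold. The tail is present in the SIMS
density map but excluded from the binding map by default — the wash artifact
is chemically present yet contributes no protein binding in the replicate
binding surface — which makes the SIMS↔SPRi disagreement it causes a
measurable quantity rather than a confound.

## SIMS cube simulator

Counts are independent Poisson draws per pixel and channel with mean

    µ = noise_scale · floor + yield(category) · weight(category, density)

where weight is: density for GDAP; (1 − density) for OEG/SAM and gold
(immobilized glycan masks the monolayer); 1 for hydrocarbon/salt
contaminants; 0 for unassigned noise channels. Default per-channel yields
(counts/pixel at unit weight): GDAP 80, OEG/SAM 40, gold 30, hydrocarbon 10,
salt 15, over the 33-channel reference assignment table; the glycan yield is
set high enough that the spot is brighter than background in the total-ion
image (12·80·d gained vs 530·d masked). The channel axis also carries 300
unassigned channels at the uniform noise floor (0.2 counts/pixel/channel),
emulating the empty bins of a real wide-window spectrum; the peak-picking
background estimate depends on their presence (below). RNG streams are keyed
(seed, modality) so either simulator reproduces bit-exactly when run alone.

## SPRi simulator and kinetics

Per pixel, R(t) = density · R_eq (1 − e^−k_obs·t) during association, with
R_eq = R_max·C/(C + K_D), K_D = k_off/k_on, k_obs = C·k_on + k_off, and
R(t_a)·e^−k_off(t−t_a) after the injection ends at t_a; additive Gaussian
read noise per frame. Defaults: k_on 10⁵ M⁻¹s⁻¹, k_off 10⁻³ s⁻¹ (K_D
10 nM, lectin-like), C 100 nM, R_max 100 intensity units, t_a 720 s, frames
every 2 s for 30 min, noise sd 1 (1 % of the ≈91-unit plateau).

`fit_langmuir` estimates (k_on, k_off, R_max) by trust-region least squares
in log-parameters (enforcing positivity) with analytic Jacobians; the five
deterministic starts scale heuristic rate seeds (63 %-rise time for k_obs,
log-linear dissociation slope for k_off, plateau for R_eq) by 10^{−2…+2}.
For an ROI whose density is below the rim maximum the fitted R_max estimates
density·R_max; rates are unaffected. The model is reaction-limited by
construction: mass-transport limitation, bivalency and regeneration are out
of scope.

## Peak picking and its background

The selection rule is total channel intensity ≥ k× background (k = 3,
inclusive, *m/z* ∈ [1, 350]). "Background" is an explicit per-channel input,
with two estimators provided:

* `background_from_roi` — median per-pixel intensity of a user-named blank
  ROI, rescaled to the summed-spectrum scale. Appropriate for genuine blank
  regions, but for species uniformly present across the surface (OEG/SAM,
  gold) a region median equals the signal itself and would suppress them;
* `noise_floor_background` — the median of per-channel total intensities,
  which on a sparse peak list over a wide window is the counting-noise
  floor. This is what the pipeline uses.

## ROI PCA

Rows are ROI-mean spectra over the picked peaks (hydrocarbon and salt
contaminants removed first). Each row is divided by its total selected-ion
intensity, then columns are mean-centered — normalization before centering,
so the decomposition acts on composition rather than absolute yield. PCA is
a full SVD (deterministic at these sizes, ≤ 15 × few hundred); component
signs are fixed by making each component's largest-magnitude loading
positive, and PC1's sign is then re-oriented so designated background ROIs
score positive. Ion selection at |PC1 loading| ≥ 0.03 is boundary-inclusive.
Region separation uses Welch's unequal-variance t-test on PC1 scores for
the two stated contrasts (spot vs pooled background; background I vs III)
rather than an omnibus test. On synthetic data PC1 captures essentially all
variance; on instrument data the fraction is dataset-specific.

## Ion maps, thresholds, morphology

Category maps sum the channels assigned to one source; hydrocarbon/salt
maps require an explicit flag (contaminant QC only). Display normalization
is min–max; binarization defaults to Otsu's criterion on a 256-bin
histogram (mask = image ≥ threshold) with a fixed-level override — the
instrument workflow's threshold choice is not specified anywhere, and Otsu
is the standard parameter-free default. When the histogram gap between
classes is empty the criterion is flat across it; the first maximizing level
is taken (any choice in the gap yields the same mask). Morphology is
measured on the largest 8-connected component; Dice = 2|A∩B|/(|A|+|B|)
against the planted disk is the recovery score. Composites assign red =
GDAP, green = OEG/SAM, blue = gold.

## Sensorgrams and the ROI sweep

Frames are averaged in consecutive blocks of 30 (final partial block kept)
before ROI statistics; the response is the spatial mean over ROI pixels,
the variability the spatial sd, timestamps the block mean. The readout time
(default 11 min) uses the nearest block time when within 60 s, else linear
interpolation. The sweep uses five concentric squares interpolating the
50–200 µm range (50, 87.5, 125, 162.5, 200 µm); responses are normalized to
the sweep maximum. The sd-vs-area monotonicity property is asserted on
noise-free stacks: the two smallest default ROIs both lie in the uniform
spot interior, so with read noise their *expected* spatial sds tie and the
realized ordering is a coin flip that says nothing about correctness;
noise-free, the ordering is determined by geometry alone.

## Co-registration and agreement

The synthetic pair shares one grid, so the default transform is identity;
an (offset, scale) transform with bilinear resampling (outside samples read
0) covers replicate-surface alignment at known geometry. Automated
cross-instrument registration is out of scope. Agreement is reported as
Dice and Jaccard of the thresholded masks plus pixelwise Pearson r of the
aligned images, together — no single number is privileged, and Dice =
2J/(1 + J) serves as an internal cross-check.

## Fragment masses

`fragment_mz` computes monoisotopic cation m/z as the sum of monoisotopic
element masses (pyteomics NIST data; elements C, H, N, O, S, Na, K, Au)
minus one electron mass (0.00055 Da — invisible at two decimals but kept
for exactness). Computed values reproduce 22 of the 33 tabulated reference
assignments at two decimals; the remainder differ by ≤ 0.02 Da (tabulated
centroids are not all theoretical values), so the calculator always reports
computed values and the assignment step matches channels at a 0.02 Da
tolerance on a 0.01 Da bin grid.

## Problem sizes used in tests

Recovery tests run the full 128 × 128 field with 5 replicate cubes and
333 channels; kinetic recovery uses 100 seeded replicates of 901-point
sensorgrams; the Welch calibration uses 10³ null simulations; PCA is
oracle-checked (covariance eigendecomposition) up to 50 × 200. These sizes
make the whole suite run in well under a minute while keeping every check at
the full acquisition geometry.

## Known limitations

No instrument physics (beam optics, charge compensation, matrix effects,
dead time, mass drift), no negative-ion mode, no multi-spot gridding of
full arrays, no mass-transport-limited or multivalent binding, no
regeneration modeling. The generator's spot interior is uniform apart from
the ring; real spots show additional microheterogeneity, so passing
recovery tests demonstrates correctness of the analysis chain, not that
real surfaces are this clean.
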