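# glycoarray

Chemical and binding-image analysis of printed carbohydrate (glycan)
microarray spots, combining the two surface-analysis modalities used to
characterize them:

* **ToF-SIMS imaging** — a hyperspectral cube of secondary-ion counts
  (one mass spectrum per ~3.9 µm pixel over a 500 × 500 µm field) that
  reports *which chemical species sit where*: glycan–diaminopyridine
  conjugate (GDAP), the NHS-activated oligo(ethylene glycol) self-assembled
  monolayer (OEG/SAM) it is printed on, the gold substrate, and
  hydrocarbon/salt contaminants.
* **SPR imaging** — a time-stamped reflectance stack that reports *where the
  glycan is bioavailable*, via lectin (Con A) binding following 1:1 Langmuir
  kinetics.

Because ToF-SIMS is destructive, the two measurements can never come from
the same physical surface. The package therefore ships a first-class
synthetic-data generator: a shared ground truth (printed spot with
"coffee-stain" ring and wash "tail" artifacts) drives both a Poisson SIMS
cube simulator and a Langmuir SPRi stack simulator, so every stage of the
pipeline is testable against planted truth without any instrument data.

## What the pipeline computes

1. **Ion discovery by ROI PCA** (`sims_cube`, `pca_roi`). Peaks ≥ 3× the
   noise background in *m/z* 1–350 are picked; three 100 × 100 µm ROIs
   (upper-left, center, lower-right) per image over five replicate images
   give a 15-row spectrum matrix; each row is normalized to its total
   selected-ion intensity and the columns mean-centered; PCA by SVD
   decomposes the matrix into scores **T** and loadings **P**
   (X = T Pᵀ, variance fraction σⱼ²/Σσ²). With PC1 oriented so background
   ROIs score positive, ions with PC1 loading ≥ +0.03 are
   substrate/background species and ≤ −0.03 glycan species; Welch's t-test
   quantifies the spot-vs-background score separation.
2. **Fragment mass calculation** (`sims_cube.fragment_mz`). Monoisotopic
   m/z of singly charged fragment cations (monoisotopic mass − mₑ), e.g.
   Au⁺ 196.97, AuC₂H₄⁺ 225.00, C₂H₅O⁺ 45.03 — used to assign picked peaks.
3. **Chemical ion maps** (`ion_maps`). Category-summed ion images,
   min–max normalization, Otsu binarization, red/green/blue composites
   (GDAP/OEG-SAM/gold), and spot morphology (area, equivalent diameter,
   eccentricity, Dice overlap against the planted mask).
4. **Sensorgram ROI analysis** (`spri`). 30-frame-averaged sensorgrams over
   concentric 50–200 µm ROIs, response read near maximal binding (11 min),
   response/variability vs ROI area, and nonlinear least-squares fits of
   R(t) = R_eq (1 − e^−(C·k_on + k_off)t), R_eq = R_max C/(C + K_D),
   with exponential k_off decay after injection ends.
5. **SIMS ↔ SPRi correlation** (`correlate`). Binding contours thresholded
   from the SPRi image, overlaid on the glycan map; Dice/Jaccard overlap and
   pixelwise Pearson r quantify the chemistry–bioactivity agreement.

## Worked example

```bash
python analysis/01_simulate.py --seed 0        # ground truth + both modalities
python analysis/02_pca_ion_discovery.py --seed 0
python analysis/04_spri_roi_sweep.py --seed 0
```

prints (abridged):

```
picked 33 peaks (26 after contaminant removal); PC1 captures 100.0% of variance
spot vs background p = 4.25e-14; background I vs III p = 0.23
selected 12 glycan ions (negative PC1) and 14 substrate ions (positive PC1)

 size_um  area_um2   mean     sd  norm_mean
  50.000  2500.000 60.563  0.193      1.000
  87.500  7656.250 60.572  0.181      1.000
 125.000 15625.000 59.957 15.643      0.990
 162.500 26406.250 43.666 32.927      0.721
 200.000 40000.000 28.486 33.760      0.470
Langmuir fit on center ROI: k_on = 9.76e+04 /M/s (true 1e+05), k_off = 0.001 /s (true 0.001)
```

Reading this: all 33 planted fragment channels are recovered by peak
picking; after dropping hydrocarbon/salt contaminants, PC1 cleanly splits
the 12 glycan ions (negative loadings) from the 14 monolayer/gold ions
(positive loadings), separating the spot ROI from background at
p ≈ 10⁻¹⁴ while the two background ROIs stay statistically alike. In the
ROI sweep over a 150 µm spot, the two ROIs fully inside the spot read the
highest response; ROIs larger than the spot dilute the mean with non-glycan
background (−53 % at 200 µm) while the spatial standard deviation grows
sharply — exactly why ROI choice matters when quantifying array spots.
The kinetic fit recovers the simulated rate constants to a few percent
under 1 % read noise.

`analysis/03_ion_maps.py` and `analysis/05_correlate.py` produce the
chemical map (Dice 1.000 against the planted 200 µm disk; equivalent
diameter 200.1 µm) and the SIMS–SPRi agreement report (Dice 1.000,
Pearson r 0.982 at default settings; the wash tail is visible to SIMS only,
so sub-unity agreement is expected when it survives thresholding).

## Layout

```
src/glycoarray/     library: synthetic_data, sims_cube, pca_roi, ion_maps,
                    spri, correlate, pipeline
analysis/           numbered narrative drivers (01_simulate ... 05_correlate)
tests/              pytest suite incl. end-to-end recovery checks
scripts/            acceptance.py
docs/methods.md     models, parameter choices, numerical details, limitations
```
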