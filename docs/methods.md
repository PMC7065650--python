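# Methods

This note documents the models, algorithms and numerical choices behind
`ramangrade`, and what the synthetic phantoms do and do not establish.

## The analysis problem

Probe-based Raman maps of bladder biopsies are rasters of spectra (600–3100
cm⁻¹) in which the Raman signature of the tissue rides on a background that
is roughly an order of magnitude larger: broad tissue autofluorescence plus
a fixed fiber-probe contribution. The analysis has three stages: (1) a
preprocessing chain that isolates the Raman signal, (2) a hierarchical
two-level PLS-LDA classification — level 1 (ML1) separates tumor from
non-tumor (NT) spectra, level 2 (ML2) grades low- (LG) vs high-grade (HG)
tumor using only the spectra level 1 assigned as tumor — and (3) spatial
heterogeneity analysis of the per-pixel predictions.

## Synthetic phantoms

No public dataset accompanies this kind of probe measurement, so the
package ships a generator whose output has the statistical structure the
analysis assumes, with full per-pixel ground truth.

Each pixel spectrum is

    y = Σᵢ cᵢ sᵢ + A·f(ν̃)·(1 + t·ν̃′) + F·g(ν̃) + d + ε + spikes

* **Pure components** sᵢ: collagen, lipid, protein and nucleic acid, each a
  sum of Gaussian bands at the standard tissue-Raman positions (729, 869,
  937, 1003, 1064, 1103, 1176, 1265, 1335, 1446, 1656, 2850, 2885, 2930
  cm⁻¹), FWHM 12 cm⁻¹ in the fingerprint and 35 cm⁻¹ in the CH-stretch
  region. The nucleic-acid component reuses the phosphate-bearing 1003/1103
  cm⁻¹ positions, as no dedicated nucleic-acid bands appear in the band
  model.
* **Concentrations** cᵢ: class means encode the biology the difference
  spectra show — NT is collagen-rich (1.0 vs ≈0.38 for tumor), tumor is
  lipid-rich (≈0.78 vs 0.30), and LG/HG differ mainly on the protein and
  nucleic-acid components (0.60/0.50 vs 0.74/0.54). Pixels scatter around
  the class mean with SD 0.05 per component; each biopsy additionally draws
  a class-level offset with SD 0.03 shared by all its pixels. These two
  dispersions were calibrated once so that the phantom reproduces the
  pixel-map purity observed in real prediction maps (a typical non-tumor
  biopsy has ≈98% of its spectra predicted NT); larger values produce maps
  far noisier than the study's.
* **Fluorescence** A·f(ν̃): a smooth exponential-plus-hump envelope with
  per-pixel amplitude (CV 25%) and a small random linear tilt; the default
  amplitude puts the background peak at 10× the Raman peak. The true
  fluorescence-to-Raman ratio of bladder tissue is not quantified anywhere;
  10:1 is an uncalibrated but deliberately unfavourable choice.
* **Fiber background** F·g(ν̃): one fixed smooth broad-band shape shared by
  all pixels, amplitude 1.5× the Raman peak.
* **Noise**: shot-like (SD = 0.03·√intensity) plus read noise (SD 0.02);
  Poisson exactness is not attempted. **Cosmic spikes**: Poisson rate
  0.03/spectrum, 1–2 channels wide, 20–120× the local noise SD.
  **Dark offset**: constant 0.2 counts.
* **Spatial structure**: graded (and ungraded-tumor) biopsies carry one
  contiguous tumor blob grown by random accretion, occupying a per-biopsy
  fraction drawn from U(0.3, 0.8); NT biopsies are homogeneous. The default
  cohort is 48 biopsies from 28 patients (14 NT / 14 LG / 14 HG / 6
  ungraded tumor), on 16×16 grids with a 2 cm⁻¹ axis — scaled so the whole
  two-level analysis runs in about a minute on one core while keeping ≈250
  spectra per biopsy, the order of the real maps.

What the phantoms do *not* emulate: instrument point-spread, wavenumber-
dependent noise correlations, substrate (CaF₂) bands, biological
covariance between constituents, or any real inter-patient biology. Tests
passing on phantoms show the pipeline recovers planted structure under
fluorescence-dominated, spatially heterogeneous conditions — not clinical
performance.

## Preprocessing chain

Order: wavenumber calibration → intensity calibration → dark subtraction →
cosmic-spike removal → PCA noise filter → Savitzky-Golay smoothing → crop
to 600–3100 cm⁻¹ → background correction → unity normalization. Cropping
before background correction is a choice (the alternative order changes
little for EMSC but matters for polynomial fits anchored by out-of-range
channels).

* **Wavenumber calibration** matches detected standard peaks (acetaminophen
  ASTM positions; sub-channel centers by log-parabola vertex interpolation,
  exact for Gaussian peaks) to references within ±6 cm⁻¹ and refits a
  polynomial of degree min(3, matches−1). Fewer than 3 matches is an error.
* **Spike removal** flags samples that are simultaneously spectral outliers
  (> 8 MAD-based SDs against a 7-channel running-median envelope) and
  spatially inconsistent (same excess against the median of the 4-connected
  neighbour pixels at that channel). Real bands are shared by neighbours,
  spikes are not, so the conjunction suppresses false positives on band
  maxima. Flagged samples are repaired by linear interpolation along the
  axis and logged.
* **PCA filter**: per-biopsy reconstruction from the top 10 principal
  components (config-exposed). **Savitzky-Golay**: window 11, order 3.
* **EMSC** (primary background correction): ordinary least squares of each
  spectrum on [reference | interferents | polynomials of degree 0..5].
  Polynomials are represented internally as Legendre terms on the axis
  domain (design condition number ≈45 instead of an unusable raw-power
  Vandermonde) and reported in the ordinary power basis. The corrected
  spectrum is (y − interferent/polynomial part)/b_ref; |b_ref| ≤ 1e-8 is a
  degenerate-fit error. The default reference is the label-free mean of all
  spectra entering the correction; the measured fiber shape is the default
  interferent.
* **Alternates**: ALS (λ=1e4, p=0.01, ≤50 iterations), Lieber-style
  clipped polynomial refitting (degree 9, ≤200 iterations), SNIP with the
  log-log-sqrt transform (half-width up to 16 channels). Defaults were set
  once against two contracts on the 10:1 fluorescence shape: pure-baseline
  residual < 2% of the baseline peak, and a narrow band's chord-corrected
  area preserved within 10%.
* **Normalization**: Euclidean (L2) by default — the most common choice in
  Raman chemometrics; L1/area/max via config.

## PLS-LDA

PLS1 (NIPALS, deflating X only) regresses spectra on numeric class codes
(1/2). The latent-variable count is selected inside each training fold by
leave-one-(biopsy)-out CV on the per-biopsy mean spectra: among candidate
counts whose LOO mean squared error is within one standard error of the
best, the highest prediction-response correlation wins, remaining ties
going to the smallest count. LDA is fitted on the training scores with
**balanced priors** (0.5/0.5), so per-spectrum assignment does not inherit
the cohort's 34-tumor/14-NT biopsy imbalance; a singular within-class
scatter falls back to a shrinkage-stabilized eigen solver (logged). The
LDA direction is back-projected through the PLS rotation to a
wavenumber-domain coefficient spectrum; decisions computed from that
coefficient vector reproduce score-space LDA decisions exactly, and exact
zeros of the decision function break toward the lower code.

## Two-level scheme

Each biopsy is represented by its mean-random-pixel (MRP) set: for k =
1..80, the mean over k uniformly drawn pixels (without replacement;
with replacement, flagged, when k exceeds the pixel count). Biopsies are
partitioned into 5 histopathology-stratified folds, independently over 10
iterations (50 train/test pairs). Each model trains on the MRP sets of its
training biopsies; each pixel spectrum is scored only by models whose test
fold held its biopsy (the leakage-free reading; an all-models mode would
leak and is not the default). Hard codes are averaged per pixel: mean > 1.5
⇒ tumor, < 1.5 ⇒ NT, exactly 1.5 ⇒ unassigned — averaging hard codes (not
continuous scores) is what makes the exact-1.5 case well defined. The
kernel-density helper quantifies the empty region around 1.5 (Gaussian
kernel, Silverman bandwidth by default — note Silverman intentionally
oversmooths strongly bimodal samples, so gap reports at the default
bandwidth are conservative).

Level 2 trains only on the tumor-assigned pixels of the graded (LG/HG)
biopsies, with the same 5×10 discipline; a graded biopsy with no
tumor-assigned spectra is excluded with a warning. Biopsy-level labels at
both levels are majority votes over the biopsy's (selected) spectra, one
vote per held-out model instance; performance reports count one prediction
per biopsy per iteration, with a Clopper-Pearson 95% CI on accuracy.
Ungraded-tumor biopsies participate in level 1 as "tumor" and are excluded
from level 2. Fold grouping is by biopsy (the literal unit of the
hierarchical split); patient-level grouping is available and stricter.

The one-level comparison runs the identical grading machinery on
*unselected* whole-biopsy MRP sets. Its handicap is tissue dilution: a
biopsy with tumor fraction f carries grade contrast scaled by f plus a
dominant tumor-fraction nuisance axis, which is exactly the degradation the
two-level selection removes.

## Numerical and degenerate-input choices

* Exact decision-boundary hits tie to the lower code; exact 1.5 means are
  unassigned, never rounded.
* Long-CSV I/O writes floats with shortest-repr precision and reads with
  round-trip parsing, so CSV and HDF5 round-trips are both bit-lossless.
* Readers reject inconsistent files (duplicate pixels, non-increasing axes,
  assignment inconsistent with the 1.5 rule) instead of repairing them.
* Constant band images cannot be min-max scaled and are returned raw with a
  flag; zero spectra cannot be normalized and raise.
* All randomness flows through seeded `numpy` generators; the full
  two-level run is bit-reproducible given (data seed, plan seed, model
  seed).

## Known limitations

* The phantom's class separability is, by construction, cleaner than
  clinical reality; headline rates on phantoms (≈95%+ at level 1) exceed
  what the method achieves on real tissue and should be read as recovery of
  planted structure, not as clinical claims.
* EMSC quality depends on the interferent set; with no fiber spectrum
  supplied, fiber background falls to the polynomial terms alone.
* The spike detector assumes spikes are spatially isolated; a spike hitting
  the same channel of two adjacent pixels simultaneously would evade the
  spatial test.
* `select_n_components` assumes a univariate response; the package is
  strictly two-class per level by design.
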