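# Methods

## The measurement model

A hyperspectral acquisition is a reflectance hypercube
`R(y, x, λ)` of shape 640 × 480 × 100 on a uniform wavelength grid.
Device literature quotes the range both as "500–1000 nm in 5 nm steps"
(101 points) and as 500–995 nm with 100 bands; the two are reconciled
here as **100 band centers at 500, 505, …, 995 nm**, which matches the
stated cube size. The grid is configurable for devices that report the
other convention.

All indices reduce to two primitives:

- **Band mean** — the arithmetic mean of reflectance over all grid
  points λ with `lo ≤ λ ≤ hi`, both ends inclusive (so 925–935 nm covers
  {925, 930, 935}). Inclusivity is applied uniformly to every band so
  all indices share one convention.
- **Band second-derivative mean** — the mean of the central-difference
  second derivative `(R(λ−h) − 2R(λ) + R(λ+h))/h²`, `h = 5 nm`, over the
  band's grid points, after an optional 1-D Gaussian pre-smoothing along
  wavelength (σ in grid steps, default 1). The estimator is not
  standardized anywhere; central differences are the canonical choice,
  exact on quadratics, and the smoothing is exposed rather than
  hard-coded because it only matters in the presence of band noise.
  Bands must be interior to the grid (one neighbour on each side).

### Indices

| index | definition (raw) | responds to |
|---|---|---|
| LWR | mean R(925–935) / mean R(965–985) | ↑ with water, ↑ with lipid loss |
| TWI | mean R(875–895) / mean R(950–975) | ↑ with water |
| TLI | mean d²R/dλ² over 925–935 (nm⁻²) | ↑ with lipid |
| StO₂ | d²-mean(575–590) / d²-mean(740–780) | hemoglobin vs deoxyhemoglobin curvature |

Water absorbs near 970 nm, i.e. inside the *denominator* bands of LWR
and TWI — both indices therefore **increase** when tissue water
increases. The interlimb difference ΔLWR (affected − unaffected) is
consequently positive for edematous limbs, and the staging model's
`direction` flag defaults to +1 (high imaging stage = large positive
ΔLWR). The flag exists because the sign convention of a plotted ΔLWR
axis is ambiguous in secondary sources; flipping it only relabels the
clusters.

The commercial device displays TWI/TLI/StO₂ affinely rescaled to
[0, 100] with unpublished constants. Here `IndexScaling` maps a
documented physiological raw range linearly onto [0, 100] (TWI raw
0.5–1.5, TLI raw 0–5·10⁻⁴ nm⁻², StO₂ raw 0–50), clamped. These choices
affect **only** display maps and the segmentation fusion (where each
map is subsequently normalized by its own maximum anyway); every
scientific output — deltas, staging, statistics — is computed from raw
values, so no conclusion depends on them. An exactly curvature-free
denominator band (|d²-mean| < 10⁻¹² nm⁻²) makes StO₂ explicitly
undefined (NaN), never silently zero.

## Segmentation

Limbs are imaged on a dark surface, so tissue is bright in both TWI and
StO₂. The fused map is `TWI_s/max(TWI_s) + StO₂_s/max(StO₂_s)` where
`·_s` denotes the scaled index image after Gaussian filtering with a
5 × 5 px support (σ = 1 px, truncated at 2σ; the kernel size is the
documented quantity, σ is a package choice and configurable).

The fused histogram is judged **bimodal** by: 64 bins over the data
range, moving-average smoothing (window 5), and counting peaks of
prominence ≥ 5 % of the tallest bin with `scipy.signal.find_peaks`
(zero-padded so modes in the extreme bins count). The criterion and bin
count are package choices — no published rule exists — and are exposed
as knobs. If bimodal, the threshold is Otsu's method on a fixed
256-bin histogram over [0, 2]; cuts through an empty valley tie exactly,
and the tie resolves to the plateau midpoint so the threshold sits
centrally between the modes. If not bimodal (no body in frame, or body
filling the frame), a fixed threshold of 1.0 is used. The mask is
`fused > threshold`, with threshold, method and central coverage
recorded for provenance.

Of the three repeat acquisitions per site, the repeat whose mask covers
the largest fraction of the central ROI disk is analyzed; ties break to
the lowest repeat index. The selection region equals the analysis ROI,
so selection optimizes exactly the region that is measured.

## ROI spectra and deltas

The ROI is a disk of 100 px diameter (≈ 4.6 cm at the fixed 50 cm
capture distance) at the image center. The center convention is
`((H−1)/2, (W−1)/2)` with strict membership `dist < diameter/2`
measured between pixel centers — unambiguous and reflection-symmetric;
note that on even-sized frames a diameter-1 disk is empty under this
convention. Each tissue pixel in body ∩ ROI is divided by its summed
intensity (L1 normalization) and the normalized spectra are averaged;
the representative spectrum sums to 1. Indices are computed **from the
averaged spectrum** — not averaged over per-pixel indices; the two
orders differ on heterogeneous tissue and the former is the contract.
An empty body ∩ ROI is flagged as a missing measurement, never a zero
spectrum. Deltas are plain componentwise subtractions on raw indices;
L1 normalization plus ratio/derivative indices make them invariant to
independent global illumination scaling of each side.

## Clinical metrics

Circumference and cutis/subcutis thickness comparisons are percentages
of the unaffected side (`affected/unaffected × 100`); two-point
discrimination and mobility angles are signed differences. Questionnaire
items (rated 1–4) are grouped into categories; the category score is
`(mean(answered) − 1)/3 × 100` — the unique order-preserving affine map
of the item range onto 0–100 — with unanswered items excluded. Items are
taken as-is (no reverse scoring; none is documented for the category
scheme modeled here). Site-level analyses include only sites flagged as
clinically affected, via a single shared predicate.

## Staging and statistics

The imaging stage is agglomerative hierarchical clustering of the 1-D
ΔLWR values cut at k = 3, relabeled low/mid/high by ascending cluster
mean. Ward linkage is the default because it mimics variance-based
grouping of scalars; on well-separated data it coincides with the
optimal contiguous partition (asserted against a dynamic-programming
oracle in the tests — a Ward violation on pathological data would
surface as a test failure, not be hidden). k = 2 merges the low and mid
groups and k = 4 subdivides the high group on three-clump distributions;
this is encoded as a regression scenario, not a universal invariant.

Group comparisons: two-sided Mann–Whitney U, exact by full null
enumeration when the smaller group has ≤ 8 observations and the pooled
sample is tie-free (the regime of the small per-stage groups), otherwise
the tie-corrected normal approximation with continuity correction.
Association with clinical stage: Spearman rank correlation.
Distribution shape: D'Agostino–Pearson omnibus test (χ² with 2 df from
transformed skewness and kurtosis); below n = 20 results carry an
"unreliable" note, and below n = 8 the test refuses. Study sizing: the
Fisher-z minimum detectable correlation
`tanh((z₁₋α/₂ + z_power)/√(n−3))`, which gives 0.36 for n = 58,
α = 0.05, power 0.80.

The cohort-level interface is a statsmodels-style pair:
`HsiStagingModel(delta_lwr, le_stage).fit()` returns an
`HsiStagingResults` carrying labels, cluster means, the Spearman
correlation, adjacent-stage tests and normality diagnostics, with a
`summary()` table; `run_cohort` wraps the whole image-to-table pipeline
around it.

## Synthetic cohort

The generator is first-class, tested code; its defaults define the
study conditions.

**Spectra.** Reflectance is a quadratic baseline (0.30 + 0.25u − 0.10u²,
u = (λ−500)/495) multiplied by Gaussian absorption dips — oxyhemoglobin
at 542 nm (σ 10, depth 0.35) and 577 nm (σ 9, 0.30), deoxyhemoglobin at
760 nm (σ 22, 0.06), lipid at 930 nm (σ 12, depth d_lipid, default
0.08), water at 970 nm (σ 18, depth d_water, default 0.20) — plus
per-band Gaussian noise (sd 0.002), clipped positive. This is the
minimal structure that reproduces the characteristic affected/unaffected
ratio signature (local peak near 920 nm, dip near 970 nm) and makes
every index respond monotonically to its chromophore. It is **not**
radiative-transfer realism: no melanin/skin-tone axis, no scattering
model, no specularities — passing tests demonstrate pipeline
correctness on the assumed signal structure, not device-level fidelity.

**Scenes.** An elliptical limb of body-model spectra on a dark flat
background (reflectance 0.06 with a weak broad NIR absorption so its
StO₂ denominator is stable), per-pixel redrawn noise, and per-repeat
framing jitter. Default rendering is 48 × 64 px with a 10 px ROI — a
1/10-scale frame that keeps the full cohort pipeline around ten
seconds; full 480 × 640 frames with the 100 px ROI are one flag away
and are used for the format-conformance checks.

**Cohort.** 58 patients with stage counts 11/13/28/6 (stages 0–III);
three sites per arm, each independently flagged "affected" with
stage-dependent probability (0.303, 0.231, 0.583, 0.778), reproducing
the observed affected-measurement counts of roughly 10/9/49/14.
Affected sites receive a stage-conditional water-depth increment on the
affected side (means 0 / 0.02 / 0.17 / 0.24, sds 0.008 / 0.01 / 0.06 /
0.05) and a proportional lipid decrement (0.15 × increment); stage II
additionally has a 35 % "non-responder" fraction drawn from the stage-0
distribution, producing the overdispersed stage-II severity spread
(stage-II measurements span all imaging stages) and a clearly
non-normal stage-II ΔLWR distribution. Between-patient baseline sds:
water 0.02, lipid 0.01; per-site sds: water 0.028, lipid 0.035.
Clinical covariates are drawn per stage: circumference increments
(0/2/7/15 %, sd 8 %), cutis (0/8/28/55 %, sd 22 %), subcutis
(0/10/32/65 %, sd 26 %), two-point discrimination (+0/0.5/1.5/3 mm,
sd 1.5), mobility (−0/3/8/15°, sd 8), questionnaire latent means
1.3/1.8/2.3/2.9 (sd 0.65) rounded onto the 1–4 item scale with 5 %
missingness.

**Calibration.** The spectral and clinical effect sizes above were fixed
*once* so the default cohort reproduces stage correlations of realistic
strength — Spearman r ≈ 0.64 between clinical and imaging stage
(committed as `CohortConfig.target_spearman_hsi`), r ≈ 0.6 for ΔTWI and
the ultrasound percentages, ≈ 0.55 for the leading questionnaire
category, with ΔTLI clearly weaker — and are committed as configuration.
They are calibrated targets, not predictions; parameter-recovery tests
check the pipeline against the generator's own target, and a zero-effect
configuration (`CohortConfig.null()`) ties the Fisher-z bound to
simulation: on null cohorts the recovered |r| stays below 0.36 in ≥ 80 %
of seeds.

**Fast path.** `render="spectra"` emits each measurement's
representative ROI spectrum directly (mean of 200 L1-normalized noisy
pixel draws) instead of rendering and segmenting scenes — identical in
distribution to the image path for a correct mask, and used where many
replicate cohorts are needed (null calibration); the image path is
exercised by the segmentation and end-to-end tests and the first
replicate of every acceptance run.

## Numerical and degenerate-input choices

- Otsu runs on a fixed 256-bin histogram over [0, 2] for determinism;
  constant input is rejected.
- Spatially constant scenes (no body) reach the fixed-threshold path;
  an all-zero index image (max-normalization impossible) raises.
- Representative-spectrum averaging renormalizes the mean to unit sum
  to absorb float rounding.
- Seeds: every stochastic entry point takes an explicit integer seed or
  `numpy` Generator; identical seeds give bit-identical cohorts.

## Known limitations

- No radiometric calibration, curvature/illumination-angle correction,
  or registration between sides; the interlimb design absorbs global
  factors only.
- The bimodality rule and Otsu binning are reasonable defaults, not
  validated against device histograms.
- The generator's clinical covariates are conditionally Gaussian given
  stage; real covariates are skewed and correlated with each other.
- Published per-patient source data are needed for the
  reproduction test of the published correlation table
  (`tests/test_acceptance.py::TestPublishedSourceData`); without that
  spreadsheet the test reports failure by design rather than silently
  passing.
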