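# Methods

This note documents the models, defaults and numerical choices behind
`thermospec`, and what the synthetic study does and does not establish.

## Spectral model and conventions

Spectra live on a strictly decreasing wavenumber axis (instrument
convention, high → low). The default synthetic axis spans 4000–898 cm⁻¹
at 2 cm⁻¹ spacing; the acquisition resolution such studies quote is
4 cm⁻¹, but digitized point spacing is typically finer, and the grid end
at 898 cm⁻¹ keeps the conventional 899 cm⁻¹ baseline anchor strictly
inside the axis. Spacing is a config knob.

The band-intensity primitive *I_ν̃* is an interpolated **peak height**,
not an area: linear interpolation between the two bracketing grid points,
exact on the grid. Band areas appear only through `band_sum`, the
inclusive sum of grid-point absorbances in a closed window, which is how
the total-protein marker ∑(I₁₆₀₀₋₁₇₀₀) is defined. Whether the original
analysis read heights or small-window integrals for single-band markers
is not documented; heights are the simpler total convention and are used
throughout.

`fwhm` measures full width at half the local maximum height above a
*local base*, defined as the lower of the two window-edge absorbances.
Spectra reaching this function are baseline-corrected, so the base is
near zero, but the rule must be total: with band overlap (the CH₃ band at
2958 cm⁻¹ sits near the default ±40 cm⁻¹ window edge around 2920 cm⁻¹)
the edges are nonzero and the local base keeps the measurement
well-defined. Half-height crossings are located by linear interpolation
walking outward from the peak; a missing interior maximum or an
uncrossed side raises a shape error naming the failing side.

## Synthetic study generator

Each pixel spectrum is

  scatter × Σ_b (amp_b · jitter · G(ν̃; c_b, σ_b)) + c₀ + c₁ν̃′ + c₂ν̃′² + ε,

with Gaussian bands G, per-pixel per-band multiplicative jitter
(sd 0.04), a uniform scatter factor in [0.7, 1.3], a random degree-2
polynomial baseline in the rescaled wavenumber ν̃′ ∈ [−1, 1]
(coefficients uniform in ±0.04/0.06, ±0.03, ±0.02), and i.i.d. additive
noise (sd 0.004). The distortion family is exactly what the anchored
baseline + quadratic EMSC chain removes, so preprocessing correctness is
verifiable by recovery. Gaussian line shapes (no Voigt) are sufficient
for every property the pipeline measures and save one parameter.

The base band model (20 bands, 3290–972 cm⁻¹) uses standard mid-IR
biomolecular assignments with amplitudes plausible for EMSC-normalized
thin brain sections. Group effects are multiplicative on amplitude and
width per assignment:

* **both fatal groups**: CH₂ stretching bands ×1.20 (amplitude) and
  ×0.85 (width), olefinic 3012 cm⁻¹ ×0.70 — more saturated lipid,
  stiffer membranes;
* **hyperthermia only**: amide I α-helix and β-turn ×0.80, β-sheet
  (1622 cm⁻¹) ×1.50, glycogen 1151 and lactate 1126 cm⁻¹ ×0.75,
  nucleic-acid bands (1122, 972, 1086 cm⁻¹) ×0.80 — protein loss and
  aggregation, carbohydrate consumption;
* **hypothermia only**: RNA 1122, DNA 972 and lactate 1126 cm⁻¹ ×1.15,
  tyrosine 1518 cm⁻¹ ×0.85, plus a milder amide I shift (β-sheet ×1.15,
  β-turn ×0.90) mirroring the cold group's difference-spectrum shape.

True effect magnitudes are not published numerically for this design, so
these multipliers are calibration choices fixed once: the smallest knob
set that reproduces every reported direction of effect *and* leaves the
strongest three-group discriminators at the nucleic-acid and β-sheet
reporter bands, as the reported random-forest ranking requires. The DNA
band amplitude (0.18) is set so the 972 cm⁻¹ block clears the additive
noise floor; weaker DNA bands leave that block just below the top-10.

Per-sample reproducibility: each image draws from
`SeedSequence([master_seed, crc32(sample_id)])`, so images regenerate
identically regardless of generation order.

What the generator does **not** emulate: resonant Mie scattering,
spatial tissue texture (pixels are exchangeable within an image),
per-animal random effects (images are i.i.d. within group), detector
physics, or water-vapor/CO₂ lines. Passing tests therefore demonstrate
the pipeline's correctness on its intended distortion family and effect
structure, not robustness to those real-data complications — in
particular, with no per-animal variance component the mean-spectrum
statistics are better powered than real data would be.

## Preprocessing

The chain runs baseline → EMSC → region reduction, in that order, with
the EMSC reference (dataset pointwise mean of baseline-corrected
spectra, the conventional choice) computed once per dataset.

Anchored baseline: anchor absorbances are read by interpolation, so
anchors need not be grid points; beyond the outer anchors the end
segments extend **linearly**. Linear extension keeps the baseline
kink-free at the off-grid 899 cm⁻¹ anchor, which makes the subtraction
exactly idempotent and the self-subtraction test exact; the choice is
immaterial downstream because region reduction discards everything
outside [899, 3100].

EMSC uses polynomial degree 2 (configurable), matching the generator's
distortion family, and is fitted on the full pre-reduction axis. A
multiplicative coefficient |b| < 1e−8 raises a degenerate-fit error —
the spectrum carries no reference-like signal and dividing by b would
be meaningless. Two exact properties are tested: idempotence (the
residual left by one correction is orthogonal to the design, so a second
fit is the identity) and scatter invariance (αs + β corrects to the same
spectrum as s).

One recovery caveat, verified rather than assumed: EMSC corrects every
spectrum toward the shared reference *plus its own out-of-span
residual*. Spectra whose chemistry differs from the reference keep that
difference (this is the point of EMSC), so exact recovery of each
group's pure spectrum is only achievable when all groups share one
chemistry; the recovery test uses a shared-profile, offset-baseline
dataset where recovery up to a common positive scale is exact, and a
separate test asserts that between-group contrast survives
preprocessing when profiles differ.

Region reduction keeps grid points inside closed regions (default
[2800, 3100] ∪ [900, 1800]), preserving values exactly. The reduced axis
is no longer uniformly spaced (it carries the inter-region gap); the
axis uniformity check is therefore advisory, applied to acquisition
axes only.

## Chemometrics

Mean spectra: seeded permutation of an image's pixels, split into
⌊n/k⌋ disjoint groups of exactly k = 10, remainder discarded (the
default geometry has none); each group averages to one observation. No
pixel is reused, and the mean of an image's group means equals the mean
of its retained pixels exactly.

PCA: SVD of the column-mean-centered matrix. Sign convention: each
loading's largest-magnitude element is positive, making scores and
loadings reproducible. Explained variance ratios come from squared
singular values; a matrix of identical observations reports zero
explained variance (guarded against rounding noise). The pipeline always
computes the first three components for each pairwise contrast and the
three-group run; which pair of components to plot is presentation, not
computation.

Random forest: 500 trees, √p features per split, unlimited depth — the
conventions of the classical R implementation. Importances are mean
decreases in Gini impurity normalized to sum 1 over wavenumbers (the
scikit-learn convention; the R implementation reports unnormalized
totals — rankings are identical). Out-of-bag accuracy is reported as a
diagnostic only; no train/test protocol or accuracy is part of the
analysis contract. Wavenumber ranking breaks importance ties by
ascending wavenumber, so rankings are stable.

## Statistics

Quantiles use the type-7 (linear interpolation) convention; IQR values
depend on this and it is stated for that reason. Kruskal–Wallis uses the
tie-corrected H referred to χ²_{k−1}; an all-tied sample returns
(H = 0, p = 1) instead of an error. The Nemenyi post-hoc test is the
chi-square variant appropriate after a Kruskal–Wallis design: jointly
ranked data, pairwise statistic
(R̄ᵢ − R̄ⱼ)² / [N(N+1)/12 · C · (1/nᵢ + 1/nⱼ)] with tie correction
C = 1 − Σ(t³−t)/(N³−N), referred to χ²_{k−1}. The studentized-range
variant is intentionally not used; the chi-square form is conservative,
which the null-calibration test quantifies (no pairwise flag in ≥95% of
null repetitions where the omnibus p ≥ 0.5, and KW type-I error within
[0.03, 0.07] at α = 0.05 under the 17/17/13 design).

The default statistical unit is the mean spectrum (n = 272/272/208),
matching what the box-plot style of reporting evaluates; a per-sample
mode (pixel-averaged markers, n = 17/17/13) is provided as a switch
because the unit of analysis is genuinely ambiguous in such designs.
Undefined marker values (ratio denominators below 1e−8, unresolvable
CH₂ bands) are dropped per marker with a logged count; a marker whose
groups cannot supply two defined values each is reported not-testable
rather than raising.

No multiple-testing correction is applied across the ten markers, by
design parity with the analysis this package reproduces.

## Pipeline and problem sizes

`run_pipeline` derives each stage's seed from the master seed mixed with
a fixed stage tag (`SeedSequence([master, crc32(stage_name)])`), so
stages are independently re-runnable and changing only the forest seed
changes only the forest outputs. All outputs are plain CSV (12
significant digits — enough to bound write/read round-trips below 1e−9
absolute for laboratory-magnitude absorbances) plus one JSON metadata
file recording every seed, parameter and dropped-value count.

The default study (7520 spectra × 1552 points) generates in ~1 s and
preprocesses in ~2 s; the full analysis including a 500-tree forest
completes in well under a minute on one CPU, and the test suite uses
reduced geometries (e.g. 4 × 5 pixel images) where study scale is not
itself the property under test.

## Known limitations

* JCAMP-DX support covers the single-block AFFN `(XY..XY)` dialect this
  package writes; compressed (DIF/DUF) encodings are not parsed.
* The FWHM rule measures the dominant local maximum in the window; it
  does not deconvolve overlapping sub-bands, and a shoulder stronger
  than the target band would be measured instead.
* The chi-square Nemenyi test is conservative for small groups; with
  n = 17/17/13 per-sample mode, borderline contrasts may go unflagged.
* Generator realism limits are listed above; in particular, statistical
  power on synthetic data overstates what per-animal variance in real
  tissue would allow.
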