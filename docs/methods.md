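# Methods

## Sensor equilibrium and pool algebra (`nernst`)

All potentials are millivolts, concentrations molar, temperatures kelvin.
The glutathione couple is treated as a two-electron half cell at
equilibrium with the sensor; `RedoxConstants` carries R = 8.315 J K⁻¹
mol⁻¹, F = 96485 C mol⁻¹, the temperature and the 60.1 mV/pH midpoint
slope. The default temperature is 310.15 K (cells at 37 °C); it is
configurable because reference computations in the literature are
sometimes done at 25 °C, and the two choices shift E_GSH by roughly
1–2 mV over the relevant range.

Q = [GSH]²/[GSSG] is referenced to a 1 M standard state. This is required
for self-consistency of the published chain (Q ≈ 81 mM together with
E_GSH ≈ −157 mV at E°′ = −190 mV); treating Q in any other unit breaks
that identity.

roGFP1-iE carries an explicit working-pH midpoint override of −190 mV at
pH 6.2. The generic pH correction from the pH-7 midpoint (−236 mV) gives
−187.9 mV; the override takes precedence because it is the value used in
practice for this sensor in acidic compartments, and the ~2 mV difference
is within the measurement uncertainty. Both routes remain available.

The degree of oxidation is clamped into [ε, 1−ε] with ε = 10⁻⁶ and a
flag. The Nernst relation diverges at OxD ∈ {0, 1}, and a sensor operated
near saturation — as this one is in the Golgi — routinely produces basal
ratios outside the [R_red, R_ox] window measured on other cells. Clamped
cells stay in the dataset (flagged) so the cohort median remains
meaningful; exact 0/1 inputs to the potential computation are rejected.

Uncertainty is a percentile bootstrap over cells (2000 resamples by
default, seeded). The cohort statistic for E_GSH is the **median**: near
sensor saturation a few clamped cells map to extreme potentials, which
would dominate a mean. `propagate_uncertainty` defaults to the mean for
general use and takes `statistic="median"` where robustness matters.

## Imaging (`imaging`)

Background is estimated as the per-block minimum intensity (600-px blocks
by default), expanded, Gaussian-smoothed (default σ = block/4) and
subtracted, clipping at zero. A known property of minimum-based
estimators under read noise is a downward offset of roughly 3 noise
standard deviations per block (the expected minimum of many Gaussian
samples), leaving a small positive residual in both channels; because the
ratio is formed over bright Golgi pixels, the induced ratio bias is well
below 1 % at realistic signal levels.

Cells are found by robust-background thresholding: discard the dimmest
and brightest 5 % of pixels, threshold at mean + k·sd (k = 2), take
8-connected components of at least 200 px. Golgi spots are enhanced with
a white top-hat (disk radius 5 px), thresholded with the same robust
rule computed within cell footprints, masked to cells, and all spot
pixels within one cell are grouped into a single region (minimum
10 px). Pixelated object rims can leave a few spurious top-hat pixels;
the minimum-area rule removes them in practice.

The per-cell ratio is the **ratio of masked channel means**, not the mean
of pixel ratios — the latter is biased at low counts because the
expectation of a quotient is not the quotient of expectations. Cells
whose denominator mean falls below 1 % of the field's 99th-percentile
intensity are excluded and logged.

Condition comparisons use the unpaired two-tailed Mann-Whitney U test:
exact enumeration when both samples have ≤ 8 values and no cross-group
ties, otherwise the normal approximation with tie correction. An
all-identical pooled sample returns p = 1.

The I(445)min/max span is estimated as the ratio of median denominator
intensities of oxidized vs. reduced cells. Since these are different
cells, expression variability enters this estimate; with ~180 cells per
condition its standard error is a few percent, contributing ≲1 mV to
E_GSH.

## TRaQ-G calibration (`calibration`)

The calibration relation is a one-site saturating hyperbola
ratio(c) = r0 + (r_max − r0)·c/(k_half + c), chemically motivated by a
HaloTag-bound dye reacting with GSH toward an end point. The functional
form is a package choice; a shape-preserving monotone interpolant (PCHIP)
is the fallback whenever the parametric fit fails to converge or to be
strictly increasing, and non-monotone calibration data are rejected with
the offending points named. Inversion is closed-form for the hyperbola;
ratios below r0 floor at zero and ratios at/above r_max return the upper
end of the calibrated range, both flagged, as is any ratio outside the
fitted ratio range (extrapolation).

The cohort summary is the median per-cell [GSH] with a percentile
bootstrap interval obtained in ratio space and mapped through the
inverse, so the interval inherits the local slope of the calibration.
Per-cell bounds shift each cell's ratio by the cohort bootstrap deltas
before inversion.

## PRM quantification (`prm`)

Monoisotopic residue masses come from pyteomics; proton and water are
1.007276 and 18.010565 Da. Cysteine carbamidomethylation is +57.021464 Da
(light); the heavy reagent I¹³CD₂¹³CONH₂ adds two ¹³C−¹²C (2 × 1.003355)
and two ²H−¹H (2 × 1.006277) differences, giving +61.040728 Da. The
complete monitored target list — eleven precursors plus the y14²⁺
quantifier fragment — is assembled from sequence + modification and
validated against its reference m/z table to ≤ 0.001 at construction;
any disagreement is a fatal error, which guards the whole arm against
mass-table typos.

Peak integration is deterministic (replacing interactive manual
curation): locate the apex inside the retention-time window, extend the
boundaries outward until the baseline-subtracted intensity falls below
1 % of the apex, and integrate trapezoidally above a median-of-trace
baseline. With a Gaussian peak the 1 % boundary captures ~99.8 % of the
area, and because light and heavy traces share their peak shape the
residual truncation cancels in the ratio. The unmodified peptide is
reported as detected only if its area reaches 1 % of light + heavy (it
is expected below the limit of detection).

Quantification uses the y14²⁺ fragment areas only; the other targets are
monitored for validation.

## Synthetic data (`synth`)

The generators emulate the study conditions: ≥50 cells per condition in
three replicates for imaging, three fields per calibration well, Gaussian
chromatographic peaks at a controlled light:heavy ratio. Cells are
non-overlapping disks with a three-blob perinuclear Golgi cluster; the
denominator channel is Poisson with expectation photon_scale (200
counts) × expression × (Golgi gain 5 or body fraction 0.3), the numerator
an independent Poisson draw at the cell's true ratio, plus a linear
background gradient and Gaussian read noise (σ = 3). Per-cell biological
dispersion of the true ratio is lognormal with σ = 0.10 — ratiometric
readouts cancel expression level, so residual per-cell spread reflects
genuine redox heterogeneity and is realistically of order 10 % — and
per-cell expression is lognormal with σ = 0.30. For the roGFP scenario
the condition ratios and denominator scales are derived from a target
potential through the exact two-state mixture of the fully reduced and
fully oxidized sensor signals, so the simulated truth is self-consistent
with the analysis equations. XIC pairs put both peaks at the same apex
and width with per-trace baseline noise at the stated SNR, on a constant
offset of five noise SDs so the nonnegativity clip does not bias the
noise.

What the generator does **not** model: optical PSF and defocus, 3-D
structure, realistic Golgi morphology, cell-shape variability, spectral
bleed-through, chromatographic tailing or retention-time drift. Passing
recovery tests therefore demonstrates correctness of the computational
chain under the stated noise model, not robustness to every property of
real data.

Determinism: every stream is derived from the integer seed plus CRC-32
labels of the condition/replicate/trace, via `numpy.random.default_rng`,
so identical scenarios are bit-identical across runs and platforms.

## Pipeline sizes and numerical choices

The self-check pipelines default to 3 replicates × 60 cells per condition
(roGFP) and 3 fields × 50 cells (TRaQ-G), with background-correction
block 64 px for the synthetic frames (each block must contain background
pixels; synthetic cells are ~32 px across). Bootstrap intervals use 2000
resamples. Calibration fits start from endpoint ratios and the median
positive concentration; ties in segmentation labels are resolved by
renumbering in raster order. Re-running any mode with the same config and
seed reproduces the summary bit-for-bit.

## Known limitations

* Near sensor saturation (OxD > 0.9) small ratio errors translate into
  several mV of potential; the clamp+median strategy bounds but does not
  remove this sensitivity.
* The block-minimum background estimator carries the noise-floor offset
  described above; fields whose objects fill entire blocks would be
  over-subtracted.
* The span estimate assumes oxidized and reduced populations have the
  same expression distribution.
* mzML ingestion is out of scope; chromatograms enter as CSV
  (rt_min, intensity, target_id, label).
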