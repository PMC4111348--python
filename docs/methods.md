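# Methods

## The measurement model

Bone is a composite of carbonated hydroxyapatite (mineral) and collagen
(protein). In an FT-Raman spectrum (1064 nm excitation, 0–3200 cm⁻¹ at
1 cm⁻¹) the mineral phase appears as the symmetric phosphate stretch ν₁
near 960 cm⁻¹ (the most intense bone band), the O-P-O bend ν₂ near
431 cm⁻¹ and a carbonate stretch near 1071 cm⁻¹; the organic phase appears
as three C-H stretches between 2800 and 3060 cm⁻¹, a C-H bend near
1425 cm⁻¹, and amide I near 1667 cm⁻¹. Protein loss during diagenesis
shrinks the organic bands while the mineral bands persist, so the ratio of
the integrated C-H stretch area to the phosphate ν₁ area is a relative —
not absolute — index of collagen survival. Three replicate scans on
different spots of compact bone average over spatially patchy preservation.

## Band integration and baseline

Integration windows are fixed: 3060–2800 (C-H), 983–930 (ν₁), 566–300
(ν₂) cm⁻¹. Integration is trapezoidal on the native grid. The default
baseline is a **local linear chord**: each window endpoint intensity is the
mean of the 5 grid points nearest the window edge, anchored at the mean of
their wavenumbers, and the chord through the two endpoints is subtracted.
The mean (rather than a median) is deliberate: means commute with affine
maps, so adding any `a + b·ν̃` background changes every corrected band area
by exactly zero — the property that makes the ratio robust to sloping
fluorescence backgrounds, and one the test suite asserts at 1e-9 relative
tolerance. For curved backgrounds the chord removes only the local linear
part; a strong exponential fluorescence hump (amplitude 5000 counts,
decay length 1500 cm⁻¹) leaves a residual curvature bias of about 5 % on
the ratio, versus a ~180 % error with no correction. Negative corrected
areas — pure noise in the organic window of a fully degraded bone — are
clipped to zero and flagged rather than treated as errors.

The ratio denominator is ν₁ alone by default, matching the convention of
the packaged reference tables; a ν₁+ν₂ variant is available because both
phosphate regions are informative. The published ratio values in the
reference tables are treated as given data, not as recomputable outputs,
because the original baseline treatment behind them is unrecorded.

## Replicates, fluorescence, C-H presence

Replicate ratios are combined as the arithmetic mean of per-replicate
ratios (replicates are independent sampling spots; the alternative — ratio
of mean areas — would weight spots by brightness). The sample standard
deviation is reported, and `sd/mean > 0.25` raises a heterogeneity flag
marking spatially uneven preservation.

A scan is rejected as fluorescence-swamped when its baseline-to-band
contrast — chord-corrected ν₁ area over the raw intensity integral of the
ν₁ window — falls below τ = 0.05, or when any point reaches a configured
saturation level. A spectrum with no bands at all is likewise unusable. A
sample whose every replicate is rejected has a missing ratio, mirroring the
two reference samples whose ratio could not be determined.

The qualitative C-H presence score (prominent / weak / absent) is the
signal-to-noise ratio of the chord-corrected C-H peak height against a
robust noise scale (1.4826 × MAD of chord-detrended intensities over the
band-free 1900–2200 cm⁻¹ region): prominent at SNR ≥ 10, weak at ≥ 3,
absent below. The score is scale-invariant and monotone in organic content
at a fixed noise realisation. Note the floor: the maximum of ~260 noise
points sits near 3 robust sigmas, so a zero-collagen but noisy spectrum can
legitimately score "weak"; "absent" is guaranteed only when the corrected
peak is non-positive. All thresholds are configurable.

## Chemistry QC

Atomic C:N = (%C/%N) × 1.1666, undefined when no nitrogen determination
exists. Flags: C:N outside the inclusive interval [2.9, 3.6] (values
printed at the endpoints count as acceptable); collagen yield below 1 % w/w
(the operative screening floor; the conventional band extends to 2 %, and
the floor is a parameter); nitrogen mass ≤ 7 µg delivered to the mass
spectrometer. δ values are per mil, (R_sample/R_standard − 1) × 1000.

## Correlation and influence analysis

Pearson r carries a t-based two-sided p (t = r√((n−2)/(1−r²)), n−2 df) and
a Fisher-z 95 % CI. Influence diagnostics for the simple regression of a
yield on the ratio are the hat values h᷉ᵢ = 1/n + (xᵢ−x̄)²/Sxx and externally
studentized residuals (statsmodels OLSInfluence supplies both). Sensitivity
re-analysis removes points by composable rules — explicit ids, then top-k
leverage, then top-m |studentized residual| recomputed on what remains —
and refits. The reconstruction of the reference three-point collagen
removal (two leverage points at the highest ratios, then one residual
outlier) is validated two ways: the rule reproduces the published
post-removal R² of 17.8 %, and an exhaustive search over all three-point
removals shows that set is the only one within ±0.1 of it.

Comparing dependent overlapping correlations (two correlations sharing the
ratio) uses Steiger's z with the covariance term evaluated at the
back-transformed average correlation; Williams' t is available and agrees
to ~0.02 in p at this n. The reference analysis did not name its test, so
its printed p-values are consistency references: our default reproduces the
collagen-vs-carbon comparison within 0.03. The method used is always
recorded in the result. p-values are two-sided and uncorrected throughout,
matching the single-family design of the comparison stage.

On the packaged tables, the collagen and nitrogen headline statistics
(r = 0.716 / R² = 51.2 %, r = 0.706 / 49.8 %) and every post-removal value
reproduce exactly, while the full-data carbon pair recomputes to
r = 0.649 / R² = 42.1 % — the printed records support the post-removal
carbon value (36.1 %) exactly, so the package reports the values its own
computation yields. Likewise the mean collagen yield over all 41 packaged
records computes to 0.97 %.

## Screening

Decision rule per sample: unusable when no ratio exists (fluorescence);
viable when the mean ratio reaches the threshold **or** C-H bands are
prominent; suspect otherwise. Evaluation against chemistry truth uses
strict inequality for truth (`collagen > floor`) and inclusive for
prediction (`ratio ≥ cut`), making confusion counts reproducible at tied
values. `choose_threshold` sweeps every observed ratio, maximises Youden's
J = sensitivity + specificity − 1 with ties broken toward higher
sensitivity (the lower cut), and returns the midpoint between the chosen
cut and the next observed ratio below it. Degenerate single-class truth is
an error, not a silent J = NaN.

## The synthetic generator

`simulate_spectrum` renders Gaussian (optionally pseudo-Voigt) bands at the
inventory above (centers/σ in cm⁻¹: 960/8, 431/12, 1071/8, 1425/20,
1667/25, 2880/20, 2935/20, 3010/20; widths chosen to resemble FT-Raman
bone and configurable), with mineral amplitudes independent of collagen
and organic amplitudes equal to `organic_gain × collagen × (1 + jitter)`,
jitter ~ N(0, sd) rectified at −1, drawn once per replicate. A polynomial
baseline plus optional exponential fluorescence hump and i.i.d. Gaussian
detector noise complete the scan; a "fluorescence-failed" sample is made by
driving the hump beyond the saturation level. `closed_form_ratio` gives the
erf-based analytic window-integral ratio used as oracle.

`simulate_cohort` co-generates chemistry: collagen ~ lognormal(−0.50,
0.85) % (median ≈ 0.6 %, upper tail to a few percent, matching the spread
of the reference cohort), %C = 3.0 + 9.0·collagen + N(0, 2.5) and
%N = 1.0 + 3.2·collagen + N(0, 1.0), truncated at zero — a crude
statistical stand-in for the reference samples, documented as such, not a
claim about real diagenesis. Defaults: n = 31, triplicates, 10 % replicate
jitter, noise sd 2 counts against a ν₁ peak of 1000. Randomness flows from
a single `SeedSequence`, so cohorts are bit-reproducible under a fixed
seed. `render_spectra=False` skips rendering and applies the jitter to the
closed-form ratio directly — the generator's own statistical model, used
where thousands of cohorts are needed; it omits detector noise, which is
negligible against the jitter at the default settings.

`jitter_sd_for_target_rho` calibrates the replicate jitter so the
population corr(mean ratio, collagen) hits a requested ρ, using the exact
rectified-normal moments E[max(1+e,0)] = Φ(1/s) + s·φ(1/s) and
E[max(1+e,0)²] = (1+s²)Φ(1/s) + s·φ(1/s); the rectification bounds the
attainable attenuation (squared CV ≤ π−1), and the solver reports
unattainable targets. At ρ = 0.7 the required jitter is large (sd ≈ 4.53)
and the sampling distribution of r̂ is wide and non-normal, so the recovery
tests use intervals frozen from a 2000-rep Monte-Carlo of the generator's
statistical model: central 99 % band (0.565, 0.822) for r̂ at n = 1000, and
mean r̂ = 0.682 at n = 31 (finite-sample attenuation below ρ).

The generator emulates band positions, relative intensities, collagen
scaling, fluorescence and noise; it does **not** model photon/shot noise,
instrument response, band-position diagenesis shifts, secondary minerals
(calcite/barite) or orientation effects. Passing tests therefore
demonstrate the correctness of the pipeline's arithmetic and statistics on
spectra with known truth, not its field performance on excavated bone.

## Problem sizes and numerical choices

Test-suite simulation sizes are chosen to keep the statistics decisive at
desk scale: one full-pipeline cohort at n = 1000 for ρ-recovery, 200 fast-
path cohorts at n = 31 for the mean-r̂ check, 2000 fast-path null cohorts
(constant collagen, so ratio ⊥ %C) for the 5 % type-I check with a 3σ
binomial band, and a 10,000-rep bootstrap oracle for the dependent-
correlation test at n = 20. Duplicate wavenumbers within 1e-9 cm⁻¹ merge
by mean intensity (order-independent); a ratio denominator at or below
1e-12 raises an undefined-ratio error; spectra not covering 300–3060 cm⁻¹
are unusable for ratio analysis. JCAMP-DX support is intentionally narrow —
uncompressed AFFN `(X++(Y..Y))` and `(XY..XY)` tables with
XFACTOR/YFACTOR — covering plain instrument exports; vendor binary formats
are out of scope.
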