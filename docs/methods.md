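# Methods

## Zernike decomposition

Thickness maps are modelled as linear combinations of Zernike polynomials on
the unit disk obtained by scaling positions by the analytical zone radius
(default 2.5 mm). The basis follows the ANSI/OSA convention: single index
`j = (n(n+2)+m)/2`, sine terms for `m < 0`, cosine for `m > 0`, and the
normalization `N(n,m) = sqrt(2(n+1)/(1+[m=0]))` included, so the basis is
orthonormal under the area-averaged inner product. "Up to the fifth radial
order" means all 21 terms with `n ≤ 5`. Whether a given device's export
includes the normalization factor is generally undocumented; this package
fixes the normalized convention, and coefficients from other conventions must
be rescaled before comparison.

Fitting is ordinary least squares over sampled points rather than analytic
inner products: segmentation dropouts (NaNs) and cropping destroy the
orthogonality of the sampled basis, while LSQ remains exact for in-span
signals under any sampling. Samples participate when their centre radius is
within the zone (closed disk) and their value is finite; invalid samples are
dropped row-wise. The design matrix must be numerically full rank (e.g.
samples on a single meridian confound azimuthal terms and are rejected with a
suggestion to sample more densely). Fit quality is the RMS residual over
participating samples, which for pure i.i.d. pixel noise of SD σ approaches
`σ·sqrt(1 − 21/N)`.

## Laterality and frames

Left and right corneas are nasal–temporal mirror images, so OS maps are
mirrored (`x → −x`) into a right-eye frame (+x nasal, +y superior) before
pooling. Under that reflection, fitted coefficients obey a parity law: cosine
terms flip sign iff `m` is odd, sine terms iff `|m|` is even, rotationally
symmetric terms are invariant — verified term-by-term in the tests. Maps
carry a frame tag and re-mirroring is refused, which guards against silent
double application. Same-day scans are averaged pixelwise (valid in the
average iff valid in at least one scan); under shared masks this commutes
with fitting by linearity.

## Biomarkers and circular statistics

Per-eye tilt and (sign-flipped) coma vectors, the population axes from the
cohort mean vectors, and the projection formulas are given in the README. Two
deliberate choices:

- The population axis is computed from the *mean vector*, not as a circular
  mean of per-eye unit axes: eyes with stronger patterns should weigh more,
  and the degenerate zero-magnitude eye then contributes nothing rather than
  an arbitrary angle. Zero vectors carry an explicit `degenerate` flag.
- Circular SD uses the Mardia definition `sqrt(−2 ln R̄)` on the per-eye
  vector directions. The reported angular dispersion could alternatively be
  defined on projected-gradient vectors; both views coincide here because the
  gradient vector is the tilt vector rescaled by 1/r.

Confidence ellipses use the bivariate-normal chi-square construction:
semi-axes `sqrt(q·λ_i)` from the eigen-decomposition of the sample covariance
`S` (data ellipse) or `S/n` (centroid ellipse), with `q` the chi-square(2 dof)
quantile at the chosen level (5.991 at 95%). A delta-method standard error of
the mean-vector direction, `sqrt(uᵀSu/n)/|μ|` with `u` the unit perpendicular,
supports coverage checks on simulated cohorts.

## Statistical battery

Each of the four coefficients of interest is tested against zero with a
Shapiro–Wilk gate at α = 0.05 (configurable): a one-sample t-test when
normality is not rejected, otherwise a Wilcoxon signed-rank test (scipy's
implementation; exact null for small n, normal approximation otherwise).
Bonferroni correction uses family size 4 by default. Paired device-compatibility
comparisons use the same gate on the per-eye differences; byte-identical
tables yield a degenerate "poolable" result rather than an error. Linear
regression (lid-wiper coma on lid-wiper gradient, so the slope is in mm, plus
the RSS astigmatism and RSS higher-order partners) reports the OLS slope,
Pearson r, R² = r², and the two-sided p for zero slope. RSS astigmatism is
`sqrt(c(2,−2)² + c(2,2)²)`; RSS HOA sums squares over `n ∈ {3,4,5}` excluding
primary coma.

A caveat replicated from the source analysis design: both eyes of a subject
are pooled without modelling within-subject correlation, which makes
population p-values slightly anti-conservative. Mixed-effects modelling is
out of scope.

## Synthetic cohorts

`PopulationSpec` defaults encode the study conditions the analysis targets:
69 subjects × 2 eyes × 2 same-day scans; per-eye coefficient vectors drawn
from a multivariate normal with the normative tilt/coma means and a diagonal
covariance from the normative SDs (1.55, 0.76, 0.62, 0.38 μm); piston mean
53 μm (a nominal central thickness; it cancels out of every biomarker); all
other coefficient moments zero — a declared assumption, since only the four
terms have published moments. An optional `tilt_coma_corr` injects covariance
between matched tilt/coma components to emulate the weak observed
gradient–coma correlation (r ≈ 0.27). Per-pixel Gaussian noise defaults to
0.35 μm, the typical Zernike-fit residual of a single scan. Maps are rendered
in the right-eye frame on a 6 × 6 mm grid (0.05 mm default spacing) and
stored mirrored for OS eyes, so the pipeline must genuinely undo laterality.
`degrade_with_artifacts` adds localized Gaussian bumps to emulate segmentation
failures for QC testing.

What the generator does **not** emulate: radial A-scan geometry and its
interpolation artifacts, speckle, tear-film structure, inter-device
differences, within-subject correlation between fellow eyes, and any real
covariance among the 17 unpublished terms. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the assumed
generative model, not robustness to every property of clinical maps.

## Problem sizes and numerical choices

Monte-Carlo tests render maps on a 0.25 mm grid (~300 in-zone samples, well
above the 21 coefficients); since LSQ is grid-density-invariant for in-span
signals, this only widens per-coefficient noise slightly relative to the
0.05 mm display grid. End-to-end recovery uses 300 replicate cohorts of 135
eyes; the type-I-error check uses 1000 null cohorts. Pseudo-inverses are
cached per grid geometry so repeated fits on a shared grid solve once.
Tolerances: noiseless round-trips to 1e−8, orthonormality of the sampled Gram
matrix to 1e−3 at 500² cell-centred resolution, angle arithmetic exact to
floating point with all outputs wrapped to [0, 360).

## Known limitations

- Quantities that depend on the full clinical distribution (per-eye RMSE
  spread, the empirical regression slope, the exact circular SDs) cannot be
  reproduced from the published moments alone; the package checks them only
  as simulation-recovery properties.
- Display orientation conventions differ between devices; internal frames are
  fixed by the quadrant semantics (+x nasal), and renderers document their
  orientation in the figure axes.
- No B-scan segmentation, device registration, or vertex re-centration: maps
  are assumed already centred on the analysis zone.
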