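# Methods

`leafspec` implements an optimal-band analysis for estimating leaf
chlorophyll content (LCC, µg·cm⁻²) from hyperspectral reflectance: an
exhaustive, cross-validated search over all ordered two-band vegetation-index
(VI) combinations in the 450–800 nm window, followed by contour-centroid band
selection and a final linear two-band prediction model.  This note documents
the statistical model, the numerical choices, and what the synthetic data
generator does and does not emulate.

## The regression model and its metrics

For a band pair (λi, λj) and per-sample reflectance R, three two-band index
families are considered:

* simple ratio `SR = R(λi)/R(λj)`
* normalised difference `ND = (R(λi) − R(λj)) / (R(λi) + R(λj))`
* chlorophyll index `CI = R(λi)/R(λj) − 1`

LCC is regressed on the index by simple OLS, `LCC = a·VI + b`.  Performance
is summarised by the coefficient of determination `R² = 1 − SSres/SStot`, the
root mean square error `RMSE = sqrt(mean((y − ŷ)²))` in µg·cm⁻², and the
Pearson correlation r.  RMSE is deliberately the standard absolute-residual
definition: it keeps RMSE in the units of LCC and directly comparable to the
response's spread, which is how two-band chlorophyll models are reported in
this field.  Qualitative correlation strength is binned on |r| as negligible
[0, 0.10), weak [0.10, 0.40), moderate [0.40, 0.70), strong [0.70, 0.90) and
very strong [0.90, 1]; interval endpoints are assigned to the higher bin — a
convention forced by the overlapping textbook interval labels.

Generalisation is assessed by k-fold cross-validation (default k = 10): the
samples are shuffled once with a caller-supplied seed and split into k
near-equal folds; each fold is held out once, the model is fitted on the
remaining folds, and validation R²/RMSE are computed on the held-out fold
with the *held-out fold's own mean* in SStot (the R² definition applied
verbatim to the validation set).  The summary is the unweighted mean of the
per-fold metrics; pooled out-of-fold metrics are available behind a flag.
Note that the held-out-fold R² is not an unbiased estimate of the population
R²: the fold mean, the training-estimated coefficients and the SSres/SStot
ratio each contribute a finite-sample downward correction of order 1/n_fold
(the unit tests derive and check the second-order value).

An important structural property: CI = SR − 1 is an affine map of the
predictor, and OLS fits, R², RMSE, r and cross-validation are all invariant
under affine predictor maps.  SR and CI therefore produce *identical* grids
to machine precision; the package surfaces this as an invariant rather than
reporting them as independent results.

## The grid search

For every ordered pair (λi, λj) in the window the VI is computed per sample
and the cross-validated regression is evaluated — with identical fold
assignment for every pair and family, so grids are directly comparable and
re-runs are bit-reproducible.  Rather than looping over the ~123 000 pairs of
a 351-band axis, the per-fold OLS coefficients and held-out residual sums are
expressed as moment sums over samples (Σx, Σx², Σxy on the training and
validation folds) and evaluated for all pairs at once with einsum
reductions; the full 351×351 grid at n = 120 takes a few seconds on one CPU.
Predictor and response are centred once before the moment pass to avoid
cancellation; the vectorised path is tested cell-for-cell (1e-10) against the
scalar k-fold implementation.

Pairs are excluded, with the reason recorded, when any sample's VI is
non-finite (e.g. a zero denominator after reflectance clamping) or when any
training fold sees a zero-variance predictor.  The λi = λj diagonal is
degenerate for all three families (the index is constant) and is always
excluded.

## Optimal-band selection

The per-pair mean validation R² forms a contour landscape over the (λi, λj)
plane.  The optimal bands are reported as the unit-weight image-moment
centroid of the top contour region:

    (Cx, Cy) = (M10/M00, M01/M00)

where the moments are sums of the region cells' wavelengths.  The top region
is defined as the cells within `delta` (default 0.01, one typical contour
step) of the grid maximum, restricted to the 8-connected component containing
the maximum.  The connectivity restriction is essential for ND: its
antisymmetry ND(λj, λi) = −ND(λi, λj) makes the mirrored cell attain exactly
the same R², so an unrestricted threshold region straddles both mirrored
blobs and its centroid collapses onto the λi = λj diagonal.  Reading one
contour blob off the map is also what the reported λi > λj band pairs imply.
Among cells tied at the maximum, the seed with λi ≥ λj (NIR-over-green
orientation) is preferred, a deterministic tie-break.  The region's half
extent per axis is reported as the ± tolerance on the selected bands.

The final model is a full-data OLS fit of LCC on the VI at the band centres
nearest the centroid.  Band lookups throughout are nearest-centre (ties
toward the shorter wavelength) rather than interpolated, because reported
band choices in this field carry ± tolerances of the order of the band
spacing.

## Chlorophyll reference values

Analytical LCC comes from DMF-extract absorbances at 647 and 664 nm:

    LCC = (20.27·A647 + 7.04·A664) · V / (n_discs · A_disc)

with defaults V = 4 mL, two discs of 0.82 cm² (geometric factor ≈ 2.439).
The 20.27/7.04 coefficients are solvent-specific constants and not exposed as
knobs; the extraction geometry is.  The inverse map (used by the generator)
fixes the A647:A664 ratio (default 0.4) because the scalar forward map is
otherwise underdetermined; the ratio is a generator knob, not a biological
claim.

## Wavelength calibration

A pencil-lamp emission line is fitted with a Lorentzian
`offset + A·γ²/((λ−c)² + γ²)` by nonlinear least squares; the fitted FWHM
(2γ) estimates the spectral resolution and the centre standard error (from
the fit covariance) the calibration uncertainty.  A low-order polynomial
(default linear) maps detector pixels to nm given several known lines,
requiring strictly more lines than the polynomial degree and reporting
per-line residuals.

## The synthetic generator

No public leaf dataset accompanies this analysis, so the package ships a
generator reproducing the statistical structure the method assumes: default
n = 120 samples with LCC uniform over 4–23 µg·cm⁻² (a five-level
fertiliser-dose mode is available), a 351-band 450–800 nm axis, and additive
reflectance noise of sd 0.005 (~1% of the NIR plateau).  Spectra follow a
Beer–Lambert form on a logistic red-edge baseline,

    R(λ) = B(λ)·exp(−ε(λ)·LCC/ρ),
    B(λ) = 0.08 + 0.5·logistic((λ − 710)/12),
    ε(λ) = 1.0·G(λ; 450, 40) + 0.8·G(λ; 670, 30),

with Gaussian absorption wells at the blue and red chlorophyll bands and
ρ = 2.4 µg·cm⁻².  The strengths and ρ were chosen once so that the default
configuration shows the four canonical features of healthy-leaf spectra —
visible maximum between 500 and 600 nm, deep blue and red wells (the red well
saturating at high LCC), a steep red edge near 700 nm, and an LCC-insensitive
NIR plateau near 0.55 — at a Fig.-style dynamic range.  Chemistry tables are
derived by the inverse absorbance map with 1% multiplicative noise.  Tray
cubes place rectangular sample footprints on a grey (R = 0.15) background;
the background level keeps the default segmentation threshold more than ten
noise standard deviations away from the background ND distribution, so
planted footprints are recovered exactly.

**Truth metadata.**  Every dataset carries a truth block so recovery tests
never re-derive ground truth from the method's own output.  Defining the
"most informative pair" needs care: under the Beer–Lambert model every
two-band ND is tanh(α + β·LCC), and as β → 0 (adjacent bands in
flat-extinction regions) the *noiseless* in-sample R² tends to 1, so the
noiseless landscape is a degenerate continuum of near-ties and its argmax is
numerically arbitrary.  The truth block therefore stores the argmax of the
*noise-attenuated* population R²,

    score(λi, λj) = cov(v, y)² / ((var(v) + E[var_noise(v)]) · var(y)),

where v is the noiseless VI and the VI noise variance comes from first-order
propagation of the configured reflectance noise (with noise_sd = 0 this
reduces to the plain noiseless R²).  Because the attenuated landscape still
has a flat ridge along the NIR reference axis (the plateau carries no LCC
signal, so the score varies by < 1e-3 across 750–800 nm), the argmax alone is
not the quantity the analysis estimates; the truth block additionally stores
the population value of the selection functional itself — the top-region
centroid of the population landscape at the default delta, computed with the
same region rule.  Recovery tests compare centroid to centroid (the estimand)
and check that the argmax pair lies within the reported region half-width.

**What passing tests do not show.**  The generator has no biophysical
radiative-transfer realism (no PROSPECT-class leaf model), no sample-to-sample
structural variability in the NIR, no wavelength-dependent instrument noise,
no specular or shadow artefacts, and its VI–LCC relation is far cleaner
(CV R² ≈ 0.99) than real rice-leaf data (reported R² ≈ 0.78).  Recovery of
planted bands here demonstrates the correctness of the search/selection
machinery, not field-level accuracy of two-band chlorophyll models.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run the full 351-band grid once per
VI family at n = 120 (seconds with the vectorised search) and use a reduced
50-band axis for replicate studies (50 band-recovery replicates, 200
slope-coverage replicates); these sizes give Monte-Carlo errors comfortably
below the asserted margins.  Key tolerances: OLS vs normal-equations oracle
and SR-vs-CI grid equality at 1e-10; inverse-chlorophyll round-trip at 1e-12;
noiseless Lorentzian recovery at 1e-6; centroid moments exact (unit weights
sum to integers and small wavelength sums are exact in double precision).

## Known limitations

* The exhaustive search is O(b²) in bands and materialises an (n, b, b)
  tensor; at 351 bands and n = 120 this is ~120 MB, fine on a workstation but
  worth windowing for much finer axes.
* The final model is a simple bivariate linear calibration by design; no
  multivariate, penalised or interval-based (continuum-removal) methods are
  provided.
* Validation-fold R² uses the fold's own mean, so with very small folds
  (n/k ≲ 5) individual fold metrics are noisy and can be negative; the
  per-fold list is exposed for inspection.
* ENVI support is a deliberately small dialect (lowercase keys, required
  wavelength block, BSQ/BIL/BIP, little-endian by default) sufficient for
  cube exchange with mainstream tools, not a full ENVI implementation.
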