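# Methods

`qusmap` implements multi-parameter quantitative-ultrasound (QUS) envelope-statistics
imaging for characterizing tissue scatterer distribution patterns: three parametric maps
— homodyned-K log10(α), Nakagami-m, and horizontally normalized Shannon entropy (hNSE) —
are computed from raw RF frames by sliding-window estimation, fused per pixel by an
RBF-kernel SVM, and the resulting binary prediction is refined into a lesion mask that is
scored against a ground-truth mask. A built-in convolution speckle simulator generates
the phantoms that exercise the whole chain at desk scale.

## Speckle simulator

**Model.** Point scatterers are placed uniformly at random in a 2-D (lateral × axial)
field and rendered onto the RF sample grid by bilinear splatting; the frame is the
convolution of that impulse image with a separable point-spread function (PSF): axially a
Gaussian-enveloped cosine at the 7.5 MHz center frequency, laterally a Gaussian.
Attenuation, noise, aperture focusing and elevational beamforming are not modeled. The
PSF is calibrated directly to the target envelope FWHMs (0.7175 mm axial, 0.7194 mm
lateral) rather than derived from the 3.5-period excitation, so the resolution-cell
arithmetic (0.7175 × 0.7194 × 0.7194 ≈ 0.3713 mm³, elevational FWHM taken equal to
lateral in this 2-D setting) is reproduced exactly. Because splatting is linear, frames
are exactly linear in scatterer amplitudes.

**Densities.** Scatterer density is expressed per 2-D resolution cell (axial FWHM ×
lateral FWHM). The background population covers the whole field at its density; the
10-mm inclusion disk is topped up with (inclusion − background) extra scatterers per
cell, so the total density inside equals the nominal inclusion density and the per-area
ratio between regions equals the density ratio. Counts are Poisson, as uniform placement
implies.

**Scatterer amplitudes** default to standard normal draws (the convention of Field II
phantom scripts). This matters: random reflectivities divide the *effective* number of
scatterers per resolution cell by the amplitude kurtosis (a factor 3 for Gaussian
amplitudes), which is what puts a nominal 2 scatterers/cell background deep into the
pre-Rayleigh regime and gives the windowed m and log10(α) maps their inclusion contrast.
With `amplitude_distribution="unit"` the same densities produce nearly fully developed
speckle (envelope SNR → 1.91, m → 1 already at 10 scatterers/cell); that configuration
is kept for studying the ideal Rayleigh limit. A consequence of the default is that a
10 scatterers/cell field has frame-level m ≈ 0.8, i.e. slightly sub-Rayleigh.

**What the simulator does not emulate.** Real acquisitions (and full wave simulators)
add depth-dependent focusing, element-width clutter, attenuation and electronic noise.
Passing tests on these phantoms therefore demonstrate the statistical machinery —
estimator correctness, map construction, classifier training, detection scoring — not
robustness to those physical effects.

## Envelope statistics estimators

The envelope is the magnitude of the per-scan-line analytic signal (Hilbert transform
along the axial axis). All three estimators are scale-invariant at the feature level
(X/U/m directly; hNSE through the frame-level normalization).

### Homodyned-K via intensity log-moments (XU)

The homodyned-K law models the envelope A as a coherent amplitude ε plus diffuse scatter
whose power is modulated by a Gamma(α, 1) mixing variable w: conditionally on w the
intensity I = A² is noncentral-exponential with scale 2σ²w and noncentrality γ/w, where
γ = ε²/(2σ²); the mean intensity is μ = ε² + 2ασ², and the coherent-to-diffuse ratio is
k = ε/(σ√α). Estimation matches the sample statistics

    μ = mean(I),  X = mean(I ln I)/mean(I) − mean(ln I),  U = ln mean(I) − mean(ln I)

(natural logs; zero samples are excluded, erroring above a 1% fraction) against their
theoretical values X_HK(α, γ), U_HK(α, γ).

**Theory evaluation.** The conditional log-moments have closed forms in the noncentrality
λ — with Ein the complementary exponential integral and E₁ = exp1,

    E[ln W]   = Ein(λ) − γ_E,
    E[W ln W] = (1 + λ)(1 + ln λ + E₁(λ)) + 1 − λ − e^{−λ},

for the unit-scale noncentral-exponential W — so X_HK/U_HK reduce to a single outer
expectation over w ~ Gamma(α, 1), evaluated by 256-node generalized Gauss–Laguerre
quadrature. All logarithmically singular terms cancel analytically; the K-distribution
limit γ = 0 is returned in closed form, X = 1 + 1/α and U = γ_E + ln α − ψ(α). Worst-case
quadrature error (small α with small γ) is ~2·10⁻⁴ absolute, far below estimation noise;
elsewhere it is near machine precision. The theory is validated in the tests against an
independent adaptive-quadrature oracle at γ = 0 and a Monte-Carlo oracle off the axis.

**Lookup table and solve.** X/U are tabulated on a 200 (α, log-spaced 0.1–40.5) × 200
(γ, linear 0–20) grid, interpolated bilinearly in (ln α, γ). Per window the solve is the
constrained minimization of |U_HK − U|: for each α, the inner step picks γ(α) with
X_HK(α, γ) = X (X is strictly decreasing in γ, so this is a 1-D inversion on the table
row); the outer step scans the α grid, refines a bracketing sign change by bisection
(tolerance 10⁻³ on α), and otherwise — simulated data sit slightly off the HK manifold,
where the residual can keep one sign — refines the interior minimum of |U_HK − U| by
golden-section search. A pure endpoint fallback was rejected because it mis-assigns
pre-Rayleigh windows to α_max. Estimates saturating at the bracket ends (notably α_max =
40.5 for Rayleigh-like windows) are flagged `clamped`. σ² = μ/(2(α + γ)) and
ε = √(2σ²γ) then satisfy the mean-intensity identity exactly by construction. The map
feature is log10(α).

### Nakagami-m

The method-of-moments plug-in m = (mean I)² / popvar(I), Ω = mean I, with population
(divide-by-N) moments so the Rayleigh identity m = 1 holds exactly in expectation. On
small sliding windows the estimator is noisy and biased toward Rayleigh (a window spans
only ~10 independent speckle cells); that is a property of this classical estimator, not
of this implementation, and the classifier consumes the maps as-is.

### hNSE

Shannon entropy (base 2) of a 60-bin probability histogram of window values after
*frame-level* min–max normalization, so every window of a frame shares the fixed bin
limits [0, 1] ("horizontal" normalization); empty bins contribute 0 (0·log 0 := 0).
Results lie in [0, log₂ 60]. Because normalization is per frame, hNSE is sensitive to
local brightness relative to the frame — by design, this is the most contrast-rich of
the three features on dense inclusions. The per-window alternative normalization is
exposed only through calling `hnse_estimate` with window-level min/max.

## Parametric imaging

Window sides are physical squares of 4 / 3 / 1 pulse lengths (PL = 0.7 mm) for
log10(α) / m / hNSE, converted to samples per axis (109×18, 82×13, 27×4 on the default
grid) and slid with 50% overlap (stride = half the window, rounded half-up; first window
anchored at the frame corner; windows never cross the frame edge). Each window's value
sits at its center; rare estimator failures (< 5%, else abort) are in-filled from the
nearest valid window. The center grid is interpolated to the full frame size by a
bicubic spline with edge values held outside the center hull, and min–max normalized to
[0, 1] per frame per parameter. The whole map stage is deterministic given the frame.

## Classification and detection

Features are the three normalized map values at identical pixels, in the fixed order
[log10(α), m, hNSE]. Training draws 100 pixels per class per frame (uniform, without
replacement, anywhere inside each region); the pooled set is capped at 4,000 rows by a
seeded class-balanced subsample. The RBF-SVM's (C, γ) are grid-searched (C ∈
2^{−5,−1,3,7,11,15}, γ ∈ 2^{−15,−11,−7,−3,1}) with seeded stratified 10-fold
cross-validation, ties broken toward smaller C then smaller γ; CV fits are capped at
200k SMO iterations because the large-C/large-γ corners are slow without ever winning,
and the winner is refit on all rows. One classifier is trained per background-density
scenario (pooling phantom types that share a background), since the per-frame min-max normalization
makes features comparable within, but not across, backgrounds; a single pooled model is
a config option.

Prediction classifies every pixel (decision scores kept for ROC analysis). The SVM mask
is refined — holes filled (4-connected background), largest 8-connected component kept,
equal-area ties broken by scan order — and compared with three single-parameter
baselines: Otsu's threshold (256-bin histogram) on each normalized map, refined
identically.

## Evaluation

Pixelwise ACC/SEN/SPE use the raw (pre-refinement) prediction; AUC is the rank-statistic
area under the ROC of the decision scores. Detection quality uses the refined masks
resampled (nearest-neighbor) onto a square-pixel grid whose pixel equals the lateral
line pitch (0.15625 mm), so Hausdorff distances are isotropic pixel distances: area
detection accuracy ADA = (1 − |A_truth − A_detected|/A_truth)·100 % (absolute difference,
so over-detection cannot exceed 100%), Dice DS = 2TP/(2TP + FP + FN), and the standard
symmetric max–min Hausdorff distance over foreground pixels (the max–max variant,
which measures a set diameter, is available behind `max_max` for audit;
boundary-only distances behind `boundary_only`). An empty prediction scores the frame
diagonal as its Hausdorff distance.

## Phantom study

The default plan simulates five phantom types (background/inclusion scatterers per cell:
2/16, 2/24, 2/32, 10/32, 10/64), 30 frames each, 20 train / 10 test; the acceptance
script runs the three background-2 types. All randomness derives from one master seed
via `numpy` SeedSequence spawning (per-frame seeds from (seed, type, frame); feature,
subsample and fold seeds from fixed tags), making runs bit-reproducible across processes.
The HK lookup table is built once per run (~2 s) and shared; a full three-type study
takes ~6–7 minutes on one CPU, and the test suite exercises a 6-frames-per-type version
of the same study.

## Known limitations

- The simulator reproduces envelope statistics versus scatterer density, not the
  clutter, attenuation, or focusing physics of a real array; classification accuracy on
  its sparse backgrounds is bounded by heavy-tailed local statistics (scattered
  background false positives dominate the error budget at the 2/16 contrast).
- The moment-based Nakagami estimator and the 1-PL hNSE window are the published,
  deliberately simple choices; lower-variance estimators (e.g. Nakagami ML) are out of
  scope.
- Ex-vivo `.bin` acquisitions are supported as an input format only; no tissue data
  ships with the package.
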