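# Methods

This note records the models, conventions and design choices behind guvkit's
estimators, what the synthetic-data generator does and does not emulate, and
the problem sizes used in the validation benchmarks.

## Image model and quantification conventions

Rendered scenes are single equatorial confocal sections, two channels
(membrane dye, labeled protein), 16-bit when written to TIFF. The vesicle
membrane is a circle and the nanotube a straight segment leaving the vesicle
edge, both drawn with a Gaussian cross-section of σ = 0.7 px (an apparent
1–2 px line width), then blurred by an isotropic Gaussian PSF, corrupted
with additive Gaussian read noise, and offset by a constant background.
Poisson shot noise is deliberately omitted: the background-subtraction rules
downstream assume additive offsets, and the estimators only use peak-minus-
background differences, which additive noise models cleanly. There is no
confocal pinhole/Airy model, no 3-D stack, no membrane fluctuations and no
actin; pixel size is a free parameter (0.1 µm/px default) because it is
setup-specific.

Because the vesicle ring and the tube line share the same cross-section and
the same PSF, the tube/vesicle *peak ratio* in each channel survives
blurring almost unchanged; validation requires recovery of the generated
sorting ratio to ≤2% after a ≤1 px PSF with no noise, and within 10% at
realistic noise.

Quantification mirrors manual ROI workflows: ROIs are explicit endpoint
coordinates, profiles are width-averaged perpendicular cuts (bilinear
sampling for oblique ROIs, via `skimage.measure.profile_line`), and
background comes from the profile ends:

* rectangle rule — mean of first 15 and last 15 values, averaged; used
  where the two sides of the membrane have different backgrounds
  (encapsulated or injected protein);
* top rule — mean of the first 15 only (membrane channel of the same ROIs);
* line rule — pooled first 10 + last 10 (narrow perpendicular line ROIs).

"First/last" is taken in profile order, not image orientation, which makes
the rules orientation-independent for oblique ROIs. Signal is profile
maximum minus background. A signal is flagged below-detection when a
3-sample median-filtered peak exceeds background by less than 2× the robust
noise SD (1.4826 × MAD of the background segments). The median filter makes
the flag insensitive to single-pixel noise spikes while passing any real,
PSF-limited peak; the factor 2 operationalizes "too close to the noise
level" and is exposed as a parameter. Frame selection from a time series
(`select_in_focus_frame`) replaces manual in-focus selection by maximizing
the background-subtracted tube peak.

## Surface density

The calibration chain is linear throughout: a zero-intercept regression of
reference-dye density on vesicle intensity gives A ((molecules/µm²)/a.u.;
the zero intercept follows from n = A·I, a free-intercept variant exists for
diagnostics only); protein density is A·I/(brightness ratio · n*) and
surface fraction Φ = n·a_protein (a_ezrin ≈ 20 nm², a_I-BAR ≈ 50 nm²,
reference lipid area 0.7 nm²). Calibration intensities are treated as
reporting dye in **both** leaflets — the standard 1120–4480 molecules/µm²
reference range for 0.04–0.16 mole% dye carries no leaflet correction, and
we keep that convention. A is per-illumination-setting and is never
defaulted; each dataset must supply its own.

## Binding fits

Unweighted nonlinear least squares of Φ(C) = Φ_max·C/(C+K_d), bounded
(K_d ∈ [10⁻⁴, 10⁴] µM, Φ_max ∈ (0, 100]) and multi-started from three
log-spaced K_d values, keeping the lowest-SSR solution. Both fixed-Φ_max
(only K_d free) and joint fits are provided, since coverage data are often
reported against a stated saturation level. Weighting by replicate SD was
considered and left out of the default: the generator's multiplicative
noise keeps the unweighted estimator's median bias well under the 10%
validation tolerance at CV = 10%. At least three concentrations are
required; degenerate designs raise.

## Tube radii and sorting

The three radius routes — √(κ/2σ), f/(4πσ), R_c·ratio — are exact algebraic
inverses of each other on self-consistent inputs and are tested as such.
R_c is refit by zero-intercept least squares of force-route radii on
membrane fluorescence ratios, with the slope SD from residuals. For the
inward-tubulation assay, where no lipid calibration exists, radii are
reported as the membrane ratio itself; an opt-in anchor conversion
(ratio 0.3 ↔ ~20 nm, 0.4 ↔ ~30 nm, affine through origin) is provided and
clearly labeled qualitative. The S = 0 below-detection convention is
delegated to the image-quantification flag above. Coverage binning defaults
to [0, 2), [2, 5), [5, ∞) percent — the conventional low/intermediate/high
coverage classes — and dispersion summaries exclude S = 0 values, which are
tallied separately.

## Tethering energetics

γ = σ(1 − cosθ) from the contact force balance; θ is an upstream input. A
helper fits a least-squares (Kasa) circle to clicked test-vesicle contour
points and takes cosθ = d/R with d the center-to-contact-chord distance —
chosen because the deformed vesicle is spherical away from the contact and
the angle at the contact line is then exactly arccos(d/R). Per-bond energy
divides γ by the bond density (half the monomer density for dimeric
tethers, the streptavidin density for biotin–streptavidin), with kBT =
4.11×10⁻²¹ J (25 °C). All zone protein is assumed load-bearing by default;
an efficiency factor ≤ 1 is exposed for sensitivity analyses. Zone protein
quantification uses the mean over the zone ROI (the peak is an alternative
the API leaves to the caller, since intensities enter as inputs).

## FRAP

Correction and normalization: out(t) = (bleached/reference) ·
(reference_prebleach/prebleach), which cancels any per-frame multiplicative
acquisition factor shared by the two regions exactly — the order
(correct, then normalize) is the natural reading of reference-based
correction followed by pre-bleach normalization; with a shared
multiplicative bleach factor the alternative orderings coincide. Recovery
is fit as y(t) = y₀ + M(1 − e^(−t/τ)) with mobile fraction M/(1 − y₀)
clipped to [0, 1]; the single exponential is the minimal model with a
plateau equal to the mobile fraction, and τ is a nuisance parameter. Traces
are fitted one at a time (no curve averaging across vesicles); a pooling
summary aggregates per-trace estimates.

## Contingency statistics

Per-class two-group comparisons use the pooled two-proportion z-test
without continuity correction, reported as χ² = z² on 1 df. The
uncorrected form is the fixed dialect of this test: applied to the
reference nanotube counts (15/60 vs 26/62 isolated; 4/60 vs 36/62 stacked)
it reproduces p = 0.0477 and p ≈ 1.5×10⁻⁹, while the Yates-corrected
variant does not. Under a simulated null its empirical type-I error at
α = 0.05 is within 0.05 ± 0.01 (10⁴ multinomial draws). The bundled
reference table's first-group stacked count (4) is reconstructed from
printed percentages (60 − 41 − 15) and flagged as inferred.

## Synthetic-data scope

The generator reproduces the *structure* of the real data — ring+line
geometry with per-channel intensity ratios, hyperbolic titrations with
multiplicative noise, shared-bleach FRAP traces, force-balance-consistent
tether geometries, multinomial class counts — under known ground truth.
Passing recovery tests therefore demonstrates that the estimators are
correct and unbiased under the stated noise models; they do not certify
performance against optical artifacts absent from the model (defocus,
flat-field error, bleed-through, membrane fluctuations, shot noise).

## Validation problem sizes

Chosen as the package's standard benchmarks: binding — 500 replicate
titrations, 8 log-spaced concentrations (0.02–4 µM, extended to 12 µM for
the low-affinity case), 10% CV noise, median K̂_d within 10%; FRAP — 200
traces, 60 frames at 0.5 s, τ = 5 s, 0.5% per-frame bleaching, 2% noise,
median mobile fraction within ±0.02 of 0.10; radius calibration — 100
replicate refits of 50 pairs (ratios uniform 0.05–0.5, 10% radius noise),
median slope within ±10 nm (R_c = 200) and ±15 nm (R_c = 312). Seeds derive
from a single integer per run.

## Known limitations

2-D scenes only; no automated vesicle/tube segmentation or drift
correction; no cooperative (Hill) or kinetic binding models; no
diffusion-equation FRAP (spot-size effects are absorbed into τ); no
Helfrich-fluctuation corrections to the tethering balance; the anchor-based
radius conversion for inward tubules is qualitative by construction.
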