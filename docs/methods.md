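# Methods

This note documents the models, parameter choices, numerical decisions, and
known limitations behind `flimspec`, in the order the pipeline runs.

## Frequency-domain lifetime model

Under excitation intensity-modulated at `f_mod` (default 10 MHz), a
mono-exponential fluorophore of lifetime τ emits with phase lag
φ = atan(ωτ) and modulation depth m = (1 + (ωτ)²)^(−1/2), ω = 2π·f_mod.
Its demodulated signal is the phasor m·e^{iφ}. A mixture of fluorophores
adds phasors weighted by steady-state intensity fractions; the measured
phase lifetime τ_app = tan(arg z)/ω of a two-component
autofluorescence + PpIX mixture therefore lies strictly between the
component lifetimes and increases strictly with the PpIX fraction α
whenever τ_auto < τ_PpIX. The defaults τ_PpIX = 16.4 ns (PpIX in solution)
and τ_auto = 1.6 ns (brain parenchyma autofluorescence in the > 580 nm
band) set the dynamic range of everything downstream.

Reconstruction inverts the relation per pixel: τ = tan(Θ − Θ₀)/(2π f_mod).
The system offset Θ₀ (time of flight plus electronic delays) is estimated
from a reference sample of known mono-exponential lifetime as the **median**
over reference pixels of the measured phase minus atan(ω τ_ref); the median
was chosen for robustness since the estimator is otherwise unspecified in
this measurement convention. Corrected phases outside [0, π/2) have no
mono-exponential interpretation and become NaN with a false validity mask —
they are *not* clamped, because clamping would bias group medians. No
intensity threshold is applied at reconstruction; low-signal masking is a
downstream, configurable concern.

## Synthetic phantoms and what they do (not) emulate

The generator renders region-labelled scenes into demodulated frames using
the forward phasor model. Noise is applied in the in-phase/quadrature
plane — Gaussian on both quadratures with
sd = sqrt(amplitude_sd² + jitter_scale²·R) — which reproduces the
amplitude-dependent phase jitter of lock-in detection
(phase sd ≈ jitter_scale/√R). Defaults (jitter_scale 0.05 rad·√mV, amplitude
sd 0.5 mV at 100 mV signal) correspond to per-pixel phase noise of a few
milliradians, i.e. a well-behaved bright acquisition.

Emission spectra are a linear autofluorescence baseline plus a PpIX shape:
Gaussians at 635 nm (σ = 10 nm) and 705 nm (σ = 12 nm, 30 % relative
height), multiplied by a smooth cosine taper that is identically zero inside
the baseline anchor windows (600–610, 720–730 nm). The taper is what makes
the noiseless RSC round trip exact: with zero anchor leakage the dual-window
OLS baseline recovers the true line, so the peak height
h = r·B(635)/(1 − r) realizes any target RSC r < 1 exactly (r = 1 uses a
zero baseline). Real PpIX spectra have finite tails into the anchor windows
and photoproduct/porphyrin side bands; the generator deliberately idealizes
these away, so passing round-trip tests validate the decomposition
machinery, not instrument spectra.

The frame mixture fraction α is defined over the full 590–740 nm detection
band, while RSC is the PpIX fraction at the 635 nm peak only. Both are
computed from the same component shapes (`alpha_to_rsc`/`rsc_to_alpha`), and
since the PpIX peak is narrower than the band, RSC > α at intermediate
values — the deliberate distinction that produces realistic scatter between
the two metrics.

Cohorts draw specimen-level *apparent* lifetimes from per-group log-normal
distributions (lifetimes are positive and right-skewed across specimens) and
invert the strictly monotone α → τ_app map (Brent root-finding, xtol 1e−14)
to obtain each specimen's PpIX fraction; draws at or below τ_auto are
represented as pure autofluorescence with that lifetime. Frames are uniform
per specimen — real specimens are spatially heterogeneous, so cohort tests
validate the statistical machinery, not spatial morphology. The demo cohort
(3 CTL at 1.6 ns, 3 LGG-INF at 4.1 ns, 3 HGG-TUM at 13 ns, 3 MNG-TUM at
12.2 ns, 64×64 frames) keeps the full pipeline in seconds; the group medians
echo the reported clinical group structure at desk scale.

## Spectral decomposition

Preprocessing subtracts a dark spectrum or constant, clips at zero, and
Gaussian-smooths along wavelength (default σ = 2 nm, configurable; the
instrument's filter width is not specified anywhere, so this is a package
default). Smoothing runs **before** baseline fitting. Note that smoothing
broadens the 635 nm peak (≈ 2 % height loss at σ = 2 nm), so exact RSC
round-trip statements apply to the unsmoothed decomposition; with Poisson
noise at 10⁴ peak counts the full pipeline recovers RSC to well within
±0.02 on average.

RSC is evaluated at the single 635 nm point (linear interpolation between
grid points). A band-integrated variant (±half-width around the peak) exists
behind `band_halfwidth_nm` for sensitivity analysis only. Counts below the
baseline at the peak clip S_PpIX to zero so RSC stays in [0, 1]; RSC is
defined as 0 when both contributions vanish.

## Lifetime–RSC polynomial and its bands

The degree-5 fit uses `numpy.polynomial.Polynomial.fit`, which fits on a
shifted/scaled domain for conditioning (a raw degree-5 Vandermonde on [0, 1]
is ill-conditioned) and converts back to monomial coefficients.
σ̂ = √(RSS/DOF) with DOF = n − 6.

Two leverage variants back the 95 % bands. The default (`"pooled"`) is the
conventional straight-line form √(1/n + (x₀−x̄)²/Σ(xᵢ−x̄)²) used by this
analysis tradition. For a degree-5 model this understates the mean-response
variance: the exact hat-matrix leverage x₀ᵀ(XᵀX)⁻¹x₀ (`"exact"`) is never
smaller, and simulation shows the pooled CI covers the true mean response
only ~70–90 % of the time for quintic fits, while the exact CI is nominal.
The prediction interval is nearly unaffected because its leading `1 +` term
dominates the leverage; the pooled PI stays within a percent of nominal
coverage. The package therefore reports the pooled formulas as the faithful
default and documents `leverage="exact"` as the calibrated option; the
coverage acceptance test uses the exact CI and the pooled PI.

Regime thresholds default to 0.25 and 0.85 with boundary values assigned to
the upper regime (the published ranges are approximate, "about" values).
Observations are pooled unweighted across specimens; a per-specimen
weighting hook exists but defaults off, matching the pooled-points analysis.

## Cohort statistics

Pixel subsampling is uniform without replacement among valid (non-NaN)
pixels, with the per-specimen count defaulting to the smallest specimen's
valid-pixel count so every specimen contributes equally (overridable to a
fixed number). Quantiles use linear interpolation; SD is the sample SD.

"Data normalization" before the KS shape check is implemented as median/IQR
standardization — a robust location-scale removal so the two-sample KS
compares shapes only (a z-score variant is available by config). The choice
is an assumption and is flagged in the output. Note the check is
conservative: standardizing each sample by its own estimated median/IQR
removes part of the sampling variability the KS null assumes, so false-flag
rates run below the nominal α.

The Mann–Whitney U test is one-sided (greater vs control), using the exact
null distribution for n ≤ 25 per group without ties and the tie-corrected
normal approximation otherwise. No multiple-testing correction is applied
(each subgroup is tested against control at the stated α); a Holm option is
out of scope. Stars follow * < 0.05, ** < 0.01, *** < 0.005.

## Visualization

Lifetime colorization scales the jet map with the binary logarithm between
fixed limits 1–16 ns, so parenchyma is blue, strong PpIX red, and
intermediate lifetimes resolve into turquoise–orange shades; NaN pixels take
a configurable sentinel color. Intensity renders as grayscale scaled from 0
to the per-image maximum.

Blending follows the exact published step order: RGB→HSL on both images,
hue/saturation from the lifetime image with the structure image's lightness,
HSL→RGB→YPbPr, keep Pb/Pr, replace Y with the structure image's Y, back to
RGB. The luma/chroma matrix is fixed to BT.601 (the YPbPr primaries are
otherwise unspecified); HSL is the standard hexagonal model, and the
luminance replacement happens in YPbPr, not HSL. Lifetime maps are upsampled
nearest-neighbor by default (no interpolated pseudo-lifetimes; bilinear
optional). Out-of-gamut pixels after the final conversion are clipped, which
necessarily shifts their luminance — luminance preservation to ≤ 1/255 holds
exactly on the in-gamut mask, which `blend_lifetime_on_intensity` can
return.

SSIM uses the standard windowed form: 11×11 Gaussian window (σ = 1.5),
K1 = 0.01, K2 = 0.03, dynamic range 1.0, population covariances, mean over
windows; RGB inputs are reduced to BT.601 luminance first. SSIM(A, A) is
exactly 1.0.

## Pipeline

A single seed fans out to per-stage child seeds through
`numpy.random.SeedSequence`, making runs fully deterministic (byte-identical
tabular outputs) while keeping stages independently re-runnable. Each stage
failure aborts with a stage-tagged error; the run manifest records version,
seed, config hash, per-stage counts, and artifact paths, and
`validate_manifest` re-checks every artifact's existence and format.

## Problem sizes

Simulation-based checks use: 256×256 frames for reconstruction fidelity;
2,000 refits of n = 331 points for CI/PI coverage at five x₀ values;
10,000 (suite) / 5,000 (acceptance script) null replicates of n = 100 for
Mann–Whitney calibration; 200 replicates of n = 5,000 per group for the KS
false-flag rate; 100 Poisson replicates per RSC target; and an 11-specimen
cohort on 64×64 frames for parameter recovery. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands.

## Known limitations

- Phase-lifetime only: no modulation-depth or multi-harmonic estimation,
  and no phasor-plot (g, s) analysis beyond the forward model.
- The generator does not simulate optics (NA, working distance),
  photobleaching, photoproducts, or absolute PpIX concentrations with
  optical-property correction; RSC is a raw-signal metric by design.
- Specimen-level spatial heterogeneity and specimen-correlation structure
  are not modelled (no mixed-effects alternative to the subsampling scheme).
- The spectrometer wavelength grid defaults to 1 nm spacing over 590–740 nm;
  this is a configurable default, not an instrument claim.
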