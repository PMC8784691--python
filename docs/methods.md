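# Methods

This note documents the models, the synthetic-data generators, the numerical
choices behind every stage, and what the tests do and do not establish.

## Pressure waveforms and hemodynamic indices

The waveform generator builds each beat from four phases: a raised-cosine
systolic upstroke from EDP to P_max (zero slope at onset, so the maximum
second derivative of the beat sits exactly at the end-diastolic point), an
exponential decay P_max·exp(−t/τ) truncated at P_min (exactly log-linear with
slope −1/τ, which is the property the τ estimator relies on), a smoothstep
diastasis ramp from P_min back to EDP, and an EDP plateau.  The upstroke
occupies 18% of the beat period and the plateau 5%; both are shape choices
only — the analysis never assumes them.  Noise is additive Gaussian,
independent per sample, with an explicit seed; generators never touch global
random state.  Default settings (heart rate 292.3 bpm, P_max 23.0 mmHg, EDP
1.3 mmHg, τ 9.9 ms) describe a healthy young control rat; the demo's second
cohort uses aged-animal values (271.5 bpm, 26.8 mmHg, 1.9 mmHg, 10.7 ms).

Analysis choices, all package defaults because the underlying measurement
conventions vary between labs:

* Derivatives come from Savitzky–Golay smoothing (window 11 samples, order 3)
  before differencing; raw second differences of catheter noise are unusable.
* Systolic peaks: local maxima with prominence ≥ 25% of trace amplitude,
  earliest sample on ties.  Heart rate = 60 / mean peak-to-peak interval.
* EDP: within the window from the pressure minimum to the next (dP/dt)_max,
  the EDP sample is the *leading half-maximum crossing* of d²P/dt², not its
  argmax — smoothing spreads the curvature burst a few samples into the rising
  limb, and the onset marks end-diastole with much less upstroke bias.  A beat
  whose curvature never exceeds the numerical-noise floor
  (10⁻⁷·amplitude/dt²) is flagged degenerate rather than given a value.
* τ: OLS of ln P vs t from the time of (dP/dt)_min to the pressure-minimum
  time, located as the first nonnegative crossing of the smoothed dP/dt and
  stepped back by the smoothing half-window so the fitted segment stays inside
  the decay limb.  A raw argmin of noisy pressure would frequently land deep
  in the flat diastasis and bias τ upward severely.  Natural logarithm of
  absolute pressure; no pressure-offset (Glantz-type) variant is implemented.
  Pressures ≤ 0 in the fit window and non-decaying segments raise distinct
  errors.
* Multi-beat summaries average ≥ 3 consecutive peak-to-peak windows; τ is
  reported from the first complete beat only.

With the defaults, noiseless τ recovery is exact to machine precision for
τ ∈ {5, 10, 20, 40} ms, and with 0.2 mmHg noise the median error over 100
seeds is ≈ 1%.

## Biaxial kinematics

Markers are ordered counterclockwise from the lower-left and validated
(positive area, simple quadrilateral); misordered input is rejected, never
silently reordered.  F is evaluated at the bilinear element center (ξ=η=0),
the standard one-point rule; any affine marker motion is therefore recovered
exactly, and rigid rotations leave E unchanged to machine precision.  The rig
has no shear channels, so P₁₂ = P₂₁ = 0 by construction, and the generator
moves markers by pure stretch, matching a suture/pulley mount.  Forces in N
and dimensions in mm give stresses in kPa.

The synthetic experiment applies the circ:long protocol ratio to the *stretch
increments* (λ−1), which is what a displacement-controlled rig prescribes;
strain ratios then differ slightly from displacement ratios at finite strain.
The dominant axis always reaches the configured `max_strain` (default 0.15
Green–Lagrange; per-protocol maxima are a free configuration, not a measured
value).

## EFE decomposition and recruitment

The scattered-data interpolant is a thin-plate spline (`RBFInterpolator`,
no smoothing) — the 2-D biharmonic Green's-function interpolant — fitted to
the pooled protocol samples after averaging duplicated strain points (every
protocol shares the origin).  The equibiaxial grid uses ΔE = 0.0025 and is
truncated, with a warning, where the diagonal leaves the convex hull of the
data; recruitment strains are therefore resolved to ± ΔE.

The recruitment scan starts at n = 5 points: the running standard deviation
needs a history, and the scan start is a package default.  The threshold uses
the *sample standard deviation* of the stiffness history (n−1 denominator),
exactly as the inequality is defined, not the standard error of its mean.  A
standard-deviation floor of 10⁻¹² kPa prevents self-triggering on numerically
flat noiseless curves, whose stiffness fluctuations are pure float rounding.
"No recruitment" is a regular outcome (None), not an error.  The
pre-recruitment slope is the OLS slope of S_EFE vs E over the points before
the detected index; on convex (exponentially stiffening) baselines it
slightly exceeds the tangent stiffness at the origin.

φ_myofiber defaults to the cohort-mean myofiber area fraction from the
histology stage; specimen-specific fractions are accepted when available.

## Fung model and fitting

W = B₀(exp(½b₁E₁₁²) + exp(½b₂E₂₂²) + exp(b₃E₁₁E₂₂) − 3), stresses by exact
differentiation (verified against finite differences of W at 10⁻⁶ relative
tolerance).  Exponent arguments above 500 raise an overflow error naming the
offending strain.  Fitting: trust-region-reflective least squares, both
stress channels weighted equally, eight starting points on a log-spaced
lattice (B₀ ∈ {0.1, 1, 10} × b ∈ {1, 10}, plus two mid-range points), best
loss wins; tolerances 10⁻¹⁴.  Bounds: B₀ ∈ (10⁻⁴, 10³) kPa,
b₁, b₂ ∈ (10⁻³, 10²), b₃ ∈ (−10², 10²); a negative coupling coefficient is
legal and flagged in the output.  R² is pooled over both channels; standard
errors come from the Gauss–Newton covariance.  W-convexity is not asserted
anywhere — the form does not guarantee it for all parameters; only W(0,0)=0
and W ≥ 0 on the fitted strain domain are relied on.

Strain-energy maps average per-specimen W surfaces pointwise on a common
grid; the low-strain window defaults to E ∈ [0, 0.07]² and the high-strain
window to [0.07, 0.15]² (both configurable; the split is a package default).

Recovery behavior: on noiseless seven-protocol data the fit returns the
generating parameters to better than 1% with R² > 0.9999 across random
ground truths (B₀ ∈ [0.5, 5], b ∈ [1, 25]); with 5% multiplicative stress
noise the median per-parameter error over 20 seeds is ≈ 8–9%.

**Known limitation.**  When the generated tissue includes the piecewise
collagen-recruitment term, the smooth exponential cannot represent the
stiffness kink; the optimizer compensates with a small B₀ and a large b₁,
which can saturate the b₁ = 100 bound while R² stays near 0.95–0.99.  This is
honest model/data mismatch, not an optimizer failure — fits to pure-Fung data
recover interior parameters precisely.

## Synthetic recruitment ground truth

Two generators carry a known recruitment strain.  `gen_efe_curve` builds an
exactly bilinear EFE stress with a slope break at the prescribed strain and
optional Gaussian noise on the stiffness channel; it is the clean test bed
for the detector (≥ 97/100 detections within one grid step at stiffness noise
of 2% of the pre-slope, slope ratios 3–30).  `gen_biaxial_experiment`
optionally adds a linear collagen stress k·(E−E*)₊ per axis on top of the
Fung baseline, so the recruitment signature survives the entire
marker → force → interpolation → detection chain; k defaults to a few times
the pre-recruitment EFE slope so detection is unambiguous.

## Histology

The generator draws two-phase sinusoidal stripe textures (wavelength 8 px,
large enough for stable gradients at the default Gaussian window), assigns
the collagen color to exactly the prescribed pixel fraction by rank
thresholding (so the collagen phase forms stripes at the section angle), and
optionally perturbs RGB values with Gaussian noise.  `coherency_target`
blends the stripe field with spatial white noise; the mapping from target to
measured coherency is monotone but deliberately uncalibrated — tests assert
the extremes (aligned > 90%, isotropic < 10%), not intermediate values.  What
the generator does *not* emulate: stain variability, blur, tissue tears,
cardiomyocyte morphology; passing tests demonstrate correct geometry and
estimator math, not robustness to real staining artifacts.

Segmentation uses inclusive RGB boxes (collagen: blue-dominant, myofiber:
red-dominant; boxes must be disjoint).  The structure tensor integrates
Gaussian-windowed gradient products (window σ = 4 px; derivatives by central
differences after Gaussian pre-smoothing at σ/2) over the section interior,
one tensor per section.  Because gradient energy concentrates perpendicular
to fibers, the fiber angle is taken from the *smaller*-eigenvalue
eigenvector — equivalently the dominant-gradient direction rotated by 90° —
and mapped to the tissue convention (0° circumferential, +90° longitudinal,
axial range (−90°, 90°]).  A formulation that reads the first eigenvector as
the fiber direction would be systematically perpendicular under this
gradient-based construction.  Orientation error on clean stripes is ≤ 1.4°
across test angles; residual bias at oblique angles comes from square-pixel
discretization of the binarized phases.

Transmural profiles normalize depth between the shallowest and deepest
section, interpolate linearly onto a 21-point grid, and interpolate/average
orientations in doubled-angle space (axial data; +80° to −80° correctly
crosses ±90°).  Regional summaries: Epi ≤ 20%, Mid (20, 80)%, Endo ≥ 80%.

## Statistics

All orientation statistics double the angles first (axial data), including
inside the Watson–Williams test; whether to double is the one genuinely open
convention for undirected fibers, and doubling is the defensible choice.  The
Watson–Williams F uses the standard concentration correction 1 + 3/(8κ̂) with
κ̂ from the usual piecewise ML approximation; a warning is issued when
κ̂ < 1.  Scalar comparisons: Shapiro–Wilk on both groups and Bartlett's test
gate a two-sided unpaired t-test versus Mann–Whitney; the chosen path is
recorded.  α = 0.05, no multiple-testing correction.  Percent changes round
half away from zero for display.

## Pipeline and reproducibility

Per-specimen seeds derive from the root seed through `SeedSequence` spawning
keyed by a CRC of the cohort name, so adding a cohort never shifts another
cohort's draws.  The manifest materializes every default; reruns with the
same config and seed are byte-identical (no timestamps are written).  Cohort
summaries report means ± SEM, percent change (or axial shift in degrees for
orientations), and the selected test's p-value.

Problem sizes used by the test suite and the acceptance script — 7 protocols
× 40 points for fitting, 100-trial detection and τ ensembles, 192-px section
images, 2-cohort × 3-specimen demo runs — were chosen as the smallest
ensembles at which the recovery statistics are stable; all are configurable
upward.

## Known limitations

* The EFE/recruitment machinery assumes pure biaxial loading (no shear
  channel); shear-coupled rigs need an extended stress reconstruction.
* The τ fit uses absolute pressures; baseline-corrected variants are not
  implemented.
* EDP under heavy noise inherits the variance of second-derivative
  localization; beat averaging mitigates but does not remove it.
* The Fung b₁ bound can saturate on strongly recruiting tissue (above).
* Coherency targets between the extremes are qualitative.
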