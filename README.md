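# rvbiomech

Multi-scale analysis of right-ventricular (RV) biomechanics for small-animal
studies that combine terminal pressure catheterization, planar biaxial testing
of the RV free wall (RVFW), and transmural trichrome histology.  The package
is aimed at cardiovascular biomechanics labs that want the full post-processing
chain — waveform indices, finite-strain stress analysis, fiber-ensemble
decomposition, constitutive fitting, and fiber-architecture quantification —
as tested, scriptable Python, together with synthetic-data generators that
forward-simulate every input type from known ground truth so each stage can be
validated by parameter recovery.

## What it computes

**Hemodynamics** (`rvbiomech.hemodynamics`).  From a sampled RV pressure trace:
heart rate from waveform periodicity, peak pressure P_max, end-diastolic
pressure (pressure at the maximum second time-derivative in the
diastole-to-upstroke window), dP/dt extrema, the contractility index
(dP/dt)_max / P_max, and the relaxation time constant τ from an OLS fit of

    ln P(t) = −t/τ + B

over the segment from (dP/dt)_min to the pressure minimum.

**Kinematics** (`rvbiomech.kinematics`).  Four epicardial markers define a
bilinear finite element; the deformation gradient **F** is evaluated at the
element center, the Green–Lagrange strain is **E** = (FᵀF − I)/2, the 1st
Piola–Kirchhoff stress comes from axial forces over reference cross-sections
(P₁₁ = f_circ /(L_long·t)), and the 2nd Piola–Kirchhoff stress is
**S** = F⁻¹**P** under plane stress.  x = circumferential, y = longitudinal
(apex-to-base).

**Effective fiber ensemble** (`rvbiomech.fiber_ensemble`).  Thin-plate-spline
surfaces S₁₁(E₁₁,E₂₂), S₂₂(E₁₁,E₂₂) fitted to the multi-protocol data are
evaluated along the equibiaxial path E₁₁ = E₂₂ = E to form the EFE stress
S_EFE = S₁₁ + S₂₂ and stiffness TM_EFE = dS_EFE/dE.  Collagen recruitment is
the first grid point where

    TM_EFE(n+1) > mean(TM_EFE(1..n)) + 4.417 · sd(TM_EFE(1..n)),

with Z = 4.417 the 99.999% two-sided normal quantile.  The pre-recruitment
slope divided by the myofiber area fraction (rule of mixtures with zero
pre-recruitment collagen stiffness) gives the effective myofiber stiffness
TM_myofiber = (TM_EFE)_before / φ_myofiber.

**Constitutive model** (`rvbiomech.constitutive`).  Fung-type anisotropic
strain energy

    W = B₀ (exp(½b₁E₁₁²) + exp(½b₂E₂₂²) + exp(b₃E₁₁E₂₂) − 3),

whose strain gradients give the model stresses.  `FungModel(...).fit()` runs
trust-region-reflective least squares from eight starting points and returns a
`FungResults` with estimates, approximate standard errors, pooled R², and a
`summary()` table; `strain_energy_map` averages per-specimen energy surfaces
into cohort maps on low-strain and high-strain windows.

**Histology** (`rvbiomech.histology`).  RGB-range segmentation of trichrome
sections (collagen blue, myofiber red/pink), area fractions within an ROI, and
fiber orientation/coherency from the Gaussian-windowed structure tensor of the
image gradients; coherency is 100·(λ₁−λ₂)/(λ₁+λ₂).  Per-section metrics are
interpolated onto a normalized-thickness grid (21 points, 0% epicardium to
100% endocardium) with epicardial (0–20%), mid-wall (20–80%) and endocardial
(80–100%) summaries; all angle handling is axial (doubled-angle space).

**Statistics** (`rvbiomech.stats`).  Axial circular means and the
Watson–Williams test on doubled angles; scalar comparisons via
Shapiro–Wilk/Bartlett-gated t-test or Mann–Whitney; percent-change reporting.

**Pipeline** (`rvbiomech.pipeline`, `rvbiomech` CLI).  A single YAML config
describes two synthetic cohorts; `run_pipeline` generates the data, runs every
stage, and writes per-cohort tables, a comparison summary (means ± SEM,
percent change, p-values) and a manifest that reproduces the run
byte-for-byte.

## Worked example

```python
import warnings
from rvbiomech import synthetic as syn, kinematics as kin
from rvbiomech import fiber_ensemble as fe, constitutive as con, hemodynamics as hemo

# catheter trace: control-like settings, 0.1 mmHg noise
w = syn.gen_pressure_waveform(syn.WaveformSpec(
    heart_rate=292.3, p_max=23.0, edp=1.3, tau=9.9, noise_sd=0.1, seed=42))
s = hemo.summarize_hemodynamics(w)
print(f"HR {s.heart_rate:.1f} | Pmax {s.p_max:.1f} | EDP {s.edp:.2f} | "
      f"dP/dt max {s.dpdt_max:.0f} | CI {s.contractility_index:.1f} | tau {s.tau:.2f} ms")

# biaxial test: Fung baseline + collagen recruitment at E = 0.104
mat = syn.MaterialSpec(B0=0.8, b1=25, b2=15, b3=5,
                       recruitment_strain=0.104, collagen_stiffness=100.0,
                       phi_myofiber=0.953)
tables = [kin.analyze_record(r)
          for r in syn.gen_biaxial_experiment(mat, noise_sd=0.05, seed=42)]
print(con.fit_fung(tables).summary())
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    curve = fe.efe_curve(fe.interpolate_equibiaxial(tables))
rec = fe.detect_recruitment(curve)
ms = fe.myofiber_stiffness(rec, mat.phi_myofiber)
print(f"recruitment strain {100*rec.recruitment_strain:.1f}% | "
      f"myofiber stiffness {ms.TM_myofiber:.1f} kPa")
```

prints

```
HR 292.3 | Pmax 23.1 | EDP 0.96 | dP/dt max 982 | CI 42.5 | tau 9.89 ms
Fung anisotropic model fit
============================================
parameter         estimate       std err
--------------------------------------------
B0 (kPa)           0.18106       0.00815
b1                     100          2.35
b2                   85.38          2.17
b3                  15.648          1.57
--------------------------------------------
n obs (per channel): 280
pooled R^2: 0.97142
converged starts: 8
recruitment strain 10.2% | myofiber stiffness 45.8 kPa
```

τ comes back within 0.1% of the 9.9 ms ground truth; the recruitment strain
is recovered to one grid step (0.25% strain) of the prescribed 10.4%, and the
myofiber stiffness is the pre-recruitment EFE slope divided by φ = 0.953.  The
Fung R² of 0.97 reflects the deliberate model/data mismatch: the generated
tissue contains a piecewise collagen term that the smooth exponential can only
approximate (the b₁ estimate saturating its bound is part of that mismatch;
see `docs/methods.md`).

A two-cohort end-to-end run:

```bash
rvbiomech demo-config demo.yaml --seed 1
rvbiomech run demo.yaml -o out/        # tables, summary.csv, manifest.json
```

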