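"""Forward simulation of the three experimental data types.

Every generator is deterministic given its seed and records its ground
truth, so each downstream analysis stage has a parameter-recovery test
surface:

* ``gen_pressure_waveform`` — catheter-style RV pressure traces whose
  diastolic limb decays exactly exponentially (log-linear with slope
  -1/tau), with a raised-cosine systolic upstroke and an end-diastolic
  plateau at the prescribed EDP.
* ``gen_biaxial_experiment`` — marker tracks and force channels for the
  seven displacement-controlled protocol ratios (1:1, 1:2, 2:1, 1:4,
  4:1, 1:6, 6:1), forward-computed from a Fung material under pure
  biaxial stretch (no shear), consistent with the kinematics module's
  conventions.
* ``gen_histology_stack`` — two-phase (collagen/myofiber) striped RGB
  sections with prescribed per-depth fiber orientation, coherency and
  collagen area fraction.
* ``gen_efe_curve`` — piecewise-linear effective fiber-ensemble curves
  with a known recruitment strain, for the recruitment detector.

Default waveform parameters follow the control-cohort means of healthy
young rats (heart rate ~292 bpm, peak pressure 23 mmHg, EDP 1.3 mmHg,
tau ~9.9 ms).  Noise is additive Gaussian, independent per sample;
seeds are explicit inputs, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constitutive import fung_stress
from .exceptions import ValidationError
from .fiber_ensemble import EFECurve, GRID_STEP_DEFAULT
from .hemodynamics import PressureWaveform
from .kinematics import BiaxialRecord, MarkerFrame

__all__ = [
    "WaveformSpec",
    "MaterialSpec",
    "ProtocolSet",
    "HistologySpec",
    "SectionImage",
    "HistologyStack",
    "gen_pressure_waveform",
    "gen_biaxial_experiment",
    "gen_histology_stack",
    "gen_efe_curve",
    "STANDARD_RATIOS",
]

#: the seven displacement-controlled circ:long protocol ratios
STANDARD_RATIOS: tuple[tuple[float, float], ...] = (
    (1, 1), (1, 2), (2, 1), (1, 4), (4, 1), (1, 6), (6, 1),
)


# --------------------------------------------------------------------------
# pressure waveforms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformSpec:
    """Ground truth for one synthetic RV pressure recording."""

    heart_rate: float = 292.3  # beats/min
    p_max: float = 23.0  # mmHg
    p_min: float = 0.8  # mmHg
    edp: float = 1.3  # mmHg
    tau: float = 9.9  # ms
    n_beats: int = 6
    sampling_rate: float = 2000.0  # Hz
    noise_sd: float = 0.0  # mmHg
    seed: int | None = 0

    def validate(self) -> None:
        if self.heart_rate <= 0:
            raise ValidationError("heart_rate: must be positive")
        if not 0 < self.p_min < self.edp < self.p_max:
            raise ValidationError("p_min/edp/p_max: require 0 < p_min < edp < p_max")
        if self.tau <= 0:
            raise ValidationError("tau: must be positive")
        if self.n_beats < 1:
            raise ValidationError("n_beats: must be >= 1")
        if self.sampling_rate < 500:
            raise ValidationError("sampling_rate: must be >= 500 Hz")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be nonnegative")
        period = 60000.0 / self.heart_rate
        if 0.18 * period + self.tau * np.log(self.p_max / self.p_min) > 0.9 * period:
            raise ValidationError("tau: diastolic decay does not fit in the beat period")


def _beat_pressure(spec: WaveformSpec, s: np.ndarray, period: float) -> np.ndarray:
    """Pressure at local beat time s in [0, period) ms.

    Phases: raised-cosine upstroke EDP -> p_max (zero slope at onset, so
    the maximum second derivative sits at the EDP point), exponential
    decay p_max * exp(-t/tau) down to p_min (exactly log-linear), a
    smoothstep diastasis ramp p_min -> EDP, and an EDP plateau.
    """
    t_rise = 0.18 * period
    t_dec = spec.tau * np.log(spec.p_max / spec.p_min)
    t_flat = 0.05 * period
    t_ramp_end = period - t_flat

    p = np.full_like(s, spec.edp)
    rise = s < t_rise
    p[rise] = spec.edp + (spec.p_max - spec.edp) * 0.5 * (1 - np.cos(np.pi * s[rise] / t_rise))
    dec = (s >= t_rise) & (s < t_rise + t_dec)
    p[dec] = spec.p_max * np.exp(-(s[dec] - t_rise) / spec.tau)
    ramp = (s >= t_rise + t_dec) & (s < t_ramp_end)
    u = (s[ramp] - t_rise - t_dec) / (t_ramp_end - t_rise - t_dec)
    p[ramp] = spec.p_min + (spec.edp - spec.p_min) * (3 * u**2 - 2 * u**3)
    return p


def gen_pressure_waveform(spec: WaveformSpec) -> PressureWaveform:
    """Synthesize a multi-beat RV pressure trace from the spec."""
    spec.validate()
    period = 60000.0 / spec.heart_rate  # ms
    dt = 1000.0 / spec.sampling_rate
    n = int(np.floor(spec.n_beats * period / dt)) + 1
    t = np.arange(n) * dt
    p = _beat_pressure(spec, np.mod(t, period), period)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        p = p + rng.normal(0.0, spec.noise_sd, size=p.shape)
    return PressureWaveform(
        time=t, pressure=p, sampling_rate=spec.sampling_rate,
        meta={"ground_truth": spec.__dict__.copy(), "generator": "gen_pressure_waveform"},
    )


# --------------------------------------------------------------------------
# biaxial experiments
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialSpec:
    """Fung material + composition ground truth for one synthetic specimen."""

    B0: float = 1.2  # kPa
    b1: float = 12.0
    b2: float = 7.0
    b3: float = 3.0
    phi_myofiber: float = 0.953
    phi_collagen: float = 0.034
    #: when set, a linear collagen stress engages on each axis above this
    #: Green-Lagrange strain, producing a piecewise EFE response with a
    #: known recruitment strain on top of the Fung baseline
    recruitment_strain: float | None = None
    collagen_stiffness: float = 500.0  # kPa, post-recruitment slope added per axis

    def validate(self) -> None:
        if self.B0 <= 0:
            raise ValidationError("B0: must be positive")
        if not 0 <= self.phi_myofiber <= 1 or not 0 <= self.phi_collagen <= 1:
            raise ValidationError("phi_myofiber/phi_collagen: must lie in [0, 1]")
        if self.phi_myofiber + self.phi_collagen > 1:
            raise ValidationError("phi_myofiber: area fractions sum above 1")


@dataclass(frozen=True)
class ProtocolSet:
    """Displacement-controlled loading protocols (circ:long ratios)."""

    displacement_ratios: tuple[tuple[float, float], ...] = STANDARD_RATIOS
    max_strain: float = 0.15  # Green-Lagrange, on the dominant axis
    points_per_protocol: int = 40

    def validate(self) -> None:
        if len(self.displacement_ratios) < 1:
            raise ValidationError("displacement_ratios: at least one protocol required")
        if self.max_strain <= 0:
            raise ValidationError("max_strain: must be positive")
        if self.points_per_protocol < 3:
            raise ValidationError("points_per_protocol: must be >= 3")


@dataclass(frozen=True)
class SpecimenDims:
    """Reference dimensions of the square test specimen (mm)."""

    length_circ: float = 10.0
    length_long: float = 10.0
    thickness: float = 0.65

    def validate(self) -> None:
        for name in ("length_circ", "length_long", "thickness"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be positive")


def gen_biaxial_experiment(
    mat: MaterialSpec,
    protocols: ProtocolSet | None = None,
    dims: SpecimenDims | None = None,
    noise_sd: float = 0.0,  # kPa, additive on the 2nd P-K stresses
    rel_noise: float = 0.0,  # fractional (multiplicative) stress noise
    seed: int | None = 0,
) -> list[BiaxialRecord]:
    """Forward-simulate one specimen's multi-protocol biaxial test.

    Each protocol ramps the marker stretches at the prescribed
    circ:long displacement ratio up to ``max_strain`` on the dominant
    axis, evaluates the Fung stresses S11, S22, and converts them to
    axial forces via P = F S over the reference cross-sections.  Markers
    sit on an axis-aligned unit square centered in the specimen and move
    by pure stretch (no shear).  Ground truth is stored in each record's
    ``meta``.
    """
    mat.validate()
    protocols = protocols or ProtocolSet()
    protocols.validate()
    dims = dims or SpecimenDims()
    dims.validate()
    rng = np.random.default_rng(seed)

    half = 0.5  # markers on a unit square (mm) centered in the specimen
    square = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
    center = np.array([dims.length_circ / 2, dims.length_long / 2])
    ref = MarkerFrame(positions=center + square)

    lam_max = np.sqrt(2.0 * protocols.max_strain + 1.0)
    records = []
    for rc, rl in protocols.displacement_ratios:
        w = np.array([rc, rl], dtype=float) / max(rc, rl)
        tnorm = np.linspace(0.0, 1.0, protocols.points_per_protocol)
        lam = 1.0 + np.outer(tnorm, w) * (lam_max - 1.0)  # (n, 2) stretches
        E11, E22 = 0.5 * (lam[:, 0] ** 2 - 1.0), 0.5 * (lam[:, 1] ** 2 - 1.0)
        S11, S22 = fung_stress(mat_params(mat), E11, E22)
        if mat.recruitment_strain is not None:
            S11 = S11 + mat.collagen_stiffness * np.clip(E11 - mat.recruitment_strain, 0, None)
            S22 = S22 + mat.collagen_stiffness * np.clip(E22 - mat.recruitment_strain, 0, None)
        if rel_noise > 0:
            S11 = S11 * (1.0 + rng.normal(0.0, rel_noise, size=S11.shape))
            S22 = S22 * (1.0 + rng.normal(0.0, rel_noise, size=S22.shape))
        if noise_sd > 0:
            S11 = S11 + rng.normal(0.0, noise_sd, size=S11.shape)
            S22 = S22 + rng.normal(0.0, noise_sd, size=S22.shape)
        # P = F S for diagonal F and S; forces: kPa * mm^2 * 1e-3 -> N
        f_circ = lam[:, 0] * S11 * dims.length_long * dims.thickness * 1e-3
        f_long = lam[:, 1] * S22 * dims.length_circ * dims.thickness * 1e-3
        frames = [
            MarkerFrame(positions=center + square * lam[i], time=float(i))
            for i in range(len(tnorm))
        ]
        records.append(
            BiaxialRecord(
                reference=ref,
                frames=frames,
                forces=np.column_stack([f_circ, f_long]),
                length_circ=dims.length_circ,
                length_long=dims.length_long,
                thickness=dims.thickness,
                protocol_ratio=f"{rc:g}:{rl:g}",
                meta={
                    "ground_truth": {
                        "material": mat.__dict__.copy(),
                        "E11": E11, "E22": E22, "S11": S11, "S22": S22,
                    },
                    "noise_sd": noise_sd,
                },
            )
        )
    return records


def mat_params(mat: MaterialSpec) -> np.ndarray:
    """(B0, b1, b2, b3) vector of a MaterialSpec."""
    return np.array([mat.B0, mat.b1, mat.b2, mat.b3])


# --------------------------------------------------------------------------
# piecewise-linear EFE curves (recruitment ground truth)
# --------------------------------------------------------------------------

def gen_efe_curve(
    slope_pre: float = 60.0,  # kPa
    slope_post: float = 600.0,  # kPa
    recruitment_strain: float = 0.104,
    max_strain: float = 0.15,
    grid_step: float = GRID_STEP_DEFAULT,
    tm_noise_sd: float = 0.0,  # kPa, on the stiffness channel
    seed: int | None = 0,
) -> EFECurve:
    """Bilinear EFE stress curve with a known recruitment strain.

    The stress is exactly piecewise linear with a slope break at
    ``recruitment_strain``; the stiffness channel is its central
    finite difference plus optional Gaussian noise (emulating the
    fluctuations of measured stiffness data).
    """
    if slope_pre <= 0 or slope_post <= slope_pre:
        raise ValidationError("slope_post: require 0 < slope_pre < slope_post")
    if not 0 < recruitment_strain < max_strain:
        raise ValidationError("recruitment_strain: must lie in (0, max_strain)")
    E = np.arange(0.0, max_strain + 0.5 * grid_step, grid_step)
    S = np.where(
        E <= recruitment_strain,
        slope_pre * E,
        slope_pre * recruitment_strain + slope_post * (E - recruitment_strain),
    )
    TM = np.gradient(S, E)
    if tm_noise_sd > 0:
        rng = np.random.default_rng(seed)
        TM = TM + rng.normal(0.0, tm_noise_sd, size=TM.shape)
    return EFECurve(
        E=E, S=S, TM=TM,
        meta={
            "ground_truth": {
                "slope_pre": slope_pre, "slope_post": slope_post,
                "recruitment_strain": recruitment_strain,
            },
            "tm_noise_sd": tm_noise_sd,
        },
    )


# --------------------------------------------------------------------------
# histology stacks
# --------------------------------------------------------------------------

MYOFIBER_COLOR = (205, 90, 100)  # red/pink, trichrome-like
COLLAGEN_COLOR = (70, 85, 200)  # blue


@dataclass(frozen=True)
class HistologySpec:
    """Ground truth for one synthetic transmural section stack.

    ``orientation_by_depth`` and ``collagen_fraction_by_depth`` may be
    scalars or callables of normalized depth in [0, 1] (0 = epicardium,
    1 = endocardium).  ``coherency_target`` blends the stripe texture
    with spatial white noise: 100 gives a fully aligned texture, 0 pure
    noise; intermediate values trade alignment for disorder
    monotonically (the mapping is not calibrated in percent).
    """

    n_sections: int = 13
    image_size: int = 192  # px, square sections
    orientation_by_depth: object = 0.0  # degrees, scalar or callable
    coherency_target: float = 100.0  # %
    collagen_fraction_by_depth: object = 0.034  # fraction, scalar or callable
    myofiber_color: tuple[int, int, int] = MYOFIBER_COLOR
    collagen_color: tuple[int, int, int] = COLLAGEN_COLOR
    color_noise_sd: float = 0.0  # intensity units on 0-255
    wavelength_px: float = 8.0
    depth_step_um: float = 60.0
    pixel_size_um: float = 2.0
    seed: int | None = 0

    def validate(self) -> None:
        if self.n_sections < 1:
            raise ValidationError("n_sections: must be >= 1")
        if self.image_size < 16:
            raise ValidationError("image_size: must be >= 16 px")
        if not 0 <= self.coherency_target <= 100:
            raise ValidationError("coherency_target: must lie in [0, 100]")
        if self.wavelength_px <= 2:
            raise ValidationError("wavelength_px: must exceed 2 px")


@dataclass
class SectionImage:
    """One RGB histological section with its transmural position."""

    rgb: np.ndarray  # (H, W, 3) uint8
    depth_um: float
    pixel_size_um: float = 2.0

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3 or self.rgb.size == 0:
            raise ValidationError("rgb: expected a nonempty (H, W, 3) raster")


@dataclass
class HistologyStack:
    sections: list[SectionImage]
    ground_truth: pd.DataFrame  # depth_um, depth_norm, orientation_deg, collagen_fraction

    def __iter__(self):
        return iter(self.sections)


def _eval_by_depth(value, depth_norm: float) -> float:
    return float(value(depth_norm)) if callable(value) else float(value)


def _stripe_field(size: int, angle_deg: float, wavelength: float) -> np.ndarray:
    """Grayscale stripes running along ``angle_deg`` (0 deg = image x axis,
    positive counterclockwise with y pointing up)."""
    theta = np.deg2rad(angle_deg)
    rows, cols = np.mgrid[0:size, 0:size]
    x = cols.astype(float)
    y_up = (size - 1 - rows).astype(float)
    s = -x * np.sin(theta) + y_up * np.cos(theta)  # coordinate across the stripes
    return 0.5 + 0.5 * np.sin(2.0 * np.pi * s / wavelength)


def gen_histology_stack(spec: HistologySpec) -> HistologyStack:
    """Synthesize a transmural stack of two-phase striped sections.

    Collagen-colored pixels occupy exactly the prescribed area fraction
    of each section (rank thresholding of the texture, so the collagen
    phase forms stripes at the section's orientation).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sections, truth_rows = [], []
    n = spec.n_sections
    for i in range(n):
        depth_norm = i / (n - 1) if n > 1 else 0.0
        angle = _eval_by_depth(spec.orientation_by_depth, depth_norm)
        angle = angle % 180.0  # wrap to (-90, 90]
        if angle > 90.0:
            angle -= 180.0
        frac = _eval_by_depth(spec.collagen_fraction_by_depth, depth_norm)
        if not 0 <= frac <= 1:
            raise ValidationError("collagen_fraction_by_depth: values must lie in [0, 1]")
        gray = _stripe_field(spec.image_size, angle, spec.wavelength_px)
        wmix = spec.coherency_target / 100.0
        if wmix < 1.0:
            gray = wmix * gray + (1.0 - wmix) * rng.random(gray.shape)
        n_px = gray.size
        n_col = int(round(frac * n_px))
        order = np.argsort(gray, axis=None, kind="stable")
        collagen = np.zeros(n_px, dtype=bool)
        collagen[order[:n_col]] = True
        collagen = collagen.reshape(gray.shape)
        rgb = np.empty((*gray.shape, 3), dtype=float)
        rgb[...] = spec.myofiber_color
        rgb[collagen] = spec.collagen_color
        if spec.color_noise_sd > 0:
            rgb = rgb + rng.normal(0.0, spec.color_noise_sd, size=rgb.shape)
        img = SectionImage(
            rgb=np.clip(rgb, 0, 255).astype(np.uint8),
            depth_um=i * spec.depth_step_um,
            pixel_size_um=spec.pixel_size_um,
        )
        sections.append(img)
        truth_rows.append(
            {
                "depth_um": img.depth_um,
                "depth_norm": depth_norm,
                "orientation_deg": angle,
                "collagen_fraction": n_col / n_px,
            }
        )
    return HistologyStack(sections=sections, ground_truth=pd.DataFrame(truth_rows))
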