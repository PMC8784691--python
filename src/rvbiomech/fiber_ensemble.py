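"""Effective fiber-ensemble (EFE) analysis and collagen-recruitment detection.

The EFE stress S_EFE = S11 + S22 along the equibiaxial strain path
(E11 = E22 = E) aggregates the collagen + myofiber response
independently of fiber orientation.  The equibiaxial path is obtained
by interpolating the scattered multi-protocol (E11, E22) -> S surfaces
with a thin-plate spline (the 2-D biharmonic Green's-function
interpolant) and evaluating along the diagonal.

Collagen recruitment is the strain at which crimped collagen begins to
bear load, detected as the first grid point whose EFE stiffness
TM_EFE = dS_EFE/dE exceeds the running mean + Z * sd (sample sd, n-1
denominator) of the stiffness values before it.  The default threshold
Z = 4.417 is the two-sided standard-normal quantile for a 99.999%
confidence interval.  The pre-recruitment slope, divided by the
myofiber area fraction (rule of mixtures with zero pre-recruitment
collagen stiffness), gives the effective myofiber stiffness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay

from .exceptions import ValidationError

__all__ = [
    "EquibiaxialResponse",
    "EFECurve",
    "RecruitmentResult",
    "MyofiberStiffness",
    "interpolate_equibiaxial",
    "efe_curve",
    "detect_recruitment",
    "myofiber_stiffness",
    "Z_THRESHOLD_DEFAULT",
    "GRID_STEP_DEFAULT",
]

Z_THRESHOLD_DEFAULT = 4.417  # 99.999% two-sided normal quantile
GRID_STEP_DEFAULT = 0.0025  # equibiaxial strain grid spacing
_SD_FLOOR = 1e-12  # kPa; guards the scan on numerically flat noiseless curves


@dataclass
class EquibiaxialResponse:
    """Interpolated stresses along the equibiaxial path E11 = E22 = E."""

    E: np.ndarray  # strain grid, from 0
    S11: np.ndarray  # kPa
    S22: np.ndarray  # kPa

    def __post_init__(self):
        if not (len(self.E) == len(self.S11) == len(self.S22)):
            raise ValidationError("E/S11/S22: length mismatch")
        if np.any(np.diff(self.E) <= 0):
            raise ValidationError("E: must be strictly increasing")


@dataclass
class EFECurve:
    """EFE stress and stiffness on the equibiaxial strain grid."""

    E: np.ndarray
    S: np.ndarray  # S_EFE = S11 + S22, kPa
    TM: np.ndarray  # dS_EFE/dE, kPa
    meta: dict = field(default_factory=dict)


@dataclass
class RecruitmentResult:
    recruitment_strain: float
    recruitment_index: int
    pre_recruitment_slope: float  # kPa, OLS slope of S vs E before recruitment
    z_threshold: float
    n_pre_points: int


@dataclass
class MyofiberStiffness:
    TM_myofiber: float  # kPa
    phi_myofiber: float


def _pool_tables(tables) -> pd.DataFrame:
    frames = []
    for t in tables:
        if isinstance(t, pd.DataFrame):
            frames.append(t[["E11", "E22", "S11", "S22"]])
        else:
            raise ValidationError("protocol tables must be DataFrames with E11,E22,S11,S22")
    return pd.concat(frames, ignore_index=True)


def interpolate_equibiaxial(
    tables: list[pd.DataFrame],
    grid_step: float = GRID_STEP_DEFAULT,
    max_strain: float | None = None,
) -> EquibiaxialResponse:
    """Thin-plate-spline surfaces S11(E11,E22), S22(E11,E22) on the diagonal.

    Requires >= 3 protocols with samples on both sides of the E11 = E22
    diagonal so the equibiaxial path is enclosed; the grid is truncated
    (with a warning) where the path leaves the convex hull of the data.
    """
    if len(tables) < 3:
        raise ValidationError("need >= 3 loading protocols for surface interpolation")
    sides = [np.mean(t["E11"].to_numpy() - t["E22"].to_numpy()) for t in tables]
    if not (any(s > -1e-12 for s in sides) and any(s < 1e-12 for s in sides)):
        raise ValidationError("protocols must span both sides of the equibiaxial diagonal")
    df = _pool_tables(tables)
    # average duplicated strain points (every protocol starts at the origin)
    df = df.groupby(
        [df["E11"].round(12), df["E22"].round(12)], as_index=False
    ).mean()
    pts = df[["E11", "E22"]].to_numpy()
    if max_strain is None:
        # candidate upper end: largest strain seen anywhere; the hull test
        # below truncates the grid to the enclosed part of the diagonal
        max_strain = float(np.max(df[["E11", "E22"]].to_numpy()))
    grid = np.arange(0.0, max_strain + 0.5 * grid_step, grid_step)
    diag = np.column_stack([grid, grid])
    tri = Delaunay(pts)
    inside = tri.find_simplex(diag) >= 0
    if not inside.all():
        last = int(np.argmin(inside))  # first point outside
        if last < 3:
            raise ValidationError("equibiaxial path leaves the data hull immediately")
        warnings.warn(
            "equibiaxial path leaves the convex hull of the protocol data; "
            f"grid truncated at E = {grid[last - 1]:.4f}",
            stacklevel=2,
        )
        grid, diag = grid[:last], diag[:last]
    s11 = RBFInterpolator(pts, df["S11"].to_numpy(), kernel="thin_plate_spline")(diag)
    s22 = RBFInterpolator(pts, df["S22"].to_numpy(), kernel="thin_plate_spline")(diag)
    return EquibiaxialResponse(E=grid, S11=s11, S22=s22)


def efe_curve(eq: EquibiaxialResponse) -> EFECurve:
    """S_EFE = S11 + S22 pointwise; TM_EFE by central differences."""
    S = np.asarray(eq.S11) + np.asarray(eq.S22)
    TM = np.gradient(S, eq.E)
    return EFECurve(E=np.asarray(eq.E, dtype=float), S=S, TM=TM)


def detect_recruitment(
    curve: EFECurve,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    min_points: int = 5,
) -> RecruitmentResult | None:
    """Scan the EFE stiffness for a statistically significant jump.

    For n = min_points, min_points+1, ... the point n+1 is flagged as
    the onset of collagen recruitment when

        TM[n+1] > mean(TM[1..n]) + z_threshold * sd(TM[1..n])

    with the sample standard deviation (n-1 denominator).  A standard
    deviation below 1e-12 kPa is floored at 1e-12 so that numerically
    flat noiseless curves do not self-trigger.  Returns None when the
    inequality is never satisfied ("no recruitment detected").
    """
    TM = np.asarray(curve.TM, dtype=float)
    E = np.asarray(curve.E, dtype=float)
    if TM.size < min_points + 1:
        raise ValidationError(f"need at least min_points+1 = {min_points + 1} grid points")
    for n in range(min_points, TM.size):
        head = TM[:n]
        sd = max(float(np.std(head, ddof=1)), _SD_FLOOR)
        if TM[n] > float(np.mean(head)) + z_threshold * sd:
            slope = float(np.polyfit(E[:n], curve.S[:n], 1)[0])
            return RecruitmentResult(
                recruitment_strain=float(E[n]),
                recruitment_index=n,
                pre_recruitment_slope=slope,
                z_threshold=z_threshold,
                n_pre_points=n,
            )
    return None


def myofiber_stiffness(rec: RecruitmentResult, phi_myofiber: float) -> MyofiberStiffness:
    """Rule of mixtures with TM_collagen = 0 before recruitment:

    TM_myofiber = (TM_EFE)_before / phi_myofiber.
    """
    if not 0 < phi_myofiber <= 1:
        raise ValidationError("phi_myofiber: must lie in (0, 1]")
    return MyofiberStiffness(
        TM_myofiber=rec.pre_recruitment_slope / phi_myofiber,
        phi_myofiber=phi_myofiber,
    )
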