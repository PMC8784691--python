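"""Finite-deformation post-processing of planar biaxial marker/force data.

Four fiducial markers tracked on the epicardial surface define a single
bilinear (four-node) finite element; the deformation gradient F is the
map from the reference to the deformed marker configuration evaluated at
the element center.  Green-Lagrange strain E = (F^T F - I)/2, the 1st
Piola-Kirchhoff stress P from force over reference cross-section, and
the 2nd Piola-Kirchhoff stress S = F^-1 P complete the plane-stress
stress-strain state used by the downstream constitutive analysis.

Coordinate convention: x = circumferential, y = longitudinal
(apex-to-base).  Markers are ordered counterclockwise from the
lower-left corner.  No shear force channels exist on a suture/pulley
biaxial rig, so P12 = P21 = 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvertedElementError, ValidationError

__all__ = [
    "MarkerFrame",
    "BiaxialRecord",
    "StrainStressState",
    "deformation_gradient",
    "green_lagrange",
    "pk1_stress",
    "pk2_stress",
    "analyze_record",
]

# dN/d(xi,eta) of the bilinear shape functions N_i = (1+xi_i*xi)(1+eta_i*eta)/4
# at the element center (xi=eta=0), nodes counterclockwise from lower-left.
_GRAD_N = 0.25 * np.array(
    [
        [-1.0, 1.0, 1.0, -1.0],  # d/dxi
        [-1.0, -1.0, 1.0, 1.0],  # d/deta
    ]
)

_AREA_TOL = 1e-12


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1p2 and p3p4."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


@dataclass(frozen=True)
class MarkerFrame:
    """Four tracked marker positions (mm), counterclockwise from lower-left."""

    positions: np.ndarray  # (4, 2)
    time: float | None = None  # ms

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (4, 2):
            raise ValidationError("positions: expected 4 (x, y) marker pairs")
        object.__setattr__(self, "positions", pos)
        area = self.signed_area()
        if abs(area) < _AREA_TOL:
            raise ValidationError("positions: degenerate marker quadrilateral (area ~ 0)")
        if area < 0:
            raise ValidationError(
                "positions: markers must be ordered counterclockwise from lower-left"
            )
        p = pos
        if _segments_intersect(p[0], p[1], p[2], p[3]) or _segments_intersect(
            p[1], p[2], p[3], p[0]
        ):
            raise ValidationError("positions: marker quadrilateral is self-intersecting")

    def signed_area(self) -> float:
        x, y = self.positions[:, 0], self.positions[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class BiaxialRecord:
    """One specimen, one loading protocol: marker tracks + force channels.

    ``forces`` holds (f_circ, f_long) in newtons per deformed frame;
    reference side lengths and thickness are in mm.
    """

    reference: MarkerFrame
    frames: list[MarkerFrame]
    forces: np.ndarray  # (n_frames, 2), N
    length_circ: float  # mm
    length_long: float  # mm
    thickness: float  # mm
    protocol_ratio: str = "1:1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.forces = np.atleast_2d(np.asarray(self.forces, dtype=float))
        for name in ("length_circ", "length_long", "thickness"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be positive")
        if self.forces.shape != (len(self.frames), 2):
            raise ValidationError("forces: one (f_circ, f_long) pair per deformed frame")


@dataclass
class StrainStressState:
    """In-plane kinematic and stress state of one frame (stresses in kPa)."""

    F: np.ndarray
    E: np.ndarray
    P: np.ndarray
    S: np.ndarray

    def as_row(self) -> dict:
        return {
            "E11": self.E[0, 0],
            "E22": self.E[1, 1],
            "E12": self.E[0, 1],
            "S11": self.S[0, 0],
            "S22": self.S[1, 1],
            "S12": self.S[0, 1],
        }


def deformation_gradient(ref: MarkerFrame, cur: MarkerFrame) -> np.ndarray:
    """Deformation gradient from the bilinear element, one-point rule.

    F = (dx/dxi)(dX/dxi)^-1 evaluated at the element center; an affine
    map of the markers is recovered exactly.
    """
    j_ref = (_GRAD_N @ ref.positions).T  # dX_i/dxi_j
    j_cur = (_GRAD_N @ cur.positions).T
    if abs(np.linalg.det(j_ref)) < _AREA_TOL:
        raise ValidationError("reference marker quadrilateral is degenerate")
    F = j_cur @ np.linalg.inv(j_ref)
    if np.linalg.det(F) <= 0:
        raise InvertedElementError("inverted element: det F <= 0")
    return F


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """E = (F^T F - I)/2; symmetric, zero for any rigid motion."""
    F = np.asarray(F, dtype=float)
    return 0.5 * (F.T @ F - np.eye(2))


def pk1_stress(
    forces: tuple[float, float], length_circ: float, length_long: float, thickness: float
) -> np.ndarray:
    """1st Piola-Kirchhoff stress (kPa) from axial forces over reference area.

    P11 = f_circ / (L_long * t), P22 = f_long / (L_circ * t); the rig has
    no shear channels so the off-diagonal terms are zero.  Forces in N,
    dimensions in mm; N/mm^2 = MPa, hence the factor 1000 to kPa.
    """
    if length_circ <= 0 or length_long <= 0 or thickness <= 0:
        raise ValidationError("specimen dimensions must be positive")
    f_circ, f_long = forces
    P = np.zeros((2, 2))
    P[0, 0] = f_circ / (length_long * thickness) * 1e3
    P[1, 1] = f_long / (length_circ * thickness) * 1e3
    return P


def pk2_stress(F: np.ndarray, P: np.ndarray) -> np.ndarray:
    """2nd Piola-Kirchhoff stress S = F^-1 P (in-plane, plane stress)."""
    F = np.asarray(F, dtype=float)
    if abs(np.linalg.det(F)) < _AREA_TOL:
        raise InvertedElementError("singular deformation gradient")
    return np.linalg.solve(F, np.asarray(P, dtype=float))


def analyze_record(record: BiaxialRecord) -> pd.DataFrame:
    """Full per-frame strain/stress table for one protocol record.

    Returns a DataFrame with columns E11, E22, E12, S11, S22, S12 (kPa),
    one row per deformed frame.
    """
    rows = []
    for frame, (f_c, f_l) in zip(record.frames, record.forces):
        F = deformation_gradient(record.reference, frame)
        E = green_lagrange(F)
        P = pk1_stress((f_c, f_l), record.length_circ, record.length_long, record.thickness)
        S = pk2_stress(F, P)
        rows.append(StrainStressState(F=F, E=E, P=P, S=S).as_row())
    return pd.DataFrame(rows)
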