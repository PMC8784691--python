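"""Quantification of trichrome-stained transmural sections.

Collagen (blue) and myofiber (red/pink) phases are segmented by RGB
range thresholding; area fractions are pixel ratios within a region of
interest.  Fiber orientation and coherency come from the
Gaussian-windowed structure tensor of the image gradients,

    T = [[<Ix Ix>, <Ix Iy>],
         [<Ix Iy>, <Iy Iy>]],

integrated over the section ROI.  The dominant image-gradient direction
(largest-eigenvalue eigenvector of T) is perpendicular to the fibers,
so the fiber angle is taken from the smaller-eigenvalue eigenvector and
mapped to the tissue convention: 0 deg = circumferential (image x),
+90 deg = longitudinal (apex-to-base, image y up).  Coherency
C = 100 (l1 - l2)/(l1 + l2) runs from 0% (isotropic texture) to 100%
(perfectly aligned fibers).

Per-section metrics are assembled into transmural profiles on an
equally spaced normalized-thickness grid (0% epicardium to 100%
endocardium); orientations are interpolated and averaged in
doubled-angle space because fiber angles are axial (undirected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ValidationError
from .stats import axial_circular_mean
from .synthetic import SectionImage

__all__ = [
    "ColorRange",
    "TrichromeThresholds",
    "DEFAULT_THRESHOLDS",
    "SegmentationMasks",
    "SectionMetrics",
    "TransmuralProfile",
    "segment_trichrome",
    "area_fractions",
    "orientation_coherency",
    "transmural_profile",
    "analyze_stack",
]

ColorRange = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class TrichromeThresholds:
    """Inclusive RGB boxes for the two stained phases (manual thresholds)."""

    collagen: ColorRange = ((0, 130), (0, 255), (140, 255))  # blue
    myofiber: ColorRange = ((140, 255), (0, 255), (0, 130))  # red/pink

    def validate(self) -> None:
        overlap = all(
            max(a[0], b[0]) <= min(a[1], b[1])
            for a, b in zip(self.collagen, self.myofiber)
        )
        if overlap:
            raise ValidationError("thresholds: collagen and myofiber RGB ranges overlap")


DEFAULT_THRESHOLDS = TrichromeThresholds()


@dataclass
class SegmentationMasks:
    collagen: np.ndarray  # bool
    myofiber: np.ndarray  # bool
    roi: np.ndarray  # bool
    thresholds: TrichromeThresholds = DEFAULT_THRESHOLDS


@dataclass
class SectionMetrics:
    """Per-section composition and architecture metrics."""

    collagen_fraction: float  # %
    myofiber_fraction: float  # %
    orientation: float  # degrees in (-90, 90], nan when undefined
    coherency: float  # %
    depth_um: float = np.nan


@dataclass
class TransmuralProfile:
    """Metrics on the normalized-thickness grid plus regional summaries.

    Regions: Epi = 0-20%, Mid = 20-80%, Endo = 80-100% of thickness.
    """

    grid: np.ndarray  # normalized thickness, %
    table: pd.DataFrame  # per-grid-point metrics
    regions: pd.DataFrame  # Epi/Mid/Endo summary rows


def _in_range(channel: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return (channel >= lo) & (channel <= hi)


def segment_trichrome(
    img: SectionImage | np.ndarray,
    thresholds: TrichromeThresholds = DEFAULT_THRESHOLDS,
    roi: np.ndarray | None = None,
) -> SegmentationMasks:
    """RGB range thresholding into disjoint collagen and myofiber masks."""
    thresholds.validate()
    rgb = img.rgb if isinstance(img, SectionImage) else np.asarray(img)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError("img: expected an (H, W, 3) RGB raster")
    if roi is None:
        roi = np.ones(rgb.shape[:2], dtype=bool)
    masks = {}
    for phase, box in (("collagen", thresholds.collagen), ("myofiber", thresholds.myofiber)):
        m = np.ones(rgb.shape[:2], dtype=bool)
        for c in range(3):
            m &= _in_range(rgb[..., c], *box[c])
        masks[phase] = m & roi
    return SegmentationMasks(
        collagen=masks["collagen"], myofiber=masks["myofiber"], roi=roi,
        thresholds=thresholds,
    )


def area_fractions(masks: SegmentationMasks) -> tuple[float, float]:
    """(collagen %, myofiber %) relative to the ROI pixel count."""
    n_roi = int(np.count_nonzero(masks.roi))
    if n_roi == 0:
        raise ValidationError("roi: empty region of interest")
    collagen = 100.0 * np.count_nonzero(masks.collagen) / n_roi
    myofiber = 100.0 * np.count_nonzero(masks.myofiber) / n_roi
    return collagen, myofiber


def orientation_coherency(
    image: np.ndarray, sigma: float = 4.0
) -> tuple[float, float]:
    """ROI-global structure-tensor fiber orientation and coherency.

    ``image`` is a grayscale array or boolean mask (a segmented phase).
    Gradients are central differences after Gaussian pre-smoothing
    (sigma/2); the products Ix*Ix, Ix*Iy, Iy*Iy are Gaussian-windowed
    (sigma) and integrated over the interior of the section to form one
    tensor per section.  Returns (orientation in degrees, coherency %);
    orientation is nan ("undefined") on structureless images.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if min(img.shape) <= 4 * sigma:
        raise ValidationError(f"image: must exceed 4*sigma = {4 * sigma:g} px in both axes")
    sm = ndimage.gaussian_filter(img, sigma / 2.0, mode="mirror")
    gy_down, gx = np.gradient(sm)
    gy = -gy_down  # image rows run downward; physical y (longitudinal) runs up
    win = lambda a: ndimage.gaussian_filter(a, sigma, mode="mirror")
    margin = int(np.ceil(3 * sigma))
    core = (slice(margin, -margin), slice(margin, -margin))
    txx = float(win(gx * gx)[core].sum())
    txy = float(win(gx * gy)[core].sum())
    tyy = float(win(gy * gy)[core].sum())
    trace = txx + tyy
    if trace <= 1e-30:
        return np.nan, 0.0
    # eigenvalues of [[txx, txy], [txy, tyy]]
    diff = np.hypot(txx - tyy, 2.0 * txy)
    lam1, lam2 = 0.5 * (trace + diff), 0.5 * (trace - diff)
    coherency = 100.0 * (lam1 - lam2) / trace
    grad_angle = 0.5 * np.degrees(np.arctan2(2.0 * txy, txx - tyy))
    fiber = (grad_angle + 90.0) % 180.0  # perpendicular to the dominant gradient
    if fiber > 90.0:
        fiber -= 180.0
    return float(fiber), float(coherency)


def _axial_interp(grid: np.ndarray, x: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Linear interpolation of axial angles via the doubled-angle embedding."""
    doubled = np.deg2rad(2.0 * angles_deg)
    c = np.interp(grid, x, np.cos(doubled))
    s = np.interp(grid, x, np.sin(doubled))
    out = 0.5 * np.degrees(np.arctan2(s, c))
    return (out + 90.0) % 180.0 - 90.0


def transmural_profile(
    sections: list[SectionMetrics], n_grid: int = 21
) -> TransmuralProfile:
    """Interpolate per-section metrics onto the normalized-thickness grid.

    Depths are normalized to 0-100% between the shallowest and deepest
    section; scalar metrics are linearly interpolated, orientations in
    doubled-angle space.  Regional summaries use the grid points with
    Epi: [0, 20], Mid: (20, 80), Endo: [80, 100] percent thickness.
    """
    if len(sections) < 2:
        raise ValidationError("sections: need >= 2 sections with distinct depths")
    depths = np.array([s.depth_um for s in sections], dtype=float)
    if np.ptp(depths) <= 0:
        raise ValidationError("sections: depths must span a nonzero range")
    order = np.argsort(depths)
    depths = depths[order]
    sections = [sections[i] for i in order]
    depth_pct = 100.0 * (depths - depths[0]) / (depths[-1] - depths[0])
    grid = np.linspace(0.0, 100.0, n_grid)

    def col(attr):
        return np.array([getattr(s, attr) for s in sections], dtype=float)

    table = pd.DataFrame(
        {
            "thickness_pct": grid,
            "collagen_fraction": np.interp(grid, depth_pct, col("collagen_fraction")),
            "myofiber_fraction": np.interp(grid, depth_pct, col("myofiber_fraction")),
            "orientation": _axial_interp(grid, depth_pct, col("orientation")),
            "coherency": np.interp(grid, depth_pct, col("coherency")),
        }
    )
    masks = {
        "Epi": grid <= 20.0,
        "Mid": (grid > 20.0) & (grid < 80.0),
        "Endo": grid >= 80.0,
    }
    rows = []
    for name, m in masks.items():
        sub = table[m]
        rows.append(
            {
                "region": name,
                "collagen_fraction": sub["collagen_fraction"].mean(),
                "myofiber_fraction": sub["myofiber_fraction"].mean(),
                "orientation": axial_circular_mean(sub["orientation"].to_numpy()),
                "coherency": sub["coherency"].mean(),
            }
        )
    return TransmuralProfile(grid=grid, table=table, regions=pd.DataFrame(rows))


def analyze_stack(
    sections: list[SectionImage],
    thresholds: TrichromeThresholds = DEFAULT_THRESHOLDS,
    sigma: float = 4.0,
    orientation_phase: str = "myofiber",
) -> list[SectionMetrics]:
    """Segment every section and compute its per-section metrics.

    Orientation/coherency are evaluated on the segmented mask of
    ``orientation_phase`` ('myofiber' or 'collagen').
    """
    out = []
    for img in sections:
        masks = segment_trichrome(img, thresholds)
        collagen_pct, myofiber_pct = area_fractions(masks)
        phase = getattr(masks, orientation_phase)
        angle, coherency = orientation_coherency(phase, sigma=sigma)
        out.append(
            SectionMetrics(
                collagen_fraction=collagen_pct,
                myofiber_fraction=myofiber_pct,
                orientation=angle,
                coherency=coherency,
                depth_um=img.depth_um,
            )
        )
    return out
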