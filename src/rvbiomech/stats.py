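"""Group-comparison statistics.

Fiber orientations are axial (undirected, modulo 180 degrees), so all
circular statistics here work on doubled angles: the axial circular
mean doubles the angles, takes the resultant-vector mean, and halves;
the Watson-Williams test for equal mean directions is likewise run on
doubled angles.  Scalar comparisons follow the usual decision tree:
Shapiro-Wilk normality on both groups and Bartlett homoscedasticity,
then an unpaired two-sided t-test if both pass, otherwise a
Mann-Whitney U-test (both delegated to scipy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = [
    "ComparisonResult",
    "axial_circular_mean",
    "watson_williams",
    "compare_groups",
    "percent_change",
    "percent_change_raw",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    test: str

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def axial_circular_mean(angles_deg) -> float:
    """Mean of axial angles (degrees), result in (-90, 90].

    Doubles the angles, averages the unit resultant vector, halves the
    resultant direction.  Raises on an empty sample or when the
    doubled-angle resultant vanishes (perfectly balanced axial data).
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValidationError("angles: need at least one finite angle")
    doubled = np.deg2rad(2.0 * a)
    c, s = float(np.mean(np.cos(doubled))), float(np.mean(np.sin(doubled)))
    if math.hypot(c, s) < 1e-12:
        raise ValidationError("angles: undefined mean (zero axial resultant)")
    mean = 0.5 * math.degrees(math.atan2(s, c))
    if mean <= -90.0:
        mean += 180.0
    return mean


def _vm_kappa(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from the mean resultant
    length (standard piecewise approximation)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(groups: list) -> ComparisonResult:
    """Watson-Williams test for a common mean direction of axial samples.

    Angles (degrees) are doubled before testing.  The F statistic uses
    the standard concentration correction 1 + 3/(8*kappa); a warning is
    issued when the pooled concentration estimate is low (kappa < 1),
    where the test's assumptions are doubtful.
    """
    if len(groups) < 2:
        raise ValidationError("groups: need >= 2 groups")
    Rs, N, parts = [], 0, []
    for g in groups:
        a = np.asarray(g, dtype=float)
        if a.size < 2:
            raise ValidationError("groups: every group needs n >= 2 angles")
        doubled = np.deg2rad(2.0 * a)
        c, s = np.sum(np.cos(doubled)), np.sum(np.sin(doubled))
        Rs.append(math.hypot(c, s))
        parts.append((c, s))
        N += a.size
    J = len(groups)
    sum_R = float(np.sum(Rs))
    c_all = sum(p[0] for p in parts)
    s_all = sum(p[1] for p in parts)
    R = math.hypot(c_all, s_all)
    rbar = sum_R / N
    kappa = _vm_kappa(min(rbar, 0.999999))
    if kappa < 1.0:
        warnings.warn(
            "low concentration (kappa < 1): Watson-Williams assumptions doubtful",
            stacklevel=2,
        )
    correction = 1.0 + 3.0 / (8.0 * kappa)
    denom = N - sum_R
    if denom <= 0:
        # all groups perfectly concentrated; identical means give F = 0
        F = 0.0 if sum_R - R < 1e-12 else np.inf
    else:
        F = correction * ((N - J) * (sum_R - R)) / ((J - 1) * denom)
    F = max(F, 0.0)
    p = float(sps.f.sf(F, J - 1, N - J))
    return ComparisonResult(statistic=float(F), p_value=p, test="watson-williams")


def compare_groups(a, b) -> ComparisonResult:
    """Scalar two-group comparison with automatic test selection.

    Shapiro-Wilk on both samples and Bartlett's test decide between the
    unpaired two-sided t-test (both normal, homoscedastic) and the
    Mann-Whitney U-test; the chosen path is recorded in ``test``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("samples: each group needs n >= 3")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (
                sps.shapiro(a).pvalue > ALPHA and sps.shapiro(b).pvalue > ALPHA
            )
            homoscedastic = normal and sps.bartlett(a, b).pvalue > ALPHA
    except ValueError:  # e.g. constant sample
        normal = homoscedastic = False
    if normal and homoscedastic:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "t-test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    return ComparisonResult(
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)), test=name
    )


def percent_change(mean_ref: float, mean_new: float) -> int:
    """100*(new - ref)/ref, rounded half away from zero to an integer."""
    if mean_ref == 0:
        raise ValidationError("mean_ref: zero reference mean")
    raw = 100.0 * (mean_new - mean_ref) / mean_ref
    return int(math.copysign(math.floor(abs(raw) + 0.5), raw))


def percent_change_raw(mean_ref: float, mean_new: float) -> float:
    """Unrounded percent change (for tables that keep full precision)."""
    if mean_ref == 0:
        raise ValidationError("mean_ref: zero reference mean")
    return 100.0 * (mean_new - mean_ref) / mean_ref
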