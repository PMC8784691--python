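"""Fung-type anisotropic constitutive model for the RV free wall.

Strain energy density (kPa) as a function of the in-plane
Green-Lagrange strains E11 (circumferential) and E22 (longitudinal):

    W = B0 * (exp(b1*E11^2/2) + exp(b2*E22^2/2) + exp(b3*E11*E22) - 3)

with B0 a stress-like scale and b1, b2, b3 dimensionless measures of
circumferential, longitudinal and coupling stiffness.  The 2nd
Piola-Kirchhoff stresses are the strain gradients of W:

    S11 = B0 * (b1*E11*exp(b1*E11^2/2) + b3*E22*exp(b3*E11*E22))
    S22 = B0 * (b2*E22*exp(b2*E22^2/2) + b3*E11*exp(b3*E11*E22))

``FungModel`` fits (B0, b1, b2, b3) to multi-protocol biaxial
stress-strain data by trust-region-reflective non-linear least squares
with multi-start initialization; ``FungResults`` carries the estimates,
their approximate standard errors, the pooled R^2, and a summary table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import FitConvergenceError, ValidationError

__all__ = [
    "FungParameters",
    "fung_energy",
    "fung_stress",
    "FungModel",
    "FungResults",
    "fit_fung",
    "StrainEnergyMap",
    "strain_energy_map",
    "LOW_STRAIN_REGION",
    "HIGH_STRAIN_REGION",
]

_EXP_CAP = 500.0  # exponent beyond which exp() is meaningless here

#: default strain windows for the cohort energy maps (E11 = E22 ranges)
LOW_STRAIN_REGION = (0.0, 0.07)
HIGH_STRAIN_REGION = (0.07, 0.15)

_DEFAULT_BOUNDS = (
    np.array([1e-4, 1e-3, 1e-3, -1e2]),
    np.array([1e3, 1e2, 1e2, 1e2]),
)

# 8 multi-start initial points: a coarse log-spaced lattice plus a
# mid-range point; the fit keeps the best-loss winner.
_STARTS = [
    (b0, b, b, 0.5 * b) for b0, b in itertools.product((0.1, 1.0, 10.0), (1.0, 10.0))
] + [(1.0, 5.0, 5.0, 2.5), (0.5, 20.0, 20.0, 5.0)]


@dataclass
class FungParameters:
    """Fitted Fung parameters with fit diagnostics."""

    B0: float  # kPa
    b1: float
    b2: float
    b3: float
    r_squared: float = np.nan
    negative_coupling: bool = False
    n_starts_converged: int = 0
    cost: float = np.nan

    def __post_init__(self):
        if self.B0 <= 0:
            raise ValidationError("B0: must be positive")
        self.negative_coupling = self.b3 < 0

    def as_array(self) -> np.ndarray:
        return np.array([self.B0, self.b1, self.b2, self.b3])


def _checked_exponents(params, E11, E22):
    B0, b1, b2, b3 = params
    E11 = np.asarray(E11, dtype=float)
    E22 = np.asarray(E22, dtype=float)
    q1 = 0.5 * b1 * E11**2
    q2 = 0.5 * b2 * E22**2
    q3 = b3 * E11 * E22
    for name, q, e in (("E11", q1, E11), ("E22", q2, E22), ("E11*E22", q3, E11 * E22)):
        if np.any(q > _EXP_CAP):
            bad = np.asarray(e).flat[int(np.argmax(np.asarray(q)))]
            raise OverflowError(f"fung model overflow at strain {name} = {bad:g}")
    return B0, b1, b2, b3, E11, E22, q1, q2, q3


def fung_energy(params, E11, E22):
    """Strain energy density W (kPa); W(0,0) = 0 for any parameters."""
    p = params.as_array() if isinstance(params, FungParameters) else np.asarray(params)
    B0, b1, b2, b3, E11, E22, q1, q2, q3 = _checked_exponents(p, E11, E22)
    return B0 * (np.exp(q1) + np.exp(q2) + np.exp(q3) - 3.0)


def fung_stress(params, E11, E22):
    """Model-predicted 2nd Piola-Kirchhoff stresses (S11, S22) in kPa."""
    p = params.as_array() if isinstance(params, FungParameters) else np.asarray(params)
    B0, b1, b2, b3, E11, E22, q1, q2, q3 = _checked_exponents(p, E11, E22)
    e3 = np.exp(q3)
    S11 = B0 * (b1 * E11 * np.exp(q1) + b3 * E22 * e3)
    S22 = B0 * (b2 * E22 * np.exp(q2) + b3 * E11 * e3)
    return S11, S22


class FungModel:
    """Fung model bound to multi-protocol biaxial stress-strain data.

    Parameters
    ----------
    E11, E22 : array_like
        Green-Lagrange strains (pooled over protocols).
    S11, S22 : array_like
        Measured 2nd Piola-Kirchhoff stresses, kPa.
    """

    def __init__(self, E11, E22, S11, S22):
        self.E11 = np.asarray(E11, dtype=float).ravel()
        self.E22 = np.asarray(E22, dtype=float).ravel()
        self.S11 = np.asarray(S11, dtype=float).ravel()
        self.S22 = np.asarray(S22, dtype=float).ravel()
        n = self.E11.size
        if not (self.E22.size == self.S11.size == self.S22.size == n):
            raise ValidationError("E11/E22/S11/S22: length mismatch")
        if np.unique(np.column_stack([self.E11, self.E22]), axis=0).shape[0] < 4:
            raise ValidationError("need >= 4 distinct (E11, E22) samples")

    @classmethod
    def from_states(cls, tables: list[pd.DataFrame]) -> "FungModel":
        """Build from per-protocol strain/stress tables (analyze_record output)."""
        df = pd.concat(tables, ignore_index=True)
        return cls(df["E11"], df["E22"], df["S11"], df["S22"])

    def _residual(self, x):
        S11, S22 = fung_stress(x, self.E11, self.E22)
        return np.concatenate([S11 - self.S11, S22 - self.S22])

    def fit(self, init=None, bounds=None) -> "FungResults":
        """Trust-region-reflective least squares, multi-start, best-loss winner.

        Both stress channels enter the residual with equal weight.
        """
        lo, hi = bounds if bounds is not None else _DEFAULT_BOUNDS
        starts = [np.asarray(init, dtype=float)] if init is not None else [
            np.clip(np.asarray(s, dtype=float), lo, hi) for s in _STARTS
        ]
        best, n_ok, diagnostics = None, 0, []
        for x0 in starts:
            try:
                sol = least_squares(
                    self._residual, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except (OverflowError, FloatingPointError) as exc:  # pragma: no cover
                diagnostics.append(f"start {x0}: {exc}")
                continue
            if not sol.success:
                diagnostics.append(f"start {x0}: {sol.message}")
                continue
            n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitConvergenceError(
                "fung fit failed from every start:\n" + "\n".join(diagnostics)
            )
        observed = np.concatenate([self.S11, self.S22])
        ss_res = float(np.sum(best.fun**2))
        ss_tot = float(np.sum((observed - observed.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        params = FungParameters(
            B0=float(best.x[0]), b1=float(best.x[1]), b2=float(best.x[2]),
            b3=float(best.x[3]), r_squared=r2, n_starts_converged=n_ok,
            cost=float(best.cost),
        )
        return FungResults(model=self, params=params, _solution=best)


@dataclass
class FungResults:
    """Fit results: parameter estimates, uncertainties, diagnostics."""

    model: FungModel
    params: FungParameters
    _solution: object = field(repr=False, default=None)

    @property
    def r_squared(self) -> float:
        return self.params.r_squared

    def bse(self) -> np.ndarray:
        """Approximate standard errors from the Gauss-Newton covariance."""
        J = self._solution.jac
        dof = max(1, J.shape[0] - J.shape[1])
        sigma2 = 2.0 * self._solution.cost / dof
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return np.full(4, np.nan)

    def predict(self, E11=None, E22=None):
        if E11 is None:
            E11, E22 = self.model.E11, self.model.E22
        return fung_stress(self.params, E11, E22)

    def energy(self, E11, E22):
        return fung_energy(self.params, E11, E22)

    def summary(self) -> str:
        se = self.bse()
        names = ["B0 (kPa)", "b1", "b2", "b3"]
        vals = self.params.as_array()
        lines = [
            "Fung anisotropic model fit",
            "=" * 44,
            f"{'parameter':<12}{'estimate':>14}{'std err':>14}",
            "-" * 44,
        ]
        lines += [f"{n:<12}{v:>14.5g}{s:>14.3g}" for n, v, s in zip(names, vals, se)]
        lines += [
            "-" * 44,
            f"n obs (per channel): {self.model.E11.size}",
            f"pooled R^2: {self.params.r_squared:.5f}",
            f"converged starts: {self.params.n_starts_converged}",
        ]
        if self.params.negative_coupling:
            lines.append("note: negative coupling coefficient b3")
        return "\n".join(lines)


def fit_fung(tables: list[pd.DataFrame], init=None, bounds=None) -> FungResults:
    """Convenience wrapper: FungModel.from_states(tables).fit()."""
    return FungModel.from_states(tables).fit(init=init, bounds=bounds)


@dataclass
class StrainEnergyMap:
    """Cohort-averaged strain-energy surface over (E11, E22)."""

    E11: np.ndarray  # 2-D grid
    E22: np.ndarray
    W: np.ndarray  # kPa, pointwise cohort mean
    region: str
    n_specimens: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"E11": self.E11.ravel(), "E22": self.E22.ravel(), "W": self.W.ravel()}
        )


def strain_energy_map(
    cohort_params: list[FungParameters],
    region: str = "low",
    strain_range: tuple[float, float] | None = None,
    n_grid: int = 41,
) -> StrainEnergyMap:
    """Pointwise average of per-specimen energy surfaces on a common grid.

    ``region`` selects the default strain window ('low' -> [0, 0.07],
    'high' -> [0.07, 0.15]); an explicit ``strain_range`` overrides it.
    """
    if not cohort_params:
        raise ValidationError("cohort_params: empty cohort")
    if strain_range is None:
        strain_range = LOW_STRAIN_REGION if region == "low" else HIGH_STRAIN_REGION
    e = np.linspace(strain_range[0], strain_range[1], n_grid)
    E11, E22 = np.meshgrid(e, e)
    W = np.mean([fung_energy(p, E11, E22) for p in cohort_params], axis=0)
    return StrainEnergyMap(E11=E11, E22=E22, W=W, region=region, n_specimens=len(cohort_params))
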