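"""Pressure-derived indices of right-ventricular function.

Operates on a uniformly sampled RV pressure trace (mmHg vs ms) and
computes the standard catheterization metrics: heart rate from waveform
periodicity, peak pressure P_max, end-diastolic pressure (EDP, the
pressure at the maximum second time-derivative in the late-diastolic
window), dP/dt extrema, the contractility index dP/dt_max / P_max, and
the relaxation time constant tau from an ordinary least-squares fit of

    ln P(t) = -t / tau + B

over the segment between dP/dt_min and the pressure minimum.

Derivatives are estimated with Savitzky-Golay local polynomial
smoothing (window 11 samples, order 3): raw finite differences of noisy
catheter data are unusable, and the smoothing choices are documented
package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .exceptions import (
    DegenerateSignalError,
    InsufficientBeatsError,
    NondecayingSegmentError,
    NonpositivePressureError,
    ValidationError,
)

__all__ = [
    "PressureWaveform",
    "BeatSegmentation",
    "BeatMetrics",
    "TauFit",
    "HemodynamicSummary",
    "segment_beats",
    "beat_metrics",
    "relaxation_tau",
    "summarize_hemodynamics",
]

_SG_WINDOW = 11
_SG_ORDER = 3
_PEAK_PROMINENCE_FRAC = 0.25


@dataclass
class PressureWaveform:
    """Uniformly sampled RV pressure trace.  time in ms, pressure in mmHg."""

    time: np.ndarray
    pressure: np.ndarray
    sampling_rate: float  # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.time.shape != self.pressure.shape or self.time.ndim != 1:
            raise ValidationError("time/pressure: must be equal-length 1-D arrays")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValidationError("time: must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate: must be positive")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate


@dataclass
class BeatSegmentation:
    peaks: np.ndarray  # systolic peak sample indices
    windows: list[tuple[int, int]]  # peak-to-peak index windows
    heart_rate: float  # beats/min


@dataclass
class BeatMetrics:
    p_max: float  # mmHg
    p_min: float  # mmHg
    edp: float  # mmHg (nan when degenerate)
    edp_degenerate: bool
    dpdt_max: float  # mmHg/s
    dpdt_min: float  # mmHg/s
    contractility_index: float  # 1/s


@dataclass
class TauFit:
    tau: float  # ms
    intercept: float  # ln(mmHg)
    r_squared: float
    n_points: int


@dataclass
class HemodynamicSummary:
    heart_rate: float
    p_max: float
    p_min: float
    edp: float
    dpdt_max: float
    dpdt_min: float
    contractility_index: float
    tau: float  # single-beat value (first complete beat)
    tau_r_squared: float
    n_beats_used: int

    def as_row(self) -> dict:
        return {
            "heart_rate_bpm": self.heart_rate,
            "p_max_mmhg": self.p_max,
            "p_min_mmhg": self.p_min,
            "edp_mmhg": self.edp,
            "dpdt_max_mmhg_s": self.dpdt_max,
            "dpdt_min_mmhg_s": self.dpdt_min,
            "contractility_index_1_s": self.contractility_index,
            "tau_ms": self.tau,
            "n_beats_used": self.n_beats_used,
        }


def _smooth_derivative(w: PressureWaveform, deriv: int) -> np.ndarray:
    """Savitzky-Golay derivative of pressure in mmHg/s (or mmHg/s^2)."""
    window = min(_SG_WINDOW, w.pressure.size if w.pressure.size % 2 else w.pressure.size - 1)
    if window <= _SG_ORDER:
        raise ValidationError("pressure: trace too short for derivative estimation")
    return signal.savgol_filter(
        w.pressure, window, _SG_ORDER, deriv=deriv, delta=1.0 / w.sampling_rate
    )


def segment_beats(w: PressureWaveform) -> BeatSegmentation:
    """Locate systolic peaks and peak-to-peak beat windows.

    Peaks are local maxima with prominence >= 25% of the trace amplitude
    (earliest sample on ties); heart rate is 60 / mean peak-to-peak
    interval in seconds.
    """
    amplitude = float(np.ptp(w.pressure))
    if amplitude <= 0:
        raise InsufficientBeatsError("insufficient beats: constant pressure trace")
    peaks, _ = signal.find_peaks(w.pressure, prominence=_PEAK_PROMINENCE_FRAC * amplitude)
    if peaks.size < 2:
        raise InsufficientBeatsError("insufficient beats: fewer than 2 systolic peaks")
    intervals_ms = np.diff(w.time[peaks])
    heart_rate = 60.0 / (float(np.mean(intervals_ms)) / 1000.0)
    windows = [(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])]
    return BeatSegmentation(peaks=peaks, windows=windows, heart_rate=heart_rate)


def beat_metrics(w: PressureWaveform, window: tuple[int, int]) -> BeatMetrics:
    """Per-beat pressure metrics on one peak-to-peak window.

    EDP is searched between the pressure minimum and the subsequent
    dP/dt maximum (the diastole-to-upstroke limb); without that window
    the maximum second derivative would fire on the systolic upstroke.
    The EDP sample is the leading half-maximum crossing of the second
    derivative: smoothing spreads the curvature peak a few samples into
    the rising limb, so the onset of the curvature burst marks
    end-diastole with far less upstroke bias than its peak.
    """
    i0, i1 = window
    if i1 - i0 < 5:
        raise ValidationError("window: beat window shorter than 5 samples")
    seg = slice(i0, i1 + 1)
    p = w.pressure[seg]
    dpdt = _smooth_derivative(w, 1)[seg]
    d2pdt2 = _smooth_derivative(w, 2)[seg]

    p_max = float(np.max(p))
    p_min = float(np.min(p))
    dpdt_max = float(np.max(dpdt))
    dpdt_min = float(np.min(dpdt))

    i_pmin = int(np.argmin(p))
    i_dpdtmax = int(np.argmax(dpdt))
    edp, degenerate = np.nan, True
    if i_dpdtmax > i_pmin:
        search = d2pdt2[i_pmin : i_dpdtmax + 1]
        # curvature below this is numerical noise (float cancellation in the
        # second derivative is amplified by 1/dt^2), not a diastolic upstroke
        dt_s = 1.0 / w.sampling_rate
        scale = 1e-7 * max(1.0, float(np.ptp(p))) / dt_s**2
        if np.max(search) > scale:
            onset = int(np.nonzero(search >= 0.5 * np.max(search))[0][0])
            edp = float(p[i_pmin + onset])
            degenerate = False
    return BeatMetrics(
        p_max=p_max,
        p_min=p_min,
        edp=edp,
        edp_degenerate=degenerate,
        dpdt_max=dpdt_max,
        dpdt_min=dpdt_min,
        contractility_index=dpdt_max / p_max,
    )


def relaxation_tau(w: PressureWaveform, window: tuple[int, int]) -> TauFit:
    """Relaxation time constant from the log-linear diastolic decay.

    Fits ln P against t (OLS) on the segment from the time of dP/dt_min
    to the time of the pressure minimum; tau = -1/slope (ms).  The
    minimum time is located as the first zero-crossing of the smoothed
    dP/dt after its minimum (robust to noise dips in the flat diastasis
    that would drag a raw argmin far past the decay), stepped back by
    the smoothing half-window so the fitted segment stays inside the
    decay limb.
    """
    i0, i1 = window
    seg = slice(i0, i1 + 1)
    dpdt = _smooth_derivative(w, 1)[seg]
    j_start = i0 + int(np.argmin(dpdt))
    after = dpdt[j_start - i0 :]
    nonneg = np.nonzero(after >= 0)[0]
    if nonneg.size:
        j_end = j_start + int(nonneg[0]) - _SG_WINDOW // 2
    else:
        j_end = i0 + int(np.argmin(w.pressure[seg]))
    if j_end - j_start < 3:
        raise NondecayingSegmentError("nondecaying segment: no diastolic decay window")
    p_fit = w.pressure[j_start : j_end + 1]
    t_fit = w.time[j_start : j_end + 1]
    if np.any(p_fit <= 0):
        raise NonpositivePressureError("nonpositive pressure in tau window")
    res = stats.linregress(t_fit, np.log(p_fit))
    if res.slope >= 0:
        raise NondecayingSegmentError("nondecaying segment: nonnegative log-pressure slope")
    return TauFit(
        tau=-1.0 / res.slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=p_fit.size,
    )


def summarize_hemodynamics(w: PressureWaveform) -> HemodynamicSummary:
    """Multi-beat summary: metrics averaged over >= 3 consecutive beats.

    tau is reported from the first complete beat only; everything else
    is the mean across all complete peak-to-peak windows.
    """
    seg = segment_beats(w)
    if len(seg.windows) < 3:
        raise InsufficientBeatsError("insufficient beats: need >= 3 complete beats")
    per_beat = [beat_metrics(w, win) for win in seg.windows]
    tau_fit = relaxation_tau(w, seg.windows[0])
    edps = [m.edp for m in per_beat if not m.edp_degenerate]
    if not edps:
        raise DegenerateSignalError("EDP degenerate in every beat")
    return HemodynamicSummary(
        heart_rate=seg.heart_rate,
        p_max=float(np.mean([m.p_max for m in per_beat])),
        p_min=float(np.mean([m.p_min for m in per_beat])),
        edp=float(np.mean(edps)),
        dpdt_max=float(np.mean([m.dpdt_max for m in per_beat])),
        dpdt_min=float(np.mean([m.dpdt_min for m in per_beat])),
        contractility_index=float(np.mean([m.contractility_index for m in per_beat])),
        tau=tau_fit.tau,
        tau_r_squared=tau_fit.r_squared,
        n_beats_used=len(per_beat),
    )
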