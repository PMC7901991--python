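"""One-cycle flow and pressure waveforms and their scalar features.

A :class:`Waveform` holds one cardiac cycle of volumetric flow (m³/s) or
pressure (Pa) on a strictly increasing time grid with the periodic
convention ``times[0] == 0`` and ``times[-1] < period`` (the value at ``T``
equals the value at ``0``).  Feature extraction follows the quantities that
seed the distal Windkessel totals: mean/max/min flow, the forward time
interval from the flow maximum to the next minimum, and the forward
(stroke) and retrograde (regurgitant) volumes, both computed with zero
crossings located by linear interpolation so that the split is exact for
piecewise-linear signals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import resample as _fft_resample

MIN_SAMPLES = 16

__all__ = [
    "Waveform",
    "WaveformFeatures",
    "PressureSummary",
    "compute_features",
    "regurgitant_volume",
    "stroke_volume",
    "net_volume",
    "scale_to_stroke_volume",
    "resample",
    "read_waveform_csv",
    "write_waveform_csv",
]


@dataclass(frozen=True)
class Waveform:
    """One period of a flow or pressure signal at a named location.

    Parameters
    ----------
    times : array, seconds, strictly increasing, ``times[0] == 0`` and
        ``times[-1] < period``.
    values : array, m³/s for ``kind='flow'`` or Pa for ``kind='pressure'``.
    period : cycle length T in seconds.
    """

    times: np.ndarray
    values: np.ndarray
    period: float
    kind: str = "flow"
    location: str = "MPA"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.kind not in ("flow", "pressure"):
            raise ValueError(f"kind must be 'flow' or 'pressure', got {self.kind!r}")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} samples per period, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0.0:
            raise ValueError("times must start at 0")
        if t[-1] >= self.period:
            raise ValueError("times[-1] must be < period (periodic convention)")

    # -- periodic accessors -------------------------------------------------

    def closed(self) -> tuple[np.ndarray, np.ndarray]:
        """Grid and values with the wrap point at t = T appended."""
        return (
            np.append(self.times, self.period),
            np.append(self.values, self.values[0]),
        )

    def sample(self, t: np.ndarray | float) -> np.ndarray | float:
        """Periodic linear interpolation at arbitrary times."""
        tc, vc = self.closed()
        return np.interp(np.mod(t, self.period), tc, vc)

    def derivative(self, t: np.ndarray | float) -> np.ndarray | float:
        """Periodic time derivative, from centred differences on the grid."""
        tc, vc = self.closed()
        grad = np.gradient(vc, tc)
        # periodic slope estimate at the seam
        seam = (vc[1] - vc[-2]) / (tc[1] - (tc[-2] - self.period))
        grad[0] = grad[-1] = seam
        return np.interp(np.mod(t, self.period), tc, grad)


@dataclass(frozen=True)
class WaveformFeatures:
    """Scalar features of a flow waveform (SI units)."""

    mean_flow: float
    max_flow: float
    min_flow: float
    t_at_max: float
    t_at_min: float
    delta_t: float
    stroke_volume: float
    regurgitant_volume: float
    period: float


@dataclass(frozen=True)
class PressureSummary:
    """Systolic / diastolic / mean pressure and pulse, in Pa."""

    p_sys: float
    p_dias: float
    p_mean: float

    def __post_init__(self) -> None:
        if not (self.p_dias <= self.p_mean + 1e-9 and self.p_mean <= self.p_sys + 1e-9):
            raise ValueError("require p_dias <= p_mean <= p_sys")

    @property
    def pulse(self) -> float:
        return self.p_sys - self.p_dias

    @classmethod
    def from_trace(cls, times: np.ndarray, values: np.ndarray) -> "PressureSummary":
        """Summary of a periodic pressure trace (endpoint included or not)."""
        times = np.asarray(times, float)
        values = np.asarray(values, float)
        mean = float(np.trapezoid(values, times) / (times[-1] - times[0]))
        return cls(p_sys=float(values.max()), p_dias=float(values.min()), p_mean=mean)


# -- internal: exact positive/negative lobe integration ----------------------


def _with_zero_crossings(t: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Insert linearly interpolated zero crossings into a piecewise-linear signal."""
    sign_change = v[:-1] * v[1:] < 0
    idx = np.nonzero(sign_change)[0]
    if idx.size == 0:
        return t, v
    tc = t[idx] - v[idx] * (t[idx + 1] - t[idx]) / (v[idx + 1] - v[idx])
    t_aug = np.insert(t, idx + 1, tc)
    v_aug = np.insert(v, idx + 1, 0.0)
    return t_aug, v_aug


def _lobe_volumes(w: Waveform) -> tuple[float, float]:
    """(forward, retrograde) volumes over one period, exact for PWL signals."""
    t, v = _with_zero_crossings(*w.closed())
    pos = float(np.trapezoid(np.clip(v, 0.0, None), t))
    neg = float(np.trapezoid(np.clip(-v, 0.0, None), t))
    return pos, neg


# -- public operations -------------------------------------------------------


def net_volume(w: Waveform) -> float:
    """Signed volume ∫₀ᵀ Q dt over one period (m³)."""
    tc, vc = w.closed()
    return float(np.trapezoid(vc, tc))


def stroke_volume(w: Waveform) -> float:
    """Forward volume ∫₀ᵀ max(Q, 0) dt (m³)."""
    _require_flow(w)
    return _lobe_volumes(w)[0]


def regurgitant_volume(w: Waveform) -> float:
    """Retrograde volume ∫₀ᵀ max(−Q, 0) dt (m³).

    Trapezoidal quadrature with zero crossings located by linear
    interpolation, so the result is exact for piecewise-linear waveforms.
    """
    _require_flow(w)
    return _lobe_volumes(w)[1]


def compute_features(w: Waveform) -> WaveformFeatures:
    """Extract the scalar flow features used to seed the distal totals.

    ``delta_t`` is measured forward in time from the global flow maximum to
    the next global minimum, wrapping periodically.
    """
    _require_flow(w)
    v = w.values
    q_max = float(v.max())
    q_min = float(v.min())
    t_at_max = float(w.times[int(np.argmax(v))])
    # first global minimum reached after the maximum, periodically
    min_times = w.times[np.isclose(v, q_min, rtol=0.0, atol=0.0)]
    fwd = np.mod(min_times - t_at_max, w.period)
    t_at_min = float(min_times[int(np.argmin(fwd))])
    delta_t = float(np.mod(t_at_min - t_at_max, w.period))
    if delta_t == 0.0:
        delta_t = w.period  # constant signal: max and min coincide
    sv, rv = _lobe_volumes(w)
    return WaveformFeatures(
        mean_flow=net_volume(w) / w.period,
        max_flow=q_max,
        min_flow=q_min,
        t_at_max=t_at_max,
        t_at_min=t_at_min,
        delta_t=delta_t,
        stroke_volume=sv,
        regurgitant_volume=rv,
        period=w.period,
    )


def scale_to_stroke_volume(w: Waveform, target_sv: float) -> Waveform:
    """Multiply the waveform by one scalar so that ∫₀ᵀ Q dt = ``target_sv``.

    The shape is preserved; used to match a characteristic flow waveform to
    a subject's measured right-ventricular stroke volume.
    """
    _require_flow(w)
    net = net_volume(w)
    if net <= 0:
        raise ValueError("net forward volume must be positive to scale")
    return dataclasses.replace(w, values=w.values * (target_sv / net))


def resample(w: Waveform, n: int, method: str = "linear") -> Waveform:
    """Resample onto a uniform grid of ``n`` points over [0, T).

    ``method='linear'`` uses periodic linear interpolation; ``'fourier'``
    uses FFT resampling and requires a uniform input grid.
    """
    if n < MIN_SAMPLES:
        raise ValueError(f"n must be >= {MIN_SAMPLES}")
    t_new = np.arange(n) * (w.period / n)
    if method == "linear":
        v_new = np.asarray(w.sample(t_new), dtype=float)
    elif method == "fourier":
        dt = np.diff(np.append(w.times, w.period))
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=0.0):
            raise ValueError("Fourier resampling requires a uniform input grid")
        v_new = _fft_resample(w.values, n)
    else:
        raise ValueError(f"unknown method {method!r}")
    return dataclasses.replace(w, times=t_new, values=v_new)


def _require_flow(w: Waveform) -> None:
    if w.kind != "flow":
        raise ValueError(f"operation requires a flow waveform, got kind={w.kind!r}")


# -- CSV interface -----------------------------------------------------------


def write_waveform_csv(w: Waveform, path) -> None:
    """Write `time_s,value` rows (one period, no wrap point)."""
    arr = np.column_stack([w.times, w.values])
    header = "time_s,value"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")


def read_waveform_csv(
    path, period: float | None = None, kind: str = "flow", location: str = "MPA"
) -> Waveform:
    """Read a `time_s,value` CSV.

    If ``period`` is omitted it is inferred as ``t[-1] + median(diff(t))``
    (uniform-grid extension of the final sample).
    """
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    t, v = arr[:, 0], arr[:, 1]
    if period is None:
        period = float(t[-1] + np.median(np.diff(t)))
    return Waveform(times=t, values=v, period=period, kind=kind, location=location)
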