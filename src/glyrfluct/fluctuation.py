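"""Stationary noise analysis of slowly changing whole-cell currents.

Windowed (mean current, variance) pairs are formed from the DC trace and a
band-pass filtered AC copy, the control background variance is subtracted,
and the variance-mean relation

    sigma^2(I) = I_u * I - I**2 / N_c

is fitted through the origin to estimate the unitary current ``I_u`` and the
number of channels ``N_c``; the open probability at a peak current follows
from ``I = I_u * N_c * P_o``.  When the parabola is not identifiable the
initial portion is fitted by the linear low-occupancy limit
``I_u = sigma^2 / I``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sp_signal

from .trace import Trace

__all__ = [
    "VarianceMeanData",
    "NoiseFit",
    "NoiseFitError",
    "bandpass_ac",
    "compute_variance_mean",
    "fit_parabolic",
    "fit_linear_initial",
    "fit_noise",
    "open_probability",
]

DEFAULT_BANDPASS = (1.0, 2000.0)  # Hz; removes drift, keeps the gating band


class NoiseFitError(RuntimeError):
    """Raised when a variance-mean fit is not identifiable."""


@dataclass
class VarianceMeanData:
    """Binned (mean current, net variance) pairs from one recording."""

    mean_current: np.ndarray  # pA, magnitudes
    variance: np.ndarray  # pA^2, background-subtracted
    raw_variance: np.ndarray  # pA^2, before subtraction
    background_variance: float  # pA^2
    window_length: float  # s
    n_window_samples: int
    negative_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean_current = np.asarray(self.mean_current, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.raw_variance = np.asarray(self.raw_variance, dtype=float)
        if self.negative_flags is None:
            self.negative_flags = self.variance < 0
        if np.any(self.mean_current < 0):
            raise ValueError("mean currents must be magnitudes (>= 0)")
        if self.background_variance < 0:
            raise ValueError("background variance must be >= 0")

    @property
    def n_windows(self) -> int:
        return int(self.mean_current.size)


@dataclass
class NoiseFit:
    unitary_current: float  # I_u, pA
    n_channels: Optional[float]  # N_c; None for the linear fit
    p_open: Optional[float]  # P_o at the supplied peak, if computed
    fit_kind: str  # "parabolic" | "linear"
    r_squared: float
    se_unitary_current: float = math.nan
    se_n_channels: float = math.nan
    warnings: list[str] = field(default_factory=list)


def bandpass_ac(
    samples: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = DEFAULT_BANDPASS,
) -> np.ndarray:
    """Zero-phase band-pass (AC-coupled) copy of the signal."""
    lo, hi = band
    nyq = sampling_rate / 2.0
    hi = min(hi, 0.95 * nyq)
    if not (0 < lo < hi):
        raise ValueError("bad band-pass corners")
    sos = sp_signal.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    # pad on the scale of the low corner's settling time, else the default
    # (~18 samples) leaves large edge transients on windowed segments
    padlen = min(samples.size - 1, int(3.0 * sampling_rate / lo))
    return sp_signal.sosfiltfilt(sos, samples, padlen=padlen)


def compute_variance_mean(
    trace: Trace,
    control_window: tuple[float, float],
    window_length: float = 0.1,
    bandpass: tuple[float, float] = DEFAULT_BANDPASS,
    analysis_window: Optional[tuple[float, float]] = None,
) -> VarianceMeanData:
    """Windowed variance-mean pairs with control background subtraction.

    The DC mean of each non-overlapping window (relative to the control
    holding current, as a magnitude) is paired with the variance of the
    linearly detrended AC signal in that window; the AC variance over the
    control window is subtracted from every point.  By default the analysis
    region runs from the end of the control window to the end of the trace.
    """
    if window_length < 0.05:
        raise ValueError("window_length must be >= 50 ms")
    c0, c1 = control_window
    if c1 <= c0:
        raise ValueError("empty control window")
    for ann in trace.annotations:
        if ann.onset < c1 and ann.offset > c0:
            raise ValueError(
                f"control window overlaps drug application {ann.label!r}"
            )

    dc = trace.samples
    i_c0, i_c1 = trace.index_of(c0), trace.index_of(c1)
    # filter the control region on its own: a zero-phase filter applied to
    # the whole trace would smear any abrupt current change backwards into
    # the control window and inflate the background variance
    ac_control = bandpass_ac(dc[i_c0:i_c1], trace.sampling_rate, bandpass)
    background = float(np.var(ac_control))
    holding = float(np.mean(dc[i_c0:i_c1]))

    if analysis_window is None:
        analysis_window = (c1, trace.start_time + trace.duration)
    a0, a1 = analysis_window
    i_a0 = trace.index_of(a0)
    i_a1 = int(round((a1 - trace.start_time) * trace.sampling_rate))
    i_a1 = min(i_a1, trace.n_samples)
    ac = bandpass_ac(dc[i_a0:i_a1], trace.sampling_rate, bandpass)

    win = int(round(window_length * trace.sampling_rate))
    n_win = (i_a1 - i_a0) // win
    if n_win < 1:
        raise ValueError("analysis window shorter than one variance window")

    means = np.empty(n_win)
    raw_vars = np.empty(n_win)
    for w in range(n_win):
        lo = w * win
        sl = slice(lo, lo + win)
        means[w] = abs(float(np.mean(dc[i_a0 + lo:i_a0 + lo + win])) - holding)
        raw_vars[w] = float(np.var(sp_signal.detrend(ac[sl], type="linear")))
    return VarianceMeanData(
        mean_current=means,
        variance=raw_vars - background,
        raw_variance=raw_vars,
        background_variance=background,
        window_length=window_length,
        n_window_samples=win,
    )


# ----------------------------------------------------------------------
# fits


def _predicted_weights(
    data: VarianceMeanData, predicted_net: np.ndarray
) -> np.ndarray:
    # variance of a sample variance scales ~ sigma^4; weights must come from
    # *predicted* totals — weighting by the observed variances over-weights
    # windows that happened to fluctuate low and biases the fit downward
    total = np.maximum(predicted_net, 0.0) + data.background_variance
    floor = max(float(np.median(total)) * 1e-3, 1e-12)
    return 1.0 / np.maximum(total, floor) ** 2


def fit_parabolic(
    data: VarianceMeanData,
    weighted: bool = True,
    min_points: int = 8,
    min_span_fraction: float = 0.5,
) -> NoiseFit:
    """Weighted least squares of ``sigma^2 = I_u*I - I**2/N_c`` (origin fixed).

    Fails (raises :class:`NoiseFitError`) when too few points, insufficient
    current span, non-negative curvature, or curvature indistinguishable
    from zero — the caller may then fall back to the linear initial fit.
    """
    I = data.mean_current
    V = data.variance
    if data.n_windows < min_points:
        raise NoiseFitError(f"need >= {min_points} variance-mean points")
    span = (I.max() - I.min()) / I.max() if I.max() > 0 else 0.0
    if span < min_span_fraction:
        raise NoiseFitError("points span less than half of the peak current")

    X = np.column_stack([I, -(I**2)])
    w = np.ones(data.n_windows)
    beta = np.zeros(2)
    n_iter = 3 if weighted else 1
    for _ in range(n_iter):  # iteratively reweight from the model prediction
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], V * sw, rcond=None)
        if weighted:
            w = _predicted_weights(data, X @ beta)
    a, b = beta  # a = I_u, b = 1/N_c

    resid = V - X @ beta
    dof = max(data.n_windows - 2, 1)
    s2 = float(np.sum(w * resid**2)) / dof
    try:
        cov = np.linalg.inv((X * w[:, None]).T @ X) * s2
        se_a, se_b = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
        raise NoiseFitError("singular design matrix") from exc

    if b <= 0:
        raise NoiseFitError("non-negative curvature: no parabola")
    if se_b >= abs(b):
        raise NoiseFitError("curvature standard error covers zero")
    # curvature must be resolvable on the scale of the data, else the points
    # are effectively on a line (the N_c -> infinity limit)
    if I.max() ** 2 * b < 1e-6 * max(V.max(), 1e-300):
        raise NoiseFitError("negligible curvature: variance-mean relation linear")
    if a <= 0:
        raise NoiseFitError("non-positive unitary current")

    n_c = 1.0 / b
    vbar = float(np.average(V, weights=w))
    ss_tot = float(np.sum(w * (V - vbar) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return NoiseFit(
        unitary_current=float(a),
        n_channels=float(n_c),
        p_open=None,
        fit_kind="parabolic",
        r_squared=r2,
        se_unitary_current=float(se_a),
        se_n_channels=float(se_b / b**2),  # delta method for 1/b
    )


def fit_linear_initial(
    data: VarianceMeanData,
    initial_fraction: float = 0.3,
    weighted: bool = True,
    min_points: int = 4,
) -> NoiseFit:
    """Origin-constrained slope of variance on mean over the initial portion.

    In the low-occupancy limit the slope equals ``I_u``; ``N_c`` is not
    identifiable.  If fewer than ``min_points`` fall in the initial fraction
    but the dataset itself is that small, all points are used (a single
    point reduces to ``I_u = sigma^2 / I``).
    """
    I = data.mean_current
    V = data.variance
    if I.size == 0:
        raise NoiseFitError("no variance-mean points")
    warn_widened = []
    sel = (I <= initial_fraction * I.max()) & (I > 0)
    if sel.sum() < min_points:
        pos = np.flatnonzero(I > 0)
        if pos.size == 0:
            raise NoiseFitError("no usable initial points")
        if pos.size <= min_points:
            sel = I > 0
        else:  # widen to the min_points smallest currents
            order = pos[np.argsort(I[pos])][:min_points]
            sel = np.zeros(I.size, dtype=bool)
            sel[order] = True
            warn_widened.append(
                f"initial fraction widened beyond {initial_fraction:.0%} "
                f"to reach {min_points} points"
            )
    Ii, Vi = I[sel], V[sel]
    w = np.ones(Ii.size)
    slope = 0.0
    n_iter = 3 if weighted else 1
    for _ in range(n_iter):
        slope = float(np.sum(w * Ii * Vi) / np.sum(w * Ii**2))
        if weighted:
            sub = VarianceMeanData(
                Ii, Vi, Vi + data.background_variance,
                data.background_variance, data.window_length,
                data.n_window_samples,
            )
            w = _predicted_weights(sub, slope * Ii)
    warnings = list(warn_widened)
    if slope <= 0:
        warnings.append("nonphysical: fitted unitary current <= 0")
        slope = max(slope, 0.0)
    resid = Vi - slope * Ii
    se = math.sqrt(
        float(np.sum(w * resid**2)) / max(Ii.size - 1, 1) / float(np.sum(w * Ii**2))
    )
    vbar = float(np.average(Vi, weights=w))
    ss_tot = float(np.sum(w * (Vi - vbar) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return NoiseFit(
        unitary_current=slope,
        n_channels=None,
        p_open=None,
        fit_kind="linear",
        r_squared=r2,
        se_unitary_current=se,
        warnings=warnings,
    )


def fit_noise(data: VarianceMeanData, weighted: bool = True) -> NoiseFit:
    """Parabolic fit with automatic fallback to the linear initial fit."""
    try:
        return fit_parabolic(data, weighted=weighted)
    except NoiseFitError as exc:
        fit = fit_linear_initial(data, weighted=weighted)
        fit.warnings.append(f"parabolic fit rejected: {exc}")
        return fit


def open_probability(peak_current: float, fit: NoiseFit) -> float:
    """``P_o = I_peak / (I_u * N_c)``, clamped over (1, 1.05] with a warning."""
    if fit.fit_kind != "parabolic" or fit.n_channels is None:
        raise NoiseFitError("open probability needs a parabolic fit (N_c unknown)")
    if not peak_current > 0:
        raise ValueError("peak_current must be > 0")
    p = peak_current / (fit.unitary_current * fit.n_channels)
    if p <= 0 or p > 1.05:
        raise NoiseFitError(f"open probability {p:.3f} outside (0, 1.05]")
    if p > 1.0:
        fit.warnings.append(f"open probability {p:.3f} clamped to 1")
        p = 1.0
    return float(p)
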