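"""Power spectra of current noise and Lorentzian gating kinetics.

The one-sided net PSD (drug minus control, truncated below 200 Hz) of a
relaxing two-state ensemble is Lorentzian,

    S(f) = S0 / (1 + (f / fc)**2),      tau = 1 / (2 * pi * fc),

and a sum of two Lorentzians yields the power-weighted time constant

    tau_w = tau1 * S01/(S01+S02) + tau2 * S02/(S01+S02).

Fits are performed on log power (periodogram errors are multiplicative);
a double-Lorentzian is retained only when an extra-sum-of-squares F-test
prefers it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, signal as sp_signal, stats

from .trace import Trace

__all__ = [
    "PowerSpectrum",
    "LorentzianFit",
    "SpectrumFitError",
    "compute_psd",
    "fit_single_lorentzian",
    "fit_double_lorentzian",
    "select_model",
    "analyze_spectrum",
    "weighted_tau",
]

DEFAULT_FMAX = 200.0  # Hz


class SpectrumFitError(RuntimeError):
    pass


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz, ascending, > 0
    psd: np.ndarray  # pA^2/Hz, one-sided
    is_net: bool = False
    fmax_used: float = DEFAULT_FMAX
    n_negative_dropped: int = 0  # bookkeeping for net spectra

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.frequencies.size != self.psd.size:
            raise ValueError("frequency and PSD arrays differ in length")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must ascend")


@dataclass
class LorentzianFit:
    s0: float  # zero-frequency power of the (first) component, pA^2/Hz
    fc: float  # corner frequency of the (first) component, Hz
    components: int = 1
    s02: float = math.nan
    fc2: float = math.nan
    goodness: float = math.nan  # residual sum of squares in log space
    selected_by: str = ""

    def __post_init__(self) -> None:
        if not self.fc > 0:
            raise ValueError("corner frequency must be > 0")

    @property
    def tau(self) -> float:
        """Relaxation time 1/(2*pi*fc) of the first component, seconds."""
        return 1.0 / (2.0 * math.pi * self.fc)

    @property
    def tau2(self) -> float:
        return 1.0 / (2.0 * math.pi * self.fc2)

    @property
    def tau_w(self) -> float:
        """Power-weighted time constant; equals ``tau`` for one component."""
        if self.components == 1:
            return self.tau
        return weighted_tau(self.tau, self.s0, self.tau2, self.s02)


def weighted_tau(tau1: float, s01: float, tau2: float, s02: float) -> float:
    total = s01 + s02
    return tau1 * s01 / total + tau2 * s02 / total


# ----------------------------------------------------------------------


def _welch(samples: np.ndarray, fs: float, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(int(round(fs / resolution)), samples.size)
    return sp_signal.welch(
        samples,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )


def compute_psd(
    trace_segment: Trace,
    control_segment: Optional[Trace] = None,
    fmax: float = DEFAULT_FMAX,
    resolution: float = 0.5,
) -> PowerSpectrum:
    """One-sided averaged-periodogram PSD, optionally control-subtracted.

    Hann window, 50% overlap, segment mean removed; the density
    normalization satisfies Parseval (PSD integral ~ segment variance).
    The net spectrum is truncated to ``0 < f < fmax``.
    """
    if trace_segment.duration < 10.0 - 1e-9:
        raise ValueError("spectral segments must be >= 10 s")
    f, p = _welch(trace_segment.samples, trace_segment.sampling_rate, resolution)
    if control_segment is not None:
        if control_segment.sampling_rate != trace_segment.sampling_rate:
            raise ValueError("segment sampling rates differ")
        fc_, pc = _welch(
            control_segment.samples, control_segment.sampling_rate, resolution
        )
        n = min(p.size, pc.size)
        f, p = f[:n], p[:n] - pc[:n]
        is_net = True
    else:
        is_net = False
    keep = (f > 0) & (f < fmax)
    return PowerSpectrum(f[keep], p[keep], is_net=is_net, fmax_used=fmax)


def _positive_points(spectrum: PowerSpectrum) -> tuple[np.ndarray, np.ndarray, int]:
    pos = spectrum.psd > 0
    return spectrum.frequencies[pos], spectrum.psd[pos], int((~pos).sum())


def fit_single_lorentzian(spectrum: PowerSpectrum) -> LorentzianFit:
    """Least squares of ``S0 / (1 + (f/fc)^2)`` in log-power space."""
    f, p, n_dropped = _positive_points(spectrum)
    if f.size < 10:
        raise SpectrumFitError("need >= 10 net-positive points")
    logp = np.log(p)

    s0_guess = float(np.mean(p[: max(3, f.size // 20)]))
    half = np.flatnonzero(p < 0.5 * s0_guess)
    fc_guess = float(f[half[0]]) if half.size else float(f[f.size // 2])

    def model(freq, log_s0, log_fc):
        return log_s0 - np.log1p((freq / np.exp(log_fc)) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            model, f, logp, p0=[math.log(s0_guess), math.log(fc_guess)], maxfev=10000
        )
    except (RuntimeError, ValueError) as exc:
        raise SpectrumFitError(f"single-Lorentzian fit failed: {exc}") from exc
    resid = logp - model(f, *popt)
    fit = LorentzianFit(
        s0=float(np.exp(popt[0])),
        fc=float(np.exp(popt[1])),
        components=1,
        goodness=float(np.sum(resid**2)),
    )
    return fit


def fit_double_lorentzian(spectrum: PowerSpectrum) -> LorentzianFit:
    """Sum-of-two-Lorentzians fit; components ordered by corner frequency.

    Raises :class:`SpectrumFitError` on non-convergence or when the two
    corners are degenerate (within 5%), in which case callers should fall
    back to the single-component fit.
    """
    f, p, _ = _positive_points(spectrum)
    if f.size < 10:
        raise SpectrumFitError("need >= 10 net-positive points")
    logp = np.log(p)
    single = fit_single_lorentzian(spectrum)

    def model(freq, ls1, lf1, ls2, lf2):
        s = np.exp(ls1) / (1.0 + (freq / np.exp(lf1)) ** 2)
        s = s + np.exp(ls2) / (1.0 + (freq / np.exp(lf2)) ** 2)
        return np.log(s)

    p0 = [
        math.log(single.s0),
        math.log(single.fc / 4.0),
        math.log(max(single.s0 / 10.0, 1e-12)),
        math.log(single.fc * 4.0),
    ]
    try:
        popt, _ = optimize.curve_fit(model, f, logp, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise SpectrumFitError(f"double-Lorentzian fit failed: {exc}") from exc

    s1, fc1 = math.exp(popt[0]), math.exp(popt[1])
    s2, fc2 = math.exp(popt[2]), math.exp(popt[3])
    if fc1 > fc2:
        s1, fc1, s2, fc2 = s2, fc2, s1, fc1
    if abs(fc2 - fc1) / fc1 < 0.05:
        raise SpectrumFitError("degenerate components (corners within 5%)")
    resid = logp - model(f, *popt)
    return LorentzianFit(
        s0=s1,
        fc=fc1,
        components=2,
        s02=s2,
        fc2=fc2,
        goodness=float(np.sum(resid**2)),
    )


def select_model(
    single: LorentzianFit,
    double: Optional[LorentzianFit],
    spectrum: PowerSpectrum,
    alpha: float = 0.05,
) -> LorentzianFit:
    """Extra-sum-of-squares F-test; the double fit must earn its parameters."""
    if double is None:
        single.selected_by = "double fit unavailable"
        return single
    f, _, _ = _positive_points(spectrum)
    n = f.size
    ss1, ss2 = single.goodness, double.goodness
    if not (ss2 < ss1):
        single.selected_by = "parsimony (no residual improvement)"
        return single
    df2 = n - 4
    if df2 <= 0:
        single.selected_by = "parsimony (too few points)"
        return single
    f_stat = ((ss1 - ss2) / 2.0) / (ss2 / df2)
    p_val = float(stats.f.sf(f_stat, 2, df2))
    if p_val < alpha:
        double.selected_by = f"F-test p={p_val:.3g} < {alpha}"
        return double
    single.selected_by = f"F-test p={p_val:.3g} >= {alpha}"
    return single


def analyze_spectrum(spectrum: PowerSpectrum) -> LorentzianFit:
    """Fit single and double Lorentzians and select between them."""
    single = fit_single_lorentzian(spectrum)
    try:
        double = fit_double_lorentzian(spectrum)
    except SpectrumFitError:
        double = None
    return select_model(single, double, spectrum)
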