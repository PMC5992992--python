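"""Dose-response EC50 estimation and tonic-inhibition quantification.

Peak currents per concentration are averaged across cells and fitted with a
Hill sigmoid ``I(C) = Imax * C^n / (C^n + EC50^n)``; blocker-sensitive tonic
currents are quantified as the pre/post shift in holding current and in
band-passed current variance around an annotated drug application.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal as sp_signal

from .fluctuation import DEFAULT_BANDPASS, bandpass_ac
from .trace import Trace

__all__ = [
    "DoseResponseFit",
    "TonicShift",
    "DoseFitError",
    "measure_peak_current",
    "fit_dose_response",
    "measure_tonic_shift",
]


class DoseFitError(RuntimeError):
    pass


@dataclass
class DoseResponseFit:
    ec50: float  # uM
    hill: float
    imax: float  # pA
    se_ec50: float = math.nan
    se_hill: float = math.nan
    se_imax: float = math.nan
    n_cells: dict = field(default_factory=dict)  # per concentration
    flagged: bool = False
    flag_reason: str = ""

    def predict(self, conc):
        c = np.asarray(conc, dtype=float)
        return self.imax * c**self.hill / (c**self.hill + self.ec50**self.hill)


@dataclass
class TonicShift:
    delta_holding: float  # pA, magnitude of the blocked inward current
    delta_variance: float  # pA^2, pre minus post band-passed variance
    pre_window: tuple[float, float]
    post_window: tuple[float, float]


# ----------------------------------------------------------------------


def measure_peak_current(
    trace: Trace,
    application_window: tuple[float, float],
    lowpass_hz: float = 50.0,
    baseline_seconds: float = 5.0,
) -> float:
    """Magnitude of the low-passed, baseline-subtracted extremum in a window.

    Baseline is the mean over ``baseline_seconds`` preceding the window
    (clipped to the trace start), so the measure is invariant to a constant
    holding-current offset.
    """
    t0, t1 = application_window
    end = trace.start_time + trace.duration
    if t0 < trace.start_time - 1e-9 or t1 > end + 1e-9 or t1 <= t0:
        raise ValueError("application window outside trace")
    nyq = trace.sampling_rate / 2.0
    if lowpass_hz < nyq:
        # Bessel: minimal step-response overshoot, so abrupt applications do
        # not inflate the measured peak
        sos = sp_signal.bessel(4, lowpass_hz / nyq, btype="low", output="sos")
        filtered = sp_signal.sosfiltfilt(sos, trace.samples)
    else:
        filtered = trace.samples
    i0 = trace.index_of(t0)
    i1 = trace.index_of(t1)
    b0 = trace.index_of(max(trace.start_time, t0 - baseline_seconds))
    baseline = float(np.mean(filtered[b0:i0])) if i0 > b0 else float(filtered[i0])
    seg = filtered[i0:max(i1, i0 + 1)] - baseline
    return float(np.max(np.abs(seg)))


def fit_dose_response(
    table: pd.DataFrame,
    conc_col: str = "concentration_um",
    peak_col: str = "peak_pa",
) -> DoseResponseFit:
    """Hill fit to per-concentration means across cells.

    The fit is parameterized in log-concentration (log EC50, slope, Imax), so
    rescaling the concentration units rescales EC50 exactly.  A fit is
    flagged when EC50 falls outside ten times the tested range.
    """
    grouped = table.groupby(conc_col)[peak_col]
    means = grouped.mean()
    n_cells = grouped.size().to_dict()
    conc = means.index.to_numpy(dtype=float)
    resp = means.to_numpy(dtype=float)
    if conc.size < 4:
        raise DoseFitError("need >= 4 distinct concentrations")
    if np.any(conc <= 0):
        raise DoseFitError("concentrations must be positive")

    logc = np.log10(conc)

    def model(lc, log_ec50, hill, imax):
        return imax / (1.0 + 10.0 ** ((log_ec50 - lc) * hill))

    imax0 = float(resp.max())
    half_idx = int(np.argmin(np.abs(resp - imax0 / 2.0)))
    p0 = [float(logc[half_idx]), 1.0, imax0]
    try:
        popt, pcov = optimize.curve_fit(model, logc, resp, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise DoseFitError(f"dose-response fit failed: {exc}") from exc

    log_ec50, hill, imax = popt
    ec50 = 10.0**log_ec50
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    se_ec50 = ec50 * math.log(10.0) * se[0]  # delta method

    fit = DoseResponseFit(
        ec50=float(ec50),
        hill=float(hill),
        imax=float(imax),
        se_ec50=float(se_ec50),
        se_hill=float(se[1]),
        se_imax=float(se[2]),
        n_cells={float(k): int(v) for k, v in n_cells.items()},
    )
    cmin, cmax = conc.min(), conc.max()
    if not (cmin / 10.0 <= ec50 <= cmax * 10.0):
        fit.flagged = True
        fit.flag_reason = (
            f"EC50 {ec50:.3g} outside 10x the tested range [{cmin:g}, {cmax:g}]"
        )
    return fit


def measure_tonic_shift(
    trace: Trace,
    drug_label: str,
    window_seconds: float = 10.0,
    equilibration_seconds: float = 5.0,
    bandpass: tuple[float, float] = DEFAULT_BANDPASS,
) -> TonicShift:
    """Holding-current and variance shift around an annotated blocker step.

    Pre window: ``window_seconds`` ending at the drug onset.  Post window:
    same length starting ``equilibration_seconds`` after onset.  The variance
    shift is computed on the band-passed (AC) signal.
    """
    try:
        ann = trace.find_annotation(drug_label)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    t_on = ann.onset
    pre = (max(trace.start_time, t_on - window_seconds), t_on)
    post_start = t_on + equilibration_seconds
    post = (post_start, min(trace.start_time + trace.duration, post_start + window_seconds))
    if post[1] <= post[0] or pre[1] <= pre[0]:
        raise ValueError("trace too short for pre/post tonic windows")

    dc_pre = trace.window_slice(pre)
    dc_post = trace.window_slice(post)
    # band-pass each window separately: a zero-phase filter applied across
    # the blocker step would smear the step transient into the pre window
    ac_pre = bandpass_ac(dc_pre, trace.sampling_rate, bandpass)
    ac_post = bandpass_ac(dc_post, trace.sampling_rate, bandpass)

    return TonicShift(
        delta_holding=abs(float(np.mean(dc_pre)) - float(np.mean(dc_post))),
        delta_variance=float(np.var(ac_pre)) - float(np.var(ac_post)),
        pre_window=pre,
        post_window=post,
    )
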