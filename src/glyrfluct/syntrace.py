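"""Seeded synthetic-data generators.

Every input class the analysis pipeline consumes can be generated here with
recorded ground truth: ensemble currents from independent two-state channels,
Poisson trains of biexponential miniature-IPSC waveforms in Gaussian noise,
Hill-type dose-response tables, and tonic currents abolished by a blocker
step.  All generators require an explicit seed and are bit-reproducible.

Channel gating is simulated by an exact-jump (Gillespie) algorithm on the
ensemble open-channel count — a birth-death chain that is statistically
identical to simulating each channel independently — and the jump process is
then sampled onto the trace grid, so the analytic binomial moments

    mean  = n_channels * unitary_current * p_open
    var   = unitary_current**2 * n_channels * p_open * (1 - p_open)

hold exactly for the generated (noise-free) channel component.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trace import Annotation, Trace

__all__ = [
    "ChannelSimConfig",
    "MipsTrainConfig",
    "GroundTruth",
    "ConfigurationError",
    "simulate_two_state_ensemble",
    "simulate_glycine_application",
    "simulate_mipsc_train",
    "simulate_dose_response",
    "simulate_tonic_block",
    "biexp_waveform",
    "biexp_peak_time",
    "write_ground_truth",
    "read_ground_truth",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


# ----------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class ChannelSimConfig:
    """Parameters of an ensemble of independent two-state channels.

    ``seed`` is mandatory: reproducibility is part of the contract and an
    implicit default would silently break it.
    """

    n_channels: int
    unitary_current: float  # pA, magnitude of the single-channel current
    k_open: float  # 1/s, closed -> open rate
    k_close: float  # 1/s, open -> closed rate
    baseline_noise_sd: float  # pA
    sampling_rate: float  # Hz
    duration: float  # s
    seed: int

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_channels < 0:
            raise ConfigurationError("n_channels must be >= 0")
        for name in ("k_open", "k_close"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0")
        if not self.unitary_current > 0:
            raise ConfigurationError("unitary_current must be > 0")
        if self.baseline_noise_sd < 0:
            raise ConfigurationError("baseline_noise_sd must be >= 0")
        if not self.sampling_rate > 0 or not self.duration > 0:
            raise ConfigurationError("sampling_rate and duration must be > 0")
        total = self.k_open + self.k_close
        if total > 0 and self.sampling_rate < 10.0 * total:
            raise ConfigurationError(
                "sampling_rate must be >= 10*(k_open+k_close) so gating is "
                f"resolvable (got {self.sampling_rate} Hz for {total}/s)"
            )

    @property
    def p_open_stationary(self) -> float:
        total = self.k_open + self.k_close
        return self.k_open / total if total > 0 else 0.0


@dataclass(frozen=True)
class MipsTrainConfig:
    """Parameters of a Poisson train of biexponential mIPSC waveforms."""

    event_rate: float  # Hz
    amp_mean: float  # pA, magnitude
    amp_cv: float  # dimensionless
    tau_rise: float  # ms
    tau_decay: float  # ms
    baseline_noise_sd: float  # pA
    duration: float  # s
    sampling_rate: float = 20000.0  # Hz
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.event_rate < 0:
            raise ConfigurationError("event_rate must be >= 0")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ConfigurationError("need tau_decay > tau_rise > 0")
        if self.amp_mean <= 0 or self.amp_cv < 0:
            raise ConfigurationError("amp_mean must be > 0 and amp_cv >= 0")
        if self.baseline_noise_sd < 0:
            raise ConfigurationError("baseline_noise_sd must be >= 0")
        if not self.sampling_rate > 0 or not self.duration > 0:
            raise ConfigurationError("sampling_rate and duration must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually produced, for parameter-recovery tests."""

    event_onsets: list[float] = field(default_factory=list)
    event_amplitudes: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.event_onsets) != len(self.event_amplitudes):
            raise ValueError("onset and amplitude lists differ in length")
        if any(b < a for a, b in zip(self.event_onsets, self.event_onsets[1:])):
            raise ValueError("event onsets must be sorted ascending")


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(gt), indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(**d)


# ----------------------------------------------------------------------
# exact ensemble gating


def _gillespie_open_count(
    n_channels: int,
    k_open_per_segment: np.ndarray,
    k_close: float,
    segment_edges: np.ndarray,
    n_open0: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact-jump simulation of the ensemble open-channel count.

    Rates are constant within each segment ``[edges[i], edges[i+1])``; the
    closed->open rate of segment ``i`` is ``k_open_per_segment[i]``.  Returns
    jump times (starting at ``edges[0]``) and the open count after each jump.
    The piecewise-constant restart at segment boundaries is exact by the
    memorylessness of the exponential waiting times.
    """
    times = [float(segment_edges[0])]
    counts = [int(n_open0)]
    t = float(segment_edges[0])
    no = int(n_open0)
    n = int(n_channels)
    kc = float(k_close)

    chunk = 1 << 15
    exp_buf = rng.standard_exponential(chunk)
    uni_buf = rng.random(chunk)
    ei = 0
    t_app = times.append
    c_app = counts.append

    for s in range(len(k_open_per_segment)):
        ko = float(k_open_per_segment[s])
        t_end = float(segment_edges[s + 1])
        while True:
            r_open = (n - no) * ko
            rate = r_open + no * kc
            if rate <= 0.0:
                break
            if ei >= chunk:
                exp_buf = rng.standard_exponential(chunk)
                uni_buf = rng.random(chunk)
                ei = 0
            dt = exp_buf[ei] / rate
            if t + dt > t_end:
                ei += 1
                break
            t += dt
            if uni_buf[ei] * rate < r_open:
                no += 1
            else:
                no -= 1
            ei += 1
            t_app(t)
            c_app(no)
        t = t_end
    return np.asarray(times), np.asarray(counts)


def _sample_on_grid(
    jump_times: np.ndarray,
    counts: np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    idx = np.searchsorted(jump_times, grid, side="right") - 1
    return counts[np.maximum(idx, 0)]


def simulate_two_state_ensemble(cfg: ChannelSimConfig) -> tuple[Trace, GroundTruth]:
    """Ensemble current of ``n_channels`` independent two-state channels.

    Each open channel contributes ``-unitary_current`` (inward, negative);
    white Gaussian baseline noise of the configured SD is added.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = round(cfg.duration * cfg.sampling_rate)
    grid = np.arange(n_samples) / cfg.sampling_rate

    p0 = cfg.p_open_stationary
    n_open0 = int(rng.binomial(cfg.n_channels, p0)) if cfg.n_channels else 0
    edges = np.array([0.0, cfg.duration])
    jt, jc = _gillespie_open_count(
        cfg.n_channels, np.array([cfg.k_open]), cfg.k_close, edges, n_open0, rng
    )
    open_grid = _sample_on_grid(jt, jc, grid)
    samples = -cfg.unitary_current * open_grid.astype(float)
    if cfg.baseline_noise_sd > 0:
        samples += rng.normal(0.0, cfg.baseline_noise_sd, n_samples)

    trace = Trace(samples, cfg.sampling_rate)
    gt = GroundTruth(
        params={
            **asdict(cfg),
            "p_open_stationary": p0,
            "expected_mean_pa": cfg.n_channels * cfg.unitary_current * p0,
            "expected_channel_variance_pa2": (
                cfg.unitary_current**2 * cfg.n_channels * p0 * (1.0 - p0)
            ),
            "mean_open_fraction": float(np.mean(open_grid)) / max(cfg.n_channels, 1),
        }
    )
    return trace, gt


def simulate_glycine_application(
    cfg: ChannelSimConfig,
    popen_profile: Callable[[float], float],
    profile_dt: float = 0.01,
) -> tuple[Trace, GroundTruth]:
    """Ensemble current whose instantaneous open probability tracks a profile.

    ``k_close`` stays fixed and ``k_open`` is rescaled per (short) segment so
    that the stationary open probability of each segment equals the profile
    value at its midpoint; the profile must change slowly relative to
    ``1/(k_open+k_close)`` for the instantaneous occupancy to track it.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = round(cfg.duration * cfg.sampling_rate)
    grid = np.arange(n_samples) / cfg.sampling_rate

    n_seg = max(1, int(math.ceil(cfg.duration / profile_dt)))
    edges = np.linspace(0.0, cfg.duration, n_seg + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    p = np.array([float(popen_profile(t)) for t in mids])
    if np.any(p < -1e-12) or np.any(p > 1.0 + 1e-12):
        raise ConfigurationError("popen_profile must take values in [0, 1]")
    p = np.clip(p, 0.0, 0.995)  # cap keeps k_open finite at p -> 1
    k_open_seg = p / (1.0 - p) * cfg.k_close

    p_start = min(max(float(popen_profile(0.0)), 0.0), 1.0)
    n_open0 = int(rng.binomial(cfg.n_channels, p_start)) if cfg.n_channels else 0
    jt, jc = _gillespie_open_count(
        cfg.n_channels, k_open_seg, cfg.k_close, edges, n_open0, rng
    )
    open_grid = _sample_on_grid(jt, jc, grid)
    samples = -cfg.unitary_current * open_grid.astype(float)
    if cfg.baseline_noise_sd > 0:
        samples += rng.normal(0.0, cfg.baseline_noise_sd, n_samples)

    trace = Trace(samples, cfg.sampling_rate)
    gt = GroundTruth(
        params={
            **asdict(cfg),
            "profile_dt": profile_dt,
            "profile_max": float(np.max(p)),
            "peak_expected_mean_pa": float(
                cfg.n_channels * cfg.unitary_current * np.max(p)
            ),
        }
    )
    return trace, gt


def triangular_profile(
    peak: float, duration: float, lead_in: float = 5.0
) -> Callable[[float], float]:
    """Open-probability profile: flat zero, linear rise to ``peak`` at the
    midpoint of the remaining time, linear fall back to zero.

    The flat lead-in gives the noise-analysis stage a clean control window
    before the simulated agonist application.
    """
    if not (0.0 <= peak <= 1.0):
        raise ConfigurationError("peak open probability must lie in [0, 1]")
    if not (0.0 <= lead_in < duration):
        raise ConfigurationError("lead_in must lie inside the duration")
    t_peak = lead_in + (duration - lead_in) / 2.0

    def profile(t: float) -> float:
        if t <= lead_in:
            return 0.0
        if t <= t_peak:
            return peak * (t - lead_in) / (t_peak - lead_in)
        return max(0.0, peak * (duration - t) / (duration - t_peak))

    return profile


# ----------------------------------------------------------------------
# miniature IPSC trains


def biexp_peak_time(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Peak time (ms from onset) of exp(-t/tau_d) - exp(-t/tau_r)."""
    tr, td = tau_rise_ms, tau_decay_ms
    return tr * td / (td - tr) * math.log(td / tr)


def biexp_waveform(
    t_ms: np.ndarray, amplitude: float, tau_rise_ms: float, tau_decay_ms: float
) -> np.ndarray:
    """Peak-normalized biexponential, peak value = ``amplitude``; 0 for t<0."""
    t = np.asarray(t_ms, dtype=float)
    shape = np.where(
        t >= 0.0,
        np.exp(-np.maximum(t, 0.0) / tau_decay_ms)
        - np.exp(-np.maximum(t, 0.0) / tau_rise_ms),
        0.0,
    )
    tp = biexp_peak_time(tau_rise_ms, tau_decay_ms)
    norm = math.exp(-tp / tau_decay_ms) - math.exp(-tp / tau_rise_ms)
    return amplitude * shape / norm


def simulate_mipsc_train(cfg: MipsTrainConfig) -> tuple[Trace, GroundTruth]:
    """Poisson train of biexponential events in Gaussian baseline noise.

    Event amplitudes are log-normal with mean ``amp_mean`` and coefficient of
    variation ``amp_cv`` (log-normal guarantees positivity).  Events are
    inward (negative); ground truth lists onset times and amplitude
    magnitudes.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = round(cfg.duration * cfg.sampling_rate)

    n_events = rng.poisson(cfg.event_rate * cfg.duration) if cfg.event_rate > 0 else 0
    onsets = np.sort(rng.uniform(0.0, cfg.duration, n_events))
    if cfg.amp_cv > 0:
        sigma2 = math.log(1.0 + cfg.amp_cv**2)
        mu = math.log(cfg.amp_mean) - 0.5 * sigma2
        amps = rng.lognormal(mu, math.sqrt(sigma2), n_events)
    else:
        amps = np.full(n_events, cfg.amp_mean)

    samples = np.zeros(n_samples)
    kernel_ms = 8.0 * cfg.tau_decay
    kernel_n = int(round(kernel_ms * 1e-3 * cfg.sampling_rate))
    for onset, amp in zip(onsets, amps):
        i0 = int(math.ceil(onset * cfg.sampling_rate - 1e-9))
        i1 = min(i0 + kernel_n, n_samples)
        if i1 <= i0:
            continue
        t_ms = (np.arange(i0, i1) / cfg.sampling_rate - onset) * 1e3
        samples[i0:i1] -= biexp_waveform(t_ms, amp, cfg.tau_rise, cfg.tau_decay)
    if cfg.baseline_noise_sd > 0:
        samples += rng.normal(0.0, cfg.baseline_noise_sd, n_samples)

    trace = Trace(samples, cfg.sampling_rate)
    gt = GroundTruth(
        event_onsets=[float(t) for t in onsets],
        event_amplitudes=[float(a) for a in amps],
        params=asdict(cfg),
    )
    return trace, gt


# ----------------------------------------------------------------------
# dose-response tables


def hill_current(conc: np.ndarray, ec50: float, hill: float, imax: float) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    return imax * c**hill / (c**hill + ec50**hill)


def simulate_dose_response(
    ec50: float,
    hill: float,
    imax: float,
    concentrations: Sequence[float],
    noise_cv: float,
    n_cells: int,
    seed: int,
) -> pd.DataFrame:
    """Per-cell peak currents on a Hill curve with multiplicative noise.

    Returns a table with columns ``cell_id, concentration_um, peak_pa``.
    """
    if not (ec50 > 0 and hill > 0 and imax > 0):
        raise ConfigurationError("ec50, hill and imax must all be > 0")
    if len(concentrations) == 0:
        raise ConfigurationError("concentration list is empty")
    if n_cells < 1:
        raise ConfigurationError("need at least one cell")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    ideal = hill_current(conc, ec50, hill, imax)

    rows = []
    for cell in range(n_cells):
        if noise_cv > 0:
            sigma2 = math.log(1.0 + noise_cv**2)
            factor = rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2), conc.size)
        else:
            factor = np.ones(conc.size)
        for c, i in zip(conc, ideal * factor):
            rows.append({"cell_id": cell, "concentration_um": c, "peak_pa": float(i)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# tonic block


def simulate_tonic_block(
    cfg: ChannelSimConfig, block_onset: float, drug_label: str = "strychnine"
) -> tuple[Trace, GroundTruth]:
    """Two-state ensemble current abolished by a blocker step.

    Channels gate at the configured rates before ``block_onset``; afterwards
    all channels are forced closed and only baseline noise remains.  The
    block is attached as a ``(drug_label, block_onset, duration)`` annotation.
    """
    if not (0.0 < block_onset < cfg.duration):
        raise ConfigurationError("block_onset must lie inside the trace")
    rng = np.random.default_rng(cfg.seed)
    n_samples = round(cfg.duration * cfg.sampling_rate)
    grid = np.arange(n_samples) / cfg.sampling_rate

    p0 = cfg.p_open_stationary
    n_open0 = int(rng.binomial(cfg.n_channels, p0)) if cfg.n_channels else 0
    edges = np.array([0.0, block_onset])
    jt, jc = _gillespie_open_count(
        cfg.n_channels, np.array([cfg.k_open]), cfg.k_close, edges, n_open0, rng
    )
    # blocker forces every channel closed from block_onset on
    jt = np.append(jt, block_onset)
    jc = np.append(jc, 0)
    open_grid = _sample_on_grid(jt, jc, grid)
    samples = -cfg.unitary_current * open_grid.astype(float)
    if cfg.baseline_noise_sd > 0:
        samples += rng.normal(0.0, cfg.baseline_noise_sd, n_samples)

    trace = Trace(
        samples,
        cfg.sampling_rate,
        annotations=[Annotation(drug_label, block_onset, cfg.duration)],
    )
    gt = GroundTruth(
        params={
            **asdict(cfg),
            "block_onset": block_onset,
            "expected_holding_shift_pa": cfg.n_channels * cfg.unitary_current * p0,
            "expected_variance_shift_pa2": (
                cfg.unitary_current**2 * cfg.n_channels * p0 * (1.0 - p0)
            ),
        }
    )
    return trace, gt
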