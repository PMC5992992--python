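"""Whole-cell current trace container and file I/O.

A :class:`Trace` is a uniformly sampled current recording in pA with the
convention that inward current is negative.  Drug applications are carried
as ``(label, onset_s, offset_s)`` annotations.  Traces round-trip through
a commented CSV format and an equivalent HDF5 layout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Annotation",
    "Trace",
    "read_trace_csv",
    "write_trace_csv",
    "read_trace_hdf5",
    "write_trace_hdf5",
    "read_trace",
    "write_trace",
]


@dataclass(frozen=True)
class Annotation:
    """A labelled application window, e.g. ``("strychnine", 30.0, 60.0)``."""

    label: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.onset) and np.isfinite(self.offset)):
            raise ValueError("annotation times must be finite")
        if self.offset < self.onset:
            raise ValueError("annotation offset precedes onset")


@dataclass
class Trace:
    """Uniformly sampled whole-cell current.

    Parameters
    ----------
    samples : ndarray
        Current in pA; inward current is negative.
    sampling_rate : float
        Samples per second (Hz).
    start_time : float
        Time of the first sample in seconds.
    annotations : list of :class:`Annotation`
        Drug-application windows, each within the trace extent.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        end = self.start_time + self.duration
        for ann in self.annotations:
            if ann.onset < self.start_time - 1e-9 or ann.offset > end + 1e-9:
                raise ValueError(
                    f"annotation {ann.label!r} lies outside the trace extent"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Nearest sample index at or before time ``t`` (clipped to range)."""
        i = int(np.floor((t - self.start_time) * self.sampling_rate + 1e-9))
        return min(max(i, 0), self.n_samples - 1)

    def segment(self, t0: float, t1: float) -> "Trace":
        """Sub-trace covering ``[t0, t1)``; annotations are not propagated."""
        if t1 <= t0:
            raise ValueError("empty segment requested")
        i0 = self.index_of(t0)
        i1 = int(np.floor((t1 - self.start_time) * self.sampling_rate + 1e-9))
        i1 = min(max(i1, i0 + 1), self.n_samples)
        return Trace(
            samples=self.samples[i0:i1].copy(),
            sampling_rate=self.sampling_rate,
            start_time=self.start_time + i0 / self.sampling_rate,
        )

    def window_slice(self, window: tuple[float, float]) -> np.ndarray:
        """Samples covering the closed-open time window."""
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window end must exceed start")
        if t0 < self.start_time - 1e-9 or t1 > self.start_time + self.duration + 1e-9:
            raise ValueError("window outside trace")
        i0 = self.index_of(t0)
        i1 = int(np.floor((t1 - self.start_time) * self.sampling_rate + 1e-9))
        return self.samples[i0:max(i1, i0 + 1)]

    def find_annotation(self, label: str) -> Annotation:
        for ann in self.annotations:
            if ann.label == label:
                return ann
        raise KeyError(f"trace carries no annotation labelled {label!r}")


# -- CSV format ---------------------------------------------------------
#   # sampling_rate_hz=20000
#   # units=pA
#   # start_time_s=0.0
#   # annotation=strychnine,30.0,60.0
#   <one sample per line>

def write_trace_csv(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz={trace.sampling_rate!r}\n")
        fh.write("# units=pA\n")
        fh.write(f"# start_time_s={trace.start_time!r}\n")
        for ann in trace.annotations:
            fh.write(f"# annotation={ann.label},{ann.onset!r},{ann.offset!r}\n")
        np.savetxt(fh, trace.samples, fmt="%.10g")


def read_trace_csv(path: str | Path) -> Trace:
    path = Path(path)
    rate = None
    start = 0.0
    annotations: list[Annotation] = []
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, value = body.split("=", 1)
            key = key.strip()
            if key == "sampling_rate_hz":
                rate = float(value)
            elif key == "start_time_s":
                start = float(value)
            elif key == "annotation":
                label, onset, offset = value.split(",")
                annotations.append(Annotation(label, float(onset), float(offset)))
    if rate is None:
        raise ValueError(f"{path}: missing '# sampling_rate_hz=' header")
    samples = np.loadtxt(path, comments="#", ndmin=1)
    return Trace(samples, rate, start, annotations)


# -- HDF5 format --------------------------------------------------------

def write_trace_hdf5(trace: Trace, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("trace/samples", data=trace.samples)
        ds.attrs["sampling_rate_hz"] = trace.sampling_rate
        ds.attrs["start_time_s"] = trace.start_time
        ds.attrs["units"] = "pA"
        ds.attrs["annotations"] = json.dumps(
            [[a.label, a.onset, a.offset] for a in trace.annotations]
        )


def read_trace_hdf5(path: str | Path) -> Trace:
    with h5py.File(path, "r") as fh:
        ds = fh["trace/samples"]
        samples = ds[()]
        rate = float(ds.attrs["sampling_rate_hz"])
        start = float(ds.attrs.get("start_time_s", 0.0))
        raw = ds.attrs.get("annotations", "[]")
        if isinstance(raw, bytes):
            raw = raw.decode()
        annotations = [Annotation(l, float(a), float(b)) for l, a, b in json.loads(raw)]
    return Trace(samples, rate, start, annotations)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Dispatch on extension: ``.h5``/``.hdf5`` binary, anything else CSV."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        write_trace_hdf5(trace, path)
    else:
        write_trace_csv(trace, path)


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_trace_hdf5(path)
    return read_trace_csv(path)
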