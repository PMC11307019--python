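"""Uniformly sampled single-channel recordings.

A :class:`Trace` is the common container for voltage- and current-clamp
data: a 1-D sample array, a sampling rate, and a unit tag (``"pA"`` for
currents, ``"mV"`` for potentials).  Traces round-trip through a plain
CSV format (columns ``time_s, value``, units recorded in the header
comment) so that synthetic and exported recordings share one path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

VALID_UNITS = ("pA", "mV")


@dataclass
class Trace:
    """A uniformly sampled recording.

    Parameters
    ----------
    samples : ndarray
        Measured values, shape ``(n,)``.
    sampling_rate : float
        Samples per second; must be positive.
    units : str
        ``"pA"`` (current clamp) or ``"mV"`` (voltage).
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    units: str
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("trace requires a non-empty 1-D sample array")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    def slice_time(self, t0: float, t1: float) -> np.ndarray:
        """Samples with time in ``[t0, t1)``."""
        i0 = int(np.ceil((t0 - self.start_time) * self.sampling_rate))
        i1 = int(np.ceil((t1 - self.start_time) * self.sampling_rate))
        i0 = max(i0, 0)
        if i1 <= i0:
            raise ValueError(f"empty time slice [{t0}, {t1})")
        return self.samples[i0:i1]

    def to_csv(self, path: str | Path) -> None:
        header = f"# units={self.units} sampling_rate={self.sampling_rate}\ntime_s,value"
        np.savetxt(
            path,
            np.column_stack([self.times, self.samples]),
            delimiter=",",
            header=header,
            comments="",
            fmt="%.9g",
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        with open(path) as fh:
            first = fh.readline().strip()
            rest = fh.read()
        meta = {}
        if first.startswith("#"):
            for tok in first.lstrip("# ").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        else:  # no metadata line: rewind
            rest = first + "\n" + rest
        data = np.loadtxt(io.StringIO(rest), delimiter=",", skiprows=1)
        times, values = data[:, 0], data[:, 1]
        if "sampling_rate" in meta:
            fs = float(meta["sampling_rate"])
        else:
            fs = 1.0 / float(np.median(np.diff(times)))
        return cls(values, fs, meta.get("units", "pA"), start_time=float(times[0]))
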