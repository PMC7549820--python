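"""Uniformly sampled scalar traces (field potential, Vm, calcium)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSignal:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : ndarray
        Sample values (mV for membrane potential, uV for field potentials,
        uM for calcium).
    dt : float
        Sampling interval in ms.
    t0 : float
        Time of the first sample in ms.
    units : str
        Unit label, informational only.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSignal values must be one-dimensional")
        if not (self.dt > 0):
            raise ValueError("sampling interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1) if self.values.size else 0.0

    def __len__(self) -> int:
        return self.values.size

    def slice(self, t_start: float, t_end: float) -> "TimeSignal":
        """Return the sub-signal with t_start <= t <= t_end."""
        t = self.times
        mask = (t >= t_start) & (t <= t_end)
        if not mask.any():
            raise ValueError("empty slice window")
        idx = np.where(mask)[0]
        return TimeSignal(self.values[idx], self.dt, t[idx[0]], self.units)

    def resample(self, dt_new: float) -> "TimeSignal":
        """Linear-interpolation resampling onto a new uniform grid."""
        t = self.times
        t_new = np.arange(self.t0, t[-1] + 0.5 * dt_new, dt_new)
        t_new = t_new[t_new <= t[-1] + 1e-12]
        return TimeSignal(np.interp(t_new, t, self.values), dt_new, self.t0, self.units)

    def to_text(self, path) -> None:
        """Write as two-column delimited text (time_ms, value)."""
        arr = np.column_stack([self.times, self.values])
        np.savetxt(path, arr, fmt="%.10g", delimiter="\t",
                   header=f"time_ms\tvalue_{self.units or 'au'}")

    @classmethod
    def from_text(cls, path, units: str = "") -> "TimeSignal":
        arr = np.loadtxt(path)
        t, v = arr[:, 0], arr[:, 1]
        dts = np.diff(t)
        if dts.size == 0:
            raise ValueError("signal file holds fewer than two samples")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling in signal file")
        return cls(v, float(dts[0]), float(t[0]), units)
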