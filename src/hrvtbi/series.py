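"""Core containers: waveforms, R-peak trains and RR-interval tachograms.

The tachogram (:class:`RRSeries`) is the central object of the pipeline:
every statistic downstream consumes an ordered sequence of RR intervals in
milliseconds, tagged with a subject id and an experimental phase.  Because
outlier trimming removes beats from the middle of a recording, each interval
carries an adjacency flag recording whether it immediately followed its
predecessor in the raw series; difference-based statistics (pNN bins, SD1,
lagged Poincare points) skip pairs broken by trimming rather than fabricate
spurious large differences across the gap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np


class PhaseLabel(str, enum.Enum):
    """Experimental phase: arm (T = TBI + hemorrhage, H = hemorrhage only)
    crossed with stage (b = baseline, h = during hemorrhage, p = post)."""

    Tb = "Tb"
    Th = "Th"
    Tp = "Tp"
    Hb = "Hb"
    Hh = "Hh"
    Hp = "Hp"

    @property
    def arm(self) -> str:
        return "tbi_hemorrhage" if self.value[0] == "T" else "control_hemorrhage"

    @property
    def stage(self) -> str:
        return self.value[1]


#: Stage suffix -> phase label, per arm.
TBI_PHASES = (PhaseLabel.Tb, PhaseLabel.Th, PhaseLabel.Tp)
CONTROL_PHASES = (PhaseLabel.Hb, PhaseLabel.Hh, PhaseLabel.Hp)


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested statistic."""


class ParameterError(ValueError):
    """Raised for out-of-range configuration values."""


@dataclass
class Waveform:
    """Uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in millivolts.
    sampling_rate : float
        Sampling frequency in Hz (> 0).
    start_time : float
        Time of the first sample, in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("waveform samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def copy_with(self, samples: np.ndarray) -> "Waveform":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class PeakTimes:
    """Detected R-peak times (seconds) with their amplitudes (mV)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ParameterError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class RRSeries:
    """Ordered RR intervals in milliseconds.

    ``adjacent[i]`` (i >= 1) is True when interval ``i`` immediately followed
    interval ``i - 1`` in the raw beat sequence; ``adjacent[0]`` is True by
    convention (it makes no claim).  A freshly detected tachogram has all
    flags True; :func:`hrvtbi.features.trim_outliers` clears flags at the
    boundaries of removed beats.
    """

    rr: np.ndarray
    subject_id: str = ""
    phase: PhaseLabel | None = None
    adjacent: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1:
            raise ParameterError("rr must be one-dimensional")
        if np.any(self.rr <= 0) or not np.all(np.isfinite(self.rr)):
            raise ParameterError("RR intervals must be positive and finite")
        if self.phase is not None and not isinstance(self.phase, PhaseLabel):
            self.phase = PhaseLabel(self.phase)
        if self.adjacent is None:
            self.adjacent = np.ones(self.rr.size, dtype=bool)
        else:
            self.adjacent = np.asarray(self.adjacent, dtype=bool)
            if self.adjacent.shape != self.rr.shape:
                raise ParameterError("adjacent flags must match rr in length")

    def __len__(self) -> int:
        return int(self.rr.size)

    @property
    def duration_s(self) -> float:
        """Total time spanned by the intervals, in seconds."""
        return float(self.rr.sum()) / 1000.0
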