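"""R-peak detection: band-pass filtering, half-wave cutting, peak picking.

The detector follows the classic rectify-then-pick structure: a zero-phase
band-pass filter isolates QRS energy (5-30 Hz by default), half-wave cutting
zeroes everything below a threshold so only positive R deflections survive,
and local maxima are selected greedily in descending amplitude subject to a
physiological refractory period.  This is intentionally simpler than
Pan-Tompkins; it is adequate for single-lead traces with a dominant R wave.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from .series import InsufficientDataError, ParameterError, PeakTimes, PhaseLabel, RRSeries, Waveform

#: Default QRS energy band (Hz).
DEFAULT_BAND = (5.0, 30.0)
#: Default refractory period (ms); caps heart rate at 300 bpm.
DEFAULT_REFRACTORY_MS = 200.0
#: Default peak threshold as a fraction of the rectified signal maximum.
DEFAULT_MIN_PROMINENCE = 0.4


def bandpass_filter(w: Waveform, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1], order: int = 2) -> Waveform:
    """Zero-phase Butterworth band-pass; removes DC and baseline drift."""
    nyquist = w.sampling_rate / 2.0
    if not 0 < low < high < nyquist:
        raise ParameterError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyquist} Hz)"
        )
    sos = _signal.butter(order, [low, high], btype="bandpass", fs=w.sampling_rate, output="sos")
    return w.copy_with(_signal.sosfiltfilt(sos, w.samples))


def half_wave_cut(w: Waveform, threshold: float = 0.0) -> Waveform:
    """Zero samples below ``threshold`` (mV); samples >= threshold pass through."""
    return w.copy_with(np.where(w.samples >= threshold, w.samples, 0.0))


def detect_r_peaks(
    w: Waveform,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> PeakTimes:
    """Pick R peaks on a filtered, rectified trace.

    Local maxima at least ``min_prominence`` times the signal maximum are
    accepted in descending amplitude order, discarding any candidate within
    the refractory period of an already-accepted peak (this is the greedy
    behaviour of :func:`scipy.signal.find_peaks` with a ``distance``
    constraint).  An all-zero trace yields an empty result.
    """
    if refractory_ms <= 0:
        raise ParameterError("refractory period must be positive")
    distance = int(np.round(refractory_ms / 1000.0 * w.sampling_rate))
    if distance < 1:
        raise ParameterError("sampling_rate too low to resolve the refractory period")
    peak_level = float(np.max(w.samples, initial=0.0))
    if peak_level <= 0:
        return PeakTimes(np.empty(0), np.empty(0))
    height = min_prominence * peak_level
    idx, props = _signal.find_peaks(w.samples, height=height, distance=distance)
    return PeakTimes(w.start_time + idx / w.sampling_rate, props["peak_heights"])


def peaks_to_rr(
    p: PeakTimes, subject_id: str = "", phase: PhaseLabel | str | None = None
) -> RRSeries:
    """Successive peak-to-peak intervals in ms; needs at least two peaks."""
    if len(p) < 2:
        raise InsufficientDataError("at least two peaks are required for RR intervals")
    return RRSeries(np.diff(p.times) * 1000.0, subject_id=subject_id, phase=phase)


def waveform_to_rr(
    w: Waveform,
    band: tuple[float, float] = DEFAULT_BAND,
    threshold: float = 0.0,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    polarity: str = "auto",
    subject_id: str = "",
    phase: PhaseLabel | str | None = None,
) -> RRSeries:
    """Full chain: filter -> (polarity) -> half-wave cut -> peaks -> tachogram.

    ``polarity`` is "auto" (invert when |min| exceeds |max| after filtering,
    so negative-dominant R deflections are handled), "positive" or "negative".
    """
    f = bandpass_filter(w, *band)
    if polarity not in ("auto", "positive", "negative"):
        raise ParameterError(f"unknown polarity {polarity!r}")
    invert = polarity == "negative" or (
        polarity == "auto" and abs(float(f.samples.min())) > abs(float(f.samples.max()))
    )
    if invert:
        f = f.copy_with(-f.samples)
    rect = half_wave_cut(f, threshold)
    peaks = detect_r_peaks(rect, refractory_ms=refractory_ms, min_prominence=min_prominence)
    return peaks_to_rr(peaks, subject_id=subject_id, phase=phase)
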