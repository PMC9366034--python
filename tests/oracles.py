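"""Brute-force reference implementations used only as test oracles.

Everything here is written with plain Python loops and ``math`` so that it
shares no code path with the package: direct transcriptions of the defining
formulas, at whatever cost in speed.
"""

from __future__ import annotations

import math


def mean(xs) -> float:
    xs = list(map(float, xs))
    return sum(xs) / len(xs)


def sample_sd(xs) -> float:
    xs = list(map(float, xs))
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def successive_diffs(xs) -> list[float]:
    xs = list(map(float, xs))
    return [b - a for a, b in zip(xs, xs[1:])]


def pnn_bins(diffs) -> list[float]:
    """Percentages for |d| in [0,10), [10,20), ..., [40,50), [50, inf)."""
    diffs = [abs(float(d)) for d in diffs]
    counts = [0] * 6
    for d in diffs:
        idx = min(int(d // 10), 5)
        counts[idx] += 1
    return [100.0 * c / len(diffs) for c in counts]


def pnn50(diffs) -> float:
    return pnn_bins(diffs)[5]


def poincare_sd1_sd2(rr) -> tuple[float, float]:
    d = successive_diffs(rr)
    var_d = sample_sd(d) ** 2
    sdnn2 = sample_sd(rr) ** 2
    sd1 = math.sqrt(var_d / 2.0)
    sd2 = math.sqrt(max(2.0 * sdnn2 - var_d / 2.0, 0.0))
    return sd1, sd2


def sd1_from_rotated_points(x, y) -> float:
    """SD1 as dispersion of order-1 Poincare points across the y = x line."""
    proj = [(yi - xi) / math.sqrt(2.0) for xi, yi in zip(x, y)]
    return sample_sd(proj)


def pooled_t(a, b) -> float:
    """Student's two-sample t with pooled variance, by the closed form."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * sample_sd(a) ** 2 + (nb - 1) * sample_sd(b) ** 2) / (na + nb - 2)
    return (mean(a) - mean(b)) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def dft_amplitude(xs, fs: float, freq: float) -> float:
    """Single-bin discrete Fourier amplitude of ``xs`` at ``freq`` Hz."""
    n = len(xs)
    re = sum(x * math.cos(2 * math.pi * freq * i / fs) for i, x in enumerate(xs))
    im = sum(x * math.sin(2 * math.pi * freq * i / fs) for i, x in enumerate(xs))
    return 2.0 * math.hypot(re, im) / n
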