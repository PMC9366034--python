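"""Seeded synthetic cohorts emulating the swine hemorrhage / TBI experiment.

No recordings were deposited with the study this pipeline models, so every
stage is exercised on synthetic data with the same structure: two arms of six
subjects (hemorrhage-only controls and hemorrhage + traumatic brain injury),
three recorded phases per subject (baseline, during hemorrhage, post), and a
beat-to-beat interval process whose successive-difference distribution is
bimodal at baseline — mass near 0-9 ms and 10-19 ms from autocorrelated
Gaussian fluctuation, plus a >= 50 ms mode from sporadic large excursions —
and collapses into the 0-9 ms bin after TBI.

The RR generative model is deliberately phenomenological::

    rr_i = max(rr_floor, mean + g_i + j_i)

where ``g`` is a stationary AR(1) Gaussian process and ``j`` a Bernoulli
(jump_prob) excursion of magnitude ``jump_scale`` with random sign.  The
Gaussian variance is set to ``target_sdnn**2 - jump_prob * jump_scale**2``
(clamped at zero) so the series' total standard deviation matches the
requested SDNN whenever the jump component alone does not exceed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .series import (
    CONTROL_PHASES,
    TBI_PHASES,
    ParameterError,
    PhaseLabel,
    RRSeries,
    Waveform,
)

#: Physiological floor for a generated RR interval (ms); keeps pulses separable.
RR_FLOOR_MS = 200.0


@dataclass(frozen=True)
class RRGenParams:
    """Targets for one generated RR series.

    target_mean_rr / target_sdnn are in ms; ``jump_prob`` is the per-beat
    probability of a large excursion of scale ``jump_scale`` ms;
    ``ar_coefficient`` in [0, 1) sets the beat-to-beat correlation of the
    Gaussian component; ``duration`` is the recording length in seconds.
    """

    target_mean_rr: float = 600.0
    target_sdnn: float = 40.0
    jump_prob: float = 0.1
    jump_scale: float = 60.0
    ar_coefficient: float = 0.4
    duration: float = 300.0

    def __post_init__(self) -> None:
        if self.target_mean_rr <= 0:
            raise ParameterError("target_mean_rr must be positive")
        if self.target_sdnn < 0:
            raise ParameterError("target_sdnn must be non-negative")
        if not 0.0 <= self.jump_prob <= 1.0:
            raise ParameterError("jump_prob must be a probability")
        if self.jump_scale < 0:
            raise ParameterError("jump_scale must be non-negative")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ParameterError("ar_coefficient must be in [0, 1)")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")

    @property
    def effective_jump_scale(self) -> float:
        """Jump magnitude (ms) after capping the jump component's variance at
        half the SDNN budget, so a small-SDNN series never degenerates into a
        constant trace waiting on rare jumps."""
        if self.jump_prob == 0.0 or self.jump_scale == 0.0:
            return self.jump_scale
        cap = self.target_sdnn * np.sqrt(0.5 / self.jump_prob)
        return float(min(self.jump_scale, cap))

    @property
    def gaussian_sd(self) -> float:
        """Marginal SD of the AR(1) component implied by the SDNN target."""
        var = self.target_sdnn**2 - self.jump_prob * self.effective_jump_scale**2
        return float(np.sqrt(max(var, 0.0)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_rr_series(
    params: RRGenParams,
    seed,
    subject_id: str = "",
    phase: PhaseLabel | str | None = None,
) -> RRSeries:
    """Draw an RR tachogram from the AR(1) + jump mixture.

    Beats are emitted until their cumulative time first reaches
    ``params.duration``, so the series spans the requested duration to within
    one beat.  Fixed (params, seed) gives bit-identical output.
    """
    rng = _as_rng(seed)
    mean, sd_g, phi = params.target_mean_rr, params.gaussian_sd, params.ar_coefficient

    rr_parts: list[np.ndarray] = []
    total_ms = 0.0
    target_ms = params.duration * 1000.0
    carry = None  # last AR state, for chunk continuation
    # Draw in chunks of the expected remaining beat count (+ margin).
    while total_ms < target_ms:
        n = int(np.ceil((target_ms - total_ms) / mean)) + 8
        if sd_g > 0:
            eps = rng.standard_normal(n) * sd_g * np.sqrt(1.0 - phi**2)
            if carry is None:
                x0 = rng.standard_normal() * sd_g  # stationary start
            else:
                x0 = carry
            # x_i = phi * x_{i-1} + eps_i, vectorised as an IIR filter
            zi = _signal.lfiltic([1.0], [1.0, -phi], [x0])
            g, _ = _signal.lfilter([1.0], [1.0, -phi], eps, zi=zi)
            carry = float(g[-1])
        else:
            g = np.zeros(n)
            carry = 0.0
        jumps = rng.random(n) < params.jump_prob
        signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        rr = np.maximum(
            mean + g + jumps * signs * params.effective_jump_scale, RR_FLOOR_MS
        )
        rr_parts.append(rr)
        total_ms += float(rr.sum())

    rr = np.concatenate(rr_parts)
    stop = int(np.searchsorted(np.cumsum(rr), target_ms - 1e-9)) + 1
    return RRSeries(rr[:stop], subject_id=subject_id, phase=phase)


#: Gaussian R-wave pulse width (standard deviation, seconds).
PULSE_SIGMA_S = 0.008
#: Effective full pulse width used for separability checks (seconds).
PULSE_WIDTH_S = 6 * PULSE_SIGMA_S


def generate_ecg_waveform(
    rr: RRSeries,
    sampling_rate: float = 1000.0,
    noise_sd: float = 0.0,
    seed=0,
    amplitude: float = 1.0,
    pad: float = 0.25,
) -> tuple[Waveform, np.ndarray]:
    """Render a tachogram as a pulse-train voltage trace.

    A positive Gaussian pulse of width :data:`PULSE_SIGMA_S` is centred at each
    beat time (the first beat at t = 0, then cumulative RR sums), with additive
    white Gaussian noise of ``noise_sd`` mV.  Returns the waveform together
    with the ground-truth peak times in seconds.
    """
    if sampling_rate < 250:
        raise ParameterError("sampling_rate must be at least 250 Hz")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    if float(np.min(rr.rr)) < 2 * PULSE_WIDTH_S * 1000.0:
        raise ParameterError(
            f"RR interval shorter than two pulse widths "
            f"({2 * PULSE_WIDTH_S * 1000:.0f} ms): pulses would merge"
        )
    rng = _as_rng(seed)
    peak_times = np.concatenate([[0.0], np.cumsum(rr.rr) / 1000.0])
    start = -pad
    n = int(np.round((peak_times[-1] + 2 * pad) * sampling_rate)) + 1
    t = start + np.arange(n) / sampling_rate
    samples = np.zeros(n)
    # Each pulse only spans ~+/-5 sigma; add locally for speed.
    half = int(np.ceil(5 * PULSE_SIGMA_S * sampling_rate))
    for tp in peak_times:
        c = int(np.round((tp - start) * sampling_rate))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        samples[lo:hi] += amplitude * np.exp(
            -0.5 * ((t[lo:hi] - tp) / PULSE_SIGMA_S) ** 2
        )
    if noise_sd > 0:
        samples = samples + rng.standard_normal(n) * noise_sd
    return Waveform(samples, sampling_rate, start_time=start), peak_times


@dataclass(frozen=True)
class EffectSizes:
    """Amplitude multipliers for the TBI arm's Th/Tp phases.

    The effect scales target_sdnn and jump_scale together while leaving
    jump_prob untouched: a uniform shrinkage of all beat-to-beat excursion
    magnitudes.  This collapses SDNN, pNN50, SD1 and SD2, moves the majority
    of |dRR| into the 0-9 ms bin and empties the >= 50 ms bin, yet preserves
    the SD1/SD2 ratio — the signature of variability loss after TBI in which
    short- and long-term variability fall in proportion.  Defaults: 35% of
    baseline during hemorrhage, 25% after.
    """

    th: float = 0.35
    tp: float = 0.25


@dataclass(frozen=True)
class Heterogeneity:
    """Between-subject lognormal spread (sigma of the log multiplier).

    Applied independently per subject-phase draw so that, within the control
    arm, every phase is an iid draw from one distribution.  The variability
    spreads are wide so that the two arms overlap the way real cohorts do:
    group contrasts are clearly significant at n = 6 per arm while a linear
    classifier still makes occasional errors, rather than the arms being
    trivially separable.  Mean heart rate varies substantially between
    animals (hemorrhage provokes anything from strong compensatory
    tachycardia to relative bradycardia), which makes mean RR a large-scale
    nuisance feature for the classifier stage.
    """

    mean_rr: float = 0.25
    sdnn: float = 0.5
    jump_prob: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """Study design: arm sizes, phase durations (s) and effect sizes."""

    arm_size: int = 6
    baseline_duration: float = 22 * 60.0
    hemorrhage_duration: float = 5 * 60.0
    post_duration: float = 5 * 60.0
    baseline: RRGenParams = field(default_factory=lambda: RRGenParams())
    effects: EffectSizes = field(default_factory=EffectSizes)
    heterogeneity: Heterogeneity = field(default_factory=Heterogeneity)

    def __post_init__(self) -> None:
        if self.arm_size < 1:
            raise ParameterError("arm_size must be positive")
        for d in (self.baseline_duration, self.hemorrhage_duration, self.post_duration):
            if d <= 0:
                raise ParameterError("phase durations must be positive")

    def phase_duration(self, phase: PhaseLabel) -> float:
        return {
            "b": self.baseline_duration,
            "h": self.hemorrhage_duration,
            "p": self.post_duration,
        }[phase.stage]

    def phase_effect(self, phase: PhaseLabel) -> float:
        if phase is PhaseLabel.Th:
            return self.effects.th
        if phase is PhaseLabel.Tp:
            return self.effects.tp
        return 1.0


@dataclass
class SubjectRecord:
    subject_id: str
    arm: str
    phases: dict[PhaseLabel, RRSeries]
    params: dict[PhaseLabel, RRGenParams]


@dataclass
class Cohort:
    config: CohortConfig
    seed: int
    subjects: list[SubjectRecord]

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


def _subject_phase_params(
    config: CohortConfig, phase: PhaseLabel, rng: np.random.Generator
) -> RRGenParams:
    """Draw one subject-phase's generator targets around the arm/phase means."""
    het = config.heterogeneity
    base = config.baseline
    effect = config.phase_effect(phase)
    mean_rr = base.target_mean_rr * np.exp(rng.normal(0.0, het.mean_rr))
    sdnn = base.target_sdnn * effect * np.exp(rng.normal(0.0, het.sdnn))
    jump_p = min(base.jump_prob * np.exp(rng.normal(0.0, het.jump_prob)), 1.0)
    return replace(
        base,
        target_mean_rr=float(mean_rr),
        target_sdnn=float(sdnn),
        jump_prob=float(jump_p),
        jump_scale=base.jump_scale * effect,
        duration=config.phase_duration(phase),
    )


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Simulate the full two-arm cohort.

    Control subjects (H01..) get phases Hb/Hh/Hp drawn from statistically
    identical parameters; TBI subjects (T01..) share the baseline distribution
    but have Th/Tp variability shrunk by the configured effect sizes.  The
    global seed expands to per-(subject, phase) sub-seeds through a
    counter-keyed :class:`numpy.random.SeedSequence`, so any subject-phase is
    reproducible in isolation.
    """
    config = config or CohortConfig()
    subjects: list[SubjectRecord] = []
    arms = [
        ("control_hemorrhage", "H", CONTROL_PHASES),
        ("tbi_hemorrhage", "T", TBI_PHASES),
    ]
    for arm_idx, (arm, prefix, phases) in enumerate(arms):
        for s in range(config.arm_size):
            sid = f"{prefix}{s + 1:02d}"
            phase_series: dict[PhaseLabel, RRSeries] = {}
            phase_params: dict[PhaseLabel, RRGenParams] = {}
            for p_idx, phase in enumerate(phases):
                ss = np.random.SeedSequence(
                    entropy=seed, spawn_key=(arm_idx, s, p_idx)
                )
                rng = np.random.default_rng(ss)
                params = _subject_phase_params(config, phase, rng)
                phase_params[phase] = params
                phase_series[phase] = generate_rr_series(
                    params, rng, subject_id=sid, phase=phase
                )
            subjects.append(SubjectRecord(sid, arm, phase_series, phase_params))
    return Cohort(config=config, seed=seed, subjects=subjects)
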