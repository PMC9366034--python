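"""Group comparisons, significance screening and stochastic validation.

Small-cohort HRV contrasts (6 vs 6 subjects) are compared with Student's
pooled-variance t-tests (Welch optional), or one-way ANOVA when more than two
groups are supplied.  No multiple-testing correction is applied; instead the
stochastic validation estimates how often significance arises by chance when
the 12 subjects are randomly reassigned into two groups of six, repeating the
t-test 100 times per trial over 10 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .features import PARAMETER_NAMES
from .series import InsufficientDataError, ParameterError

DEFAULT_ALPHA = 0.05

#: The six phase contrasts screened per parameter.  The first three are
#: injury-related (between arms post, and within the TBI arm over time) and
#: qualify a parameter as significant; the last three are control checks.
INJURY_CONTRASTS = (
    ("Hp_vs_Tp", "Hp", "Tp"),
    ("Tb_vs_Th", "Tb", "Th"),
    ("Tb_vs_Tp", "Tb", "Tp"),
)
CONTROL_CONTRASTS = (
    ("Hb_vs_Tb", "Hb", "Tb"),
    ("Hb_vs_Hh", "Hb", "Hh"),
    ("Hb_vs_Hp", "Hb", "Hp"),
)
ALL_CONTRASTS = INJURY_CONTRASTS + CONTROL_CONTRASTS


@dataclass(frozen=True)
class TestResult:
    parameter: str
    label: str
    statistic: float
    p_value: float
    alpha: float = DEFAULT_ALPHA
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(
    *groups,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
    parameter: str = "",
    label: str = "",
) -> TestResult:
    """Two groups: two-sided t-test (pooled variance by default).  More than
    two: one-way ANOVA.

    Degenerate zero-variance input follows the conventions: both groups
    constant with equal means gives statistic 0, p = 1; constant with unequal
    means is reported significant with p below the smallest positive float
    and flagged degenerate.
    """
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InsufficientDataError("each group needs at least two values")
    if len(arrays) == 2:
        a, b = arrays
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            if np.mean(a) == np.mean(b):
                return TestResult(parameter, label, 0.0, 1.0, alpha, degenerate=True)
            stat = np.inf if np.mean(a) > np.mean(b) else -np.inf
            return TestResult(
                parameter, label, float(stat), float(np.nextafter(0.0, 1.0)),
                alpha, degenerate=True,
            )
        stat, p = _stats.ttest_ind(a, b, equal_var=not welch)
    else:
        stat, p = _stats.f_oneway(*arrays)
    return TestResult(parameter, label, float(stat), float(p), alpha)


@dataclass
class ScreeningResult:
    """Per-parameter contrasts and the resulting significant-parameter set.

    A parameter is significant when any injury-related contrast rejects;
    control contrasts are reported but never qualify."""

    alpha: float
    results: dict[tuple[str, str], TestResult]
    significant: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        sig = set()
        injury = {c[0] for c in INJURY_CONTRASTS}
        for (param, label), res in self.results.items():
            if label in injury and res.significant:
                sig.add(param)
        self.significant = frozenset(sig)

    @property
    def significant_indices(self) -> frozenset[int]:
        """Significant set in classifier numbering (1-R ... 8-sd_ratio)."""
        return frozenset(
            i + 1 for i, name in enumerate(PARAMETER_NAMES) if name in self.significant
        )

    def flagged_instances(self) -> list[tuple[str, str]]:
        """(parameter, contrast) pairs where an injury contrast rejected."""
        injury = {c[0] for c in INJURY_CONTRASTS}
        return [
            key for key, res in self.results.items()
            if key[1] in injury and res.significant
        ]


def _phase_values(features: pd.DataFrame, parameter: str, phase: str) -> np.ndarray:
    sub = features.loc[features["phase"] == phase, parameter]
    return sub.to_numpy(dtype=float)


def screen_parameters(
    features: pd.DataFrame, alpha: float = DEFAULT_ALPHA, welch: bool = False
) -> ScreeningResult:
    """Run the six contrasts for each of the eight parameters.

    ``features`` is a cohort table (one row per subject-phase) with a
    ``phase`` column and one column per parameter.
    """
    needed = {"Hb", "Hh", "Hp", "Tb", "Th", "Tp"}
    present = set(features["phase"].unique())
    if not needed <= present:
        raise ParameterError(f"missing phases: {sorted(needed - present)}")
    results: dict[tuple[str, str], TestResult] = {}
    for param in PARAMETER_NAMES:
        for label, pa, pb in ALL_CONTRASTS:
            a = _phase_values(features, param, pa)
            b = _phase_values(features, param, pb)
            results[(param, label)] = compare_groups(
                a, b, alpha=alpha, welch=welch, parameter=param, label=label
            )
    return ScreeningResult(alpha=alpha, results=results)


@dataclass(frozen=True)
class StochasticResult:
    """Outcome of the random-reassignment validation for one quantity."""

    trial_counts: tuple[int, ...]  # significant tests per trial
    n_tests: int
    alpha: float

    @property
    def empirical_probability(self) -> float:
        total = self.n_tests * len(self.trial_counts)
        return sum(self.trial_counts) / total if total else float("nan")


def stochastic_validation(
    values,
    n_tests: int = 100,
    n_trials: int = 10,
    alpha: float = DEFAULT_ALPHA,
    seed=0,
    group_size: int | None = None,
    welch: bool = False,
) -> StochasticResult:
    """Randomly reassign the 12 subjects into two groups of six, t-test, and
    count how often significance arises; ``n_tests`` tests per trial over
    ``n_trials`` trials.

    Splits are sampled uniformly with replacement (random draws, not an
    enumeration of the 462 distinct splits).  Subject counts other than 12
    are accepted with a warning-free even split unless ``group_size`` says
    otherwise.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if group_size is None:
        group_size = n // 2
    if not 2 <= group_size <= n - 2:
        raise ParameterError("group_size leaves too few subjects per group")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_trials):
        c = 0
        for _ in range(n_tests):
            perm = rng.permutation(n)
            res = compare_groups(
                values[perm[:group_size]], values[perm[group_size:]],
                alpha=alpha, welch=welch,
            )
            c += int(res.significant)
        counts.append(c)
    return StochasticResult(tuple(counts), n_tests, alpha)


def validate_screening(
    features: pd.DataFrame,
    screening: ScreeningResult,
    n_tests: int = 100,
    n_trials: int = 10,
    alpha: float = DEFAULT_ALPHA,
    seed=0,
) -> dict:
    """Run the stochastic validation for every flagged (parameter, contrast).

    Each flagged instance gets its own 100 x 10 schedule on the pooled 12
    values of its two phase groups; a pooled probability across instances is
    reported as well.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out: dict[tuple[str, str], StochasticResult] = {}
    phase_of = {label: (pa, pb) for label, pa, pb in ALL_CONTRASTS}
    for (param, label), child in zip(
        screening.flagged_instances(),
        ss.spawn(max(len(screening.flagged_instances()), 1)),
    ):
        pa, pb = phase_of[label]
        pooled = np.concatenate(
            [_phase_values(features, param, pa), _phase_values(features, param, pb)]
        )
        out[(param, label)] = stochastic_validation(
            pooled, n_tests=n_tests, n_trials=n_trials, alpha=alpha,
            seed=np.random.default_rng(child),
        )
    probs = [r.empirical_probability for r in out.values()]
    return {
        "instances": out,
        "pooled_probability": float(np.mean(probs)) if probs else float("nan"),
    }
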