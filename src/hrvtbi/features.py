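"""Time-domain and Poincare HRV parameters from a trimmed tachogram.

Eight parameters are computed per subject-phase, numbered as used throughout
the classifier stage:

1. ``R``       mean instantaneous heart rate (beats/min), h_i = 60000 / rr_i
2. ``SDR``     sample SD of instantaneous heart rate (beats/min)
3. ``mean_rr`` arithmetic mean RR (ms)
4. ``SDNN``    sample SD of RR (ms), n-1 denominator
5. ``pNN50``   percentage of successive |dRR| >= 50 ms
6. ``SD1``     Poincare short-term descriptor, sqrt(Var(dRR) / 2) (ms)
7. ``SD2``     Poincare long-term descriptor, sqrt(2 SDNN^2 - Var(dRR) / 2) (ms)
8. ``sd_ratio`` SD1 / SD2 (unitless)

Under these definitions SD1^2 + SD2^2 = 2 SDNN^2 identically.  The full pNN
distribution bins |dRR| into half-open 10 ms classes [0,10) ... [40,50) and
[50, inf); pNN50 is the top bin, using >= 50 ms.  Outlier trimming (2.5% of
beats from each value tail by default) precedes everything, and every
difference-based quantity skips beat pairs whose adjacency was broken by
trimming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import InsufficientDataError, ParameterError, PhaseLabel, RRSeries

#: Classifier numbering of the eight parameters (1-based index -> column name).
PARAMETER_NAMES: tuple[str, ...] = (
    "R",
    "SDR",
    "mean_rr",
    "SDNN",
    "pNN50",
    "SD1",
    "SD2",
    "sd_ratio",
)

#: pNN bin edges in ms (half-open; final bin is [50, inf)).
PNN_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
PNN_LABELS = ("pNN1_10", "pNN10_20", "pNN20_30", "pNN30_40", "pNN40_50", "pNN50")

DEFAULT_TRIM = 0.025


def trim_outliers(rr: RRSeries, tail_fraction: float = DEFAULT_TRIM) -> RRSeries:
    """Drop the k = floor(tail_fraction * n) largest and smallest RR values.

    Selection is by value (ties broken by position, earliest first); the
    survivors keep their original order, and adjacency flags are cleared where
    a removed beat leaves a gap.
    """
    if not 0.0 <= tail_fraction < 0.5:
        raise ParameterError("tail_fraction must be in [0, 0.5)")
    n = len(rr)
    if n == 0:
        raise InsufficientDataError("cannot trim an empty series")
    k = int(np.floor(tail_fraction * n))
    if k == 0:
        return RRSeries(rr.rr.copy(), rr.subject_id, rr.phase, rr.adjacent.copy())
    order = np.argsort(rr.rr, kind="stable")
    drop = np.zeros(n, dtype=bool)
    drop[order[:k]] = True
    drop[order[-k:]] = True
    keep_idx = np.flatnonzero(~drop)
    new_adj = np.empty(keep_idx.size, dtype=bool)
    new_adj[0] = True
    new_adj[1:] = (np.diff(keep_idx) == 1) & rr.adjacent[keep_idx[1:]]
    return RRSeries(rr.rr[keep_idx], rr.subject_id, rr.phase, new_adj)


def compute_time_domain(rr: RRSeries) -> dict[str, float]:
    """Mean/SD of RR and of instantaneous heart rate (R, SDR, mean_rr, SDNN)."""
    if len(rr) < 2:
        raise InsufficientDataError("need at least two intervals")
    hr = 60000.0 / rr.rr
    return {
        "R": float(np.mean(hr)),
        "SDR": float(np.std(hr, ddof=1)),
        "mean_rr": float(np.mean(rr.rr)),
        "SDNN": float(np.std(rr.rr, ddof=1)),
    }


def successive_differences(rr: RRSeries, signed: bool = False) -> np.ndarray:
    """Differences rr[i] - rr[i-1] over adjacency-intact pairs.

    Pairs broken by trimming are skipped.  Returns |d| unless ``signed``.
    """
    if len(rr) < 2:
        raise InsufficientDataError("need at least two intervals")
    valid = rr.adjacent[1:]
    d = np.diff(rr.rr)[valid]
    if d.size == 0:
        raise InsufficientDataError("no adjacency-intact interval pairs")
    return d if signed else np.abs(d)


@dataclass(frozen=True)
class PNNDistribution:
    """Percentages of |dRR| per 10 ms class; ``pNN50`` is the [50, inf) bin."""

    percentages: tuple[float, ...]  # aligned with PNN_LABELS
    n_diffs: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PNN_LABELS, self.percentages))

    @property
    def pNN50(self) -> float:
        return self.percentages[-1]


def pnn_distribution(diffs: np.ndarray) -> PNNDistribution:
    """Bin |dRR| values into the six half-open pNN classes (percent of pairs)."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise InsufficientDataError("no successive differences to bin")
    edges = np.concatenate([PNN_EDGES, [np.inf]])
    counts, _ = np.histogram(np.abs(diffs), bins=edges)
    return PNNDistribution(tuple(100.0 * counts / diffs.size), int(diffs.size))


def poincare_descriptors(rr: RRSeries) -> tuple[float, float, float]:
    """(SD1, SD2, SD1/SD2) from the successive-difference variance.

    SD1 = sqrt(Var(dRR)/2) measures dispersion across the Poincare identity
    line (beat-to-beat variability); SD2 = sqrt(2 SDNN^2 - Var(dRR)/2) the
    dispersion along it.  A negative SD2 radicand (possible when trimming
    decouples the two variances) is clamped to zero with a warning; the ratio
    is NaN when SD2 = 0.
    """
    if len(rr) < 3:
        raise InsufficientDataError("need at least three intervals")
    d = successive_differences(rr, signed=True)
    if d.size < 2:
        raise InsufficientDataError("need at least two interval pairs")
    var_d = float(np.var(d, ddof=1))
    sdnn = float(np.std(rr.rr, ddof=1))
    sd1 = float(np.sqrt(var_d / 2.0))
    radicand = 2.0 * sdnn**2 - var_d / 2.0
    if radicand < 0:
        warnings.warn("SD2 radicand negative; clamping to zero", RuntimeWarning)
        radicand = 0.0
    sd2 = float(np.sqrt(radicand))
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    return sd1, sd2, ratio


def poincare_points(rr: RRSeries, order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Lagged scatter pairs: order 1 = (RR_n, RR_n+1); order 2 = successive
    difference pairs (RR_n+1 - RR_n, RR_n+2 - RR_n+1).  Pairs spanning a
    trimmed gap are excluded."""
    if order not in (1, 2):
        raise ParameterError("order must be 1 or 2")
    if len(rr) <= order:
        raise InsufficientDataError("series shorter than the requested lag")
    adj = rr.adjacent
    if order == 1:
        valid = adj[1:]
        return rr.rr[:-1][valid], rr.rr[1:][valid]
    d = np.diff(rr.rr)
    valid = adj[1:-1] & adj[2:]
    x, y = d[:-1][valid], d[1:][valid]
    if x.size == 0:
        raise InsufficientDataError("no adjacency-intact triples")
    return x, y


@dataclass(frozen=True)
class HRVFeatures:
    """All eight parameters plus the pNN distribution for one subject-phase."""

    subject_id: str
    phase: PhaseLabel | None
    R: float
    SDR: float
    mean_rr: float
    SDNN: float
    pnn: PNNDistribution
    SD1: float
    SD2: float
    sd_ratio: float
    n_beats: int

    @property
    def pNN50(self) -> float:
        return self.pnn.pNN50

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "subject_id": self.subject_id,
            "arm": self.phase.arm if self.phase else "",
            "phase": self.phase.value if self.phase else "",
            "R": self.R,
            "SDR": self.SDR,
            "mean_rr": self.mean_rr,
            "SDNN": self.SDNN,
        }
        row.update(self.pnn.as_dict())
        row.update({"SD1": self.SD1, "SD2": self.SD2, "sd_ratio": self.sd_ratio,
                    "n_beats": self.n_beats})
        return row

    def vector(self) -> np.ndarray:
        """The eight parameters in classifier numbering order."""
        return np.array(
            [self.R, self.SDR, self.mean_rr, self.SDNN, self.pNN50,
             self.SD1, self.SD2, self.sd_ratio]
        )


def compute_features(rr: RRSeries, trim: float = DEFAULT_TRIM) -> HRVFeatures:
    """Trim the tachogram then compute every parameter."""
    trimmed = trim_outliers(rr, trim)
    td = compute_time_domain(trimmed)
    pnn = pnn_distribution(successive_differences(trimmed))
    sd1, sd2, ratio = poincare_descriptors(trimmed)
    return HRVFeatures(
        subject_id=rr.subject_id,
        phase=rr.phase,
        R=td["R"],
        SDR=td["SDR"],
        mean_rr=td["mean_rr"],
        SDNN=td["SDNN"],
        pnn=pnn,
        SD1=sd1,
        SD2=sd2,
        sd_ratio=ratio,
        n_beats=len(trimmed),
    )


#: Columns of a cohort feature table, in output order.
FEATURE_COLUMNS = (
    "subject_id", "arm", "phase", "R", "SDR", "mean_rr", "SDNN",
    *PNN_LABELS, "SD1", "SD2", "sd_ratio", "n_beats",
)


def cohort_feature_table(series: list[RRSeries], trim: float = DEFAULT_TRIM) -> pd.DataFrame:
    """One row per subject-phase, columns per :data:`FEATURE_COLUMNS`."""
    rows = [compute_features(rr, trim).as_row() for rr in series]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
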