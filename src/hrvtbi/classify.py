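"""Linear-SVM subset selection with repeated one-subject-out evaluation.

Parameter subsets of the eight HRV features are enumerated (22 by default:
all contiguous index ranges starting at 1, 2 or 3, plus incremental prefixes
of the significant set), each trained as a soft-margin linear SVM on the
post-phase features of the 12 subjects, and scored by repeatedly holding out
one subject per arm as test data.  Per-repeat weight vectors are averaged
into a "mean model".

Features are fed to the SVM in raw units by default, libsvm-style with no
scaling.  This is deliberate: the parameters live on very different scales
(mean RR ~600 ms against SD1 of a few ms), so subsets that include
uninformative large-scale parameters pay a real accuracy penalty, and subset
selection has teeth.  Per-fold standardisation is available via
``standardize=True``, which makes accuracy invariant to per-column rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import PARAMETER_NAMES
from .series import ParameterError

#: Default significant parameter set in classifier numbering
#: (2-SDR, 4-SDNN, 5-pNN50, 6-SD1, 7-SD2).
DEFAULT_SIGNIFICANT = frozenset({2, 4, 5, 6, 7})

#: Arm label -> class sign used by the decision function (TBI positive).
CLASS_OF_ARM = {"control_hemorrhage": 0, "tbi_hemorrhage": 1}

PHASE_POLICIES = {
    "post": ("Hp", "Tp"),
    "hemorrhage": ("Hh", "Th"),
    "baseline": ("Hb", "Tb"),
}


@dataclass(frozen=True)
class ParameterSubset:
    """Sorted parameter indices (1-8) plus the share that passed screening."""

    indices: tuple[int, ...]
    significant_fraction: float
    family: str = ""

    def __post_init__(self) -> None:
        if len(self.indices) < 2:
            raise ParameterError("a subset needs at least two parameters")
        if tuple(sorted(set(self.indices))) != self.indices:
            raise ParameterError("indices must be sorted and unique")
        if not set(self.indices) <= set(range(1, 9)):
            raise ParameterError("indices must lie in 1..8")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(PARAMETER_NAMES[i - 1] for i in self.indices)

    @property
    def label(self) -> str:
        """Table-style label: contiguous runs >= 3 render as 'i-j'."""
        idx = self.indices
        if len(idx) >= 3 and idx == tuple(range(idx[0], idx[-1] + 1)):
            return f"{idx[0]}-{idx[-1]}"
        return ",".join(str(i) for i in idx)


def _fraction(indices: tuple[int, ...], significant: frozenset[int]) -> float:
    return 100.0 * len(set(indices) & significant) / len(indices)


def enumerate_models(
    significant: frozenset[int] | set[int] = DEFAULT_SIGNIFICANT,
) -> list[ParameterSubset]:
    """The default 22-subset enumeration.

    Contiguous ranges [i..j] for i in {1, 2, 3}, j > i (18 subsets), plus the
    incremental prefixes of the sorted significant set with at least two
    members (4 subsets when five parameters are significant).
    """
    significant = frozenset(significant)
    if not significant <= set(range(1, 9)):
        raise ParameterError("significant indices must lie in 1..8")
    subsets: list[ParameterSubset] = []
    for start in (1, 2, 3):
        for end in range(start + 1, 9):
            idx = tuple(range(start, end + 1))
            subsets.append(
                ParameterSubset(idx, _fraction(idx, significant), f"range{start}")
            )
    ordered = tuple(sorted(significant))
    for k in range(2, len(ordered) + 1):
        idx = ordered[:k]
        subsets.append(
            ParameterSubset(idx, _fraction(idx, significant), "significant_prefix")
        )
    return subsets


def build_feature_matrix(
    features: pd.DataFrame,
    subset: ParameterSubset,
    phase_policy: str = "post",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One raw (unstandardised) row per subject for the policy's phase pair.

    Returns (X, y, subject_ids) with y = 1 for the TBI arm.  Standardisation
    happens inside each training fold at fit time.
    """
    if phase_policy not in PHASE_POLICIES:
        raise ParameterError(f"unknown phase_policy {phase_policy!r}")
    control_phase, tbi_phase = PHASE_POLICIES[phase_policy]
    sub = features[features["phase"].isin([control_phase, tbi_phase])]
    missing = [c for c in subset.names if c not in sub.columns]
    if missing:
        raise ParameterError(f"feature table lacks columns {missing}")
    X = sub[list(subset.names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ParameterError("non-finite feature values in matrix")
    y = (sub["phase"] == tbi_phase).to_numpy(dtype=int)
    return X, y, sub["subject_id"].tolist()


@dataclass(frozen=True)
class LinearModel:
    """w . (x - center) / scale + b; positive decision => TBI."""

    subset: ParameterSubset | None
    weights: np.ndarray
    bias: float
    center: np.ndarray
    scale: np.ndarray

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.size:
            raise ParameterError("feature row does not cover the model subset")
        return ((X - self.center) / self.scale) @ self.weights + self.bias


def predict(model: LinearModel, features: np.ndarray) -> tuple[str, float]:
    """Label one subject ('TBI' or 'control') with its signed margin.

    Rows exactly on the boundary get the conservative 'control' label.
    """
    margin = float(model.decision(np.atleast_2d(features))[0])
    return ("TBI" if margin > 0 else "control"), margin


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant column guard
    return (X - center) / scale, center, scale


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    subset: ParameterSubset | None = None,
    standardize: bool = False,
) -> LinearModel:
    """Fit a libsvm C-SVC with linear kernel; raw feature units by default."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ParameterError("training data must contain both classes")
    if standardize:
        Xs, center, scale = _standardise(X)
    else:
        Xs = X
        center = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    svm = SVC(kernel="linear", C=C)
    svm.fit(Xs, y)
    return LinearModel(
        subset=subset,
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        center=center,
        scale=scale,
    )


@dataclass
class EvaluationResult:
    subset: ParameterSubset
    accuracies: np.ndarray  # one value per repeat, in [0, 1]
    mean_model: LinearModel

    @property
    def mean_accuracy(self) -> float:
        """Average held-out accuracy, in percent."""
        return 100.0 * float(np.mean(self.accuracies))


def evaluate_subset(
    subset: ParameterSubset,
    features: pd.DataFrame,
    n_repeats: int = 100,
    C: float = 1.0,
    seed=0,
    phase_policy: str = "post",
    permute_labels: bool = False,
    standardize: bool = False,
) -> EvaluationResult:
    """Repeated one-subject-per-arm hold-out evaluation.

    Each repeat holds out one randomly chosen subject from each arm as the
    two test rows, trains on the remaining ten, and scores the held-out pair;
    ``mean_model`` averages the per-repeat weights, biases and scalings.
    ``permute_labels`` reshuffles the arm labels each repeat (the chance
    floor used as a null check).
    """
    X, y, _ = build_feature_matrix(features, subset, phase_policy)
    rng = np.random.default_rng(seed)
    controls = np.flatnonzero(y == 0)
    tbis = np.flatnonzero(y == 1)
    if controls.size < 2 or tbis.size < 2:
        raise ParameterError("need at least two subjects per arm")
    accs = np.empty(n_repeats)
    w_sum = np.zeros(X.shape[1])
    b_sum = 0.0
    c_sum = np.zeros(X.shape[1])
    s_sum = np.zeros(X.shape[1])
    for r in range(n_repeats):
        yr = rng.permutation(y) if permute_labels else y
        ctl = np.flatnonzero(yr == 0)
        tbi = np.flatnonzero(yr == 1)
        test = np.array([rng.choice(ctl), rng.choice(tbi)])
        train = np.setdiff1d(np.arange(y.size), test)
        model = train_linear_svm(
            X[train], yr[train], C=C, subset=subset, standardize=standardize
        )
        pred = (model.decision(X[test]) > 0).astype(int)
        accs[r] = float(np.mean(pred == yr[test]))
        w_sum += model.weights
        b_sum += model.bias
        c_sum += model.center
        s_sum += model.scale
    mean_model = LinearModel(
        subset=subset,
        weights=w_sum / n_repeats,
        bias=b_sum / n_repeats,
        center=c_sum / n_repeats,
        scale=s_sum / n_repeats,
    )
    return EvaluationResult(subset=subset, accuracies=accs, mean_model=mean_model)


def accuracy_grid(
    subsets: list[ParameterSubset],
    features: pd.DataFrame,
    n_repeats: int = 100,
    C: float = 1.0,
    seed=0,
    phase_policy: str = "post",
    standardize: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean accuracy per subset plus per-family band averages.

    Returns (grid, bands): ``grid`` has one row per subset (label, indices,
    significant fraction, mean accuracy); ``bands`` groups the subsets into
    their enumeration families and reports the family's mean significant
    fraction and mean accuracy, ordered by significant fraction.
    """
    if not subsets:
        raise ParameterError("no subsets supplied")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for subset, child in zip(subsets, ss.spawn(len(subsets))):
        res = evaluate_subset(
            subset, features, n_repeats=n_repeats, C=C,
            seed=np.random.default_rng(child), phase_policy=phase_policy,
            standardize=standardize,
        )
        rows.append(
            {
                "parameters": subset.label,
                "indices": ",".join(map(str, subset.indices)),
                "family": subset.family or "unspecified",
                "percent_significant": subset.significant_fraction,
                "accuracy_pct": res.mean_accuracy,
            }
        )
    grid = pd.DataFrame(rows)
    bands = (
        grid.groupby("family", as_index=False)
        .agg(
            percent_significant=("percent_significant", "mean"),
            average_accuracy_pct=("accuracy_pct", "mean"),
            n_subsets=("parameters", "size"),
        )
        .sort_values("percent_significant", kind="stable")
        .reset_index(drop=True)
    )
    return grid, bands
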