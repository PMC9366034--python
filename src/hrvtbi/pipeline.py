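"""End-to-end orchestration: simulate -> (detect) -> features -> validate -> train.

One :func:`run_pipeline` call executes every stage on a seeded synthetic
cohort and returns a :class:`RunReport` holding the per-phase feature table,
the screening and stochastic-validation results, the subset accuracy grid,
and plot-ready tables (group bar summaries with standard errors, Poincare
point sets for all six phase groups, and the binned |dRR| percentage
distributions).  Outputs are plain text and byte-identical for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    DEFAULT_SIGNIFICANT,
    accuracy_grid,
    enumerate_models,
)
from .features import (
    DEFAULT_TRIM,
    PARAMETER_NAMES,
    PNN_LABELS,
    cohort_feature_table,
    poincare_points,
    successive_differences,
    trim_outliers,
)
from .io import FLOAT_FMT, write_features, write_json, write_manifest, write_rr
from .peaks import waveform_to_rr
from .series import ParameterError, PhaseLabel, RRSeries
from .stats import screen_parameters, validate_screening
from .synthetic import CohortConfig, generate_cohort, generate_ecg_waveform

logger = logging.getLogger("hrvtbi")

FIGURE_IDS = ("parameter_bars", "poincare", "rr_diff_distribution")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    use_waveform: bool = False
    sampling_rate: float = 1000.0
    noise_sd: float = 0.05
    trim: float = DEFAULT_TRIM
    alpha: float = 0.05
    n_tests: int = 100
    n_trials: int = 10
    n_repeats: int = 100
    svm_C: float = 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", None)
        if isinstance(cohort, dict):
            from .synthetic import EffectSizes, Heterogeneity, RRGenParams

            cohort = CohortConfig(
                **{
                    **cohort,
                    "baseline": RRGenParams(**cohort.get("baseline", {})),
                    "effects": EffectSizes(**cohort.get("effects", {})),
                    "heterogeneity": Heterogeneity(**cohort.get("heterogeneity", {})),
                }
            )
        return cls(cohort=cohort or CohortConfig(), **d)


@dataclass
class RunReport:
    config: RunConfig
    features: pd.DataFrame
    screening: object
    validation: dict
    grid: pd.DataFrame
    bands: pd.DataFrame
    poincare: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]]
    provenance: dict


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall=%.2fs %s", name, time.perf_counter() - t0, extra)


def run_pipeline(config: RunConfig | None = None, outdir=None) -> RunReport:
    """Execute every stage in order; optionally write all outputs to outdir.

    With ``use_waveform`` the tachograms are re-derived by synthesising an
    ECG trace per subject-phase and running the peak detector over it;
    otherwise the simulated tachograms feed the feature stage directly.
    """
    config = config or RunConfig()
    t0 = time.perf_counter()
    cohort = generate_cohort(config.cohort, seed=config.seed)
    series: list[RRSeries] = []
    for subj in cohort:
        for phase, rr in subj.phases.items():
            if config.use_waveform:
                wseed = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(9999, len(series))
                )
                w, _ = generate_ecg_waveform(
                    rr, sampling_rate=config.sampling_rate,
                    noise_sd=config.noise_sd, seed=np.random.default_rng(wseed),
                )
                rr = waveform_to_rr(w, subject_id=subj.subject_id, phase=phase)
            series.append(rr)
    _stage("simulate", t0, subjects=len(cohort), series=len(series))

    t1 = time.perf_counter()
    features = cohort_feature_table(series, trim=config.trim)
    _stage("features", t1, rows=len(features))

    t2 = time.perf_counter()
    screening = screen_parameters(features, alpha=config.alpha)
    validation = validate_screening(
        features, screening, n_tests=config.n_tests, n_trials=config.n_trials,
        alpha=config.alpha, seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)),
    )
    _stage("validate", t2, flagged=len(screening.flagged_instances()))

    t3 = time.perf_counter()
    significant = screening.significant_indices or DEFAULT_SIGNIFICANT
    subsets = enumerate_models(significant)
    grid, bands = accuracy_grid(
        subsets, features, n_repeats=config.n_repeats, C=config.svm_C,
        seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)),
    )
    _stage("train", t3, subsets=len(subsets))

    poincare = {}
    for rr in series:
        trimmed = trim_outliers(rr, config.trim)
        poincare[f"{rr.subject_id}:{rr.phase.value}"] = {
            1: poincare_points(trimmed, 1),
            2: poincare_points(trimmed, 2),
        }

    provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "package_version": __version__,
        "significant_parameters": sorted(screening.significant),
        "empty_significant_set": len(screening.significant) == 0,
    }
    report = RunReport(
        config=config, features=features, screening=screening,
        validation=validation, grid=grid, bands=bands,
        poincare=poincare, provenance=provenance,
    )
    if outdir is not None:
        write_report(report, outdir, series=series)
    return report


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def export_figure_data(report: RunReport, which: str) -> pd.DataFrame:
    """Plot-ready tables for the three report figures.

    ``parameter_bars``: per phase-group mean and SEM of every parameter.
    ``poincare``: long table of lag-1 and lag-2 point sets per phase group.
    ``rr_diff_distribution``: mean and SEM of the pNN bin percentages for the
    baseline and post phases of both arms.
    """
    f = report.features
    if which == "parameter_bars":
        rows = []
        for phase in ("Hb", "Hh", "Hp", "Tb", "Th", "Tp"):
            sub = f[f["phase"] == phase]
            for param in PARAMETER_NAMES:
                vals = sub[param].to_numpy(dtype=float)
                rows.append(
                    {"phase": phase, "parameter": param,
                     "mean": float(np.mean(vals)), "sem": _sem(vals), "n": vals.size}
                )
        return pd.DataFrame(rows)
    if which == "poincare":
        rows = []
        for key, by_order in report.poincare.items():
            subject, phase = key.split(":")
            for order, (x, y) in by_order.items():
                rows.append(
                    pd.DataFrame(
                        {"subject_id": subject, "phase": phase, "order": order,
                         "x": x, "y": y}
                    )
                )
        return pd.concat(rows, ignore_index=True)
    if which == "rr_diff_distribution":
        rows = []
        for phase in ("Hb", "Tb", "Hp", "Tp"):
            sub = f[f["phase"] == phase]
            for label in PNN_LABELS:
                vals = sub[label].to_numpy(dtype=float)
                rows.append(
                    {"phase": phase, "bin": label,
                     "mean_pct": float(np.mean(vals)), "sem": _sem(vals), "n": vals.size}
                )
        return pd.DataFrame(rows)
    raise ParameterError(f"unknown figure id {which!r}; choose from {FIGURE_IDS}")


def write_report(report: RunReport, outdir, series: list[RRSeries] | None = None) -> None:
    """Write every artefact of a run as plain text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_features(report.features, out / "features.tsv")
    report.grid.to_csv(out / "grid.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    report.bands.to_csv(out / "bands.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    validation = {
        "alpha": report.config.alpha,
        "significant_parameters": sorted(report.screening.significant),
        "tests": [
            {"parameter": r.parameter, "contrast": r.label,
             "statistic": r.statistic, "p_value": r.p_value,
             "significant": r.significant}
            for r in report.screening.results.values()
        ],
        "stochastic": {
            f"{param}:{label}": {
                "trial_counts": list(res.trial_counts),
                "empirical_probability": res.empirical_probability,
            }
            for (param, label), res in report.validation["instances"].items()
        },
        "pooled_probability": report.validation["pooled_probability"],
    }
    write_json(validation, out / "validation.json")
    write_json(report.provenance, out / "provenance.json")
    for fig in FIGURE_IDS:
        export_figure_data(report, fig).to_csv(
            out / f"fig_{fig}.csv", index=False, float_format=FLOAT_FMT
        )
    if series is not None:
        rr_dir = out / "rr"
        rr_dir.mkdir(exist_ok=True)
        manifest = []
        for rr in series:
            name = f"{rr.subject_id}_{rr.phase.value}.csv"
            write_rr(rr, rr_dir / name)
            manifest.append(
                {"subject_id": rr.subject_id, "arm": rr.phase.arm,
                 "phase": rr.phase.value, "rr_file": f"rr/{name}"}
            )
        write_manifest(manifest, out / "manifest.csv")
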