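"""Statistical comparison, cohort summaries and the end-to-end pipeline.

Distributions of per-cell metrics are compared with two-sample
Kolmogorov-Smirnov tests (distributions are typically not normal), with
the usual significance stars.  The pipeline chains cohort generation,
deformation analysis, Kelvin-Voigt fitting, feature assembly, KS tables
and random-forest classification into one reproducible, seeded bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classification import RFConfig, permutation_importance, train_and_evaluate
from .features import FeatureMatrix, assemble_matrix, default_schema, featurize_trace
from .rheology import ACTIVITY_THRESHOLD, relative_deformation
from .synthetic import SynthConfig, generate_cohort, clinical_cohort_config

__all__ = [
    "KSResult",
    "CohortSummary",
    "ks_two_sample",
    "median_curve",
    "fold_enrichment",
    "run_pipeline",
    "PipelineError",
]


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov result."""

    statistic: float  # sup-distance D between the two ECDFs, in [0, 1]
    p_value: float
    n1: int
    n2: int

    @property
    def stars(self) -> str:
        """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
        if self.p_value < 1e-3:
            return "***"
        if self.p_value < 1e-2:
            return "**"
        if self.p_value < 5e-2:
            return "*"
        return ""


def ks_two_sample(x, y) -> KSResult:
    """Two-sample KS test with the asymptotic p-value.

    D is the supremum distance between the two empirical CDFs; it is
    invariant under any strictly monotone transform applied to both
    samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 finite values")
    res = stats.ks_2samp(x, y, method="asymp")
    p = float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return KSResult(statistic=float(res.statistic), p_value=p, n1=x.size, n2=y.size)


def median_curve(curves: list) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise median and interquartile band over aligned curves.

    Returns (time, median, q25, q75).  All curves must share one time grid.
    """
    if not curves:
        raise ValueError("need at least one curve")
    t0 = curves[0].time
    for c in curves[1:]:
        if c.time.shape != t0.shape or not np.allclose(c.time, t0):
            raise ValueError("curves must share one time grid")
    V = np.vstack([c.value for c in curves])
    return (
        t0,
        np.median(V, axis=0),
        np.quantile(V, 0.25, axis=0),
        np.quantile(V, 0.75, axis=0),
    )


def fold_enrichment(prop_case: float, prop_control: float) -> tuple[float, int]:
    """Ratio of two proportions plus its integer-rounded headline value."""
    if prop_control <= 0:
        raise ValueError("control proportion must be > 0")
    if prop_case < 0:
        raise ValueError("case proportion must be >= 0")
    fold = prop_case / prop_control
    return fold, int(round(fold))


@dataclass
class CohortSummary:
    """Per-class medians and activity balance of one analyzed cohort."""

    medians: pd.DataFrame  # classes x metrics
    active_ratio: float  # active : non-active over determined cells
    active_ratio_per_class: dict[str, float]
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "medians": self.medians.to_dict(orient="index"),
            "active_ratio": self.active_ratio,
            "active_ratio_per_class": self.active_ratio_per_class,
            "n_cells": self.n_cells,
        }


_SUMMARY_METRICS = [
    "relative_def_end_stretch",
    "elliptic_def_end_stretch",
    "shape_restoration",
    "radius_um",
]
_ACTIVITY_COL = "a_relative_full_active"


def _ratio(n_act: int, n_non: int) -> float:
    return n_act / n_non if n_non > 0 else float("inf")


def summarize_cohort(matrix: FeatureMatrix, threshold: float = ACTIVITY_THRESHOLD) -> CohortSummary:
    """Class-wise medians plus the active:non-active cell ratio.

    The activity median per class is taken over active cells (fitted
    activity above threshold), matching how a per-cohort "median activity"
    is usually quoted; the active ratio counts cells with a determined
    (converged) activity fit only.
    """
    X, y = matrix.X, matrix.y
    rows = {}
    ratios = {}
    for label in pd.unique(y):
        sub = X[y == label]
        med = {m: float(sub[m].median()) for m in _SUMMARY_METRICS if m in sub}
        a = sub[_ACTIVITY_COL].dropna()
        active = a > threshold
        med["activity_pa_per_s"] = float(a[active].median()) if active.any() else float("nan")
        rows[label] = med
        ratios[label] = _ratio(int(active.sum()), int((~active).sum()))
    a_all = X[_ACTIVITY_COL].dropna()
    act_all = a_all > threshold
    return CohortSummary(
        medians=pd.DataFrame.from_dict(rows, orient="index"),
        active_ratio=_ratio(int(act_all.sum()), int((~act_all).sum())),
        active_ratio_per_class=ratios,
        n_cells=len(matrix),
    )


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is carried along."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


_KS_METRICS = ["relative_def_end_stretch", "elliptic_def_end_stretch", "shape_restoration"]


def ks_tables(matrix: FeatureMatrix, metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-power and pooled two-class KS comparisons of scalar metrics."""
    metrics = metrics or _KS_METRICS
    labels = list(pd.unique(matrix.y))
    if len(labels) != 2:
        raise ValueError("KS tables need exactly two classes")
    a, b = labels
    rows = []
    powers = sorted(matrix.laser_power.unique())
    scopes = [("pooled", np.ones(len(matrix), dtype=bool))] + [
        (f"{p:g} mW", (matrix.laser_power == p).values) for p in powers
    ]
    for scope, sel in scopes:
        for m in metrics:
            xa = matrix.X.loc[sel & (matrix.y == a).values, m]
            xb = matrix.X.loc[sel & (matrix.y == b).values, m]
            r = ks_two_sample(xa, xb)
            rows.append(
                {
                    "scope": scope,
                    "metric": m,
                    "D": r.statistic,
                    "p_value": r.p_value,
                    "stars": r.stars,
                    "n1": r.n1,
                    "n2": r.n2,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run simulate -> fit -> featurize -> classify -> summarize.

    ``config`` keys (all optional): ``n_per_class``, ``separation``,
    ``frame_rate``, ``axis_noise_sd``, ``synth`` (a full SynthConfig as a
    dict, overriding the preset), ``rf`` (RFConfig fields),
    ``importances`` (bool).  Everything is seeded from ``seed``; rerunning
    with the same config and seed reproduces the bundle bit for bit.
    """
    config = dict(config or {})
    if "synth" in config:
        synth = SynthConfig.from_json(json.dumps(config["synth"]))
    else:
        synth = clinical_cohort_config(
            n_per_class=config.get("n_per_class", 200),
            frame_rate=config.get("frame_rate", 30.0),
            separation=config.get("separation", 1.0),
            seed=seed,
        )
        if "axis_noise_sd" in config:
            synth.axis_noise_sd = config["axis_noise_sd"]
    rf = RFConfig(**{**config.get("rf", {}), "seed": seed})

    try:
        traces, truths = generate_cohort(synth, seed=seed)
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineError("simulate", e)

    schema = default_schema()
    try:
        rows = [
            featurize_trace(tr, schema, class_label=truth.class_label)
            for tr, truth in zip(traces, truths)
        ]
        matrix = assemble_matrix(rows, mode="pooled")
    except Exception as e:
        raise PipelineError("featurize", e)

    try:
        ks = ks_tables(matrix)
        summary = summarize_cohort(matrix)
        med_curves = {}
        for label in pd.unique(matrix.y):
            for p in sorted({tr.protocol.laser_power for tr in traces}):
                group = [
                    relative_deformation(tr)
                    for tr, truth in zip(traces, truths)
                    if truth.class_label == label and tr.protocol.laser_power == p
                ]
                if group:
                    t, med, q25, q75 = median_curve(group)
                    med_curves[f"{label}@{p:g}mW"] = {
                        "time": t, "median": med, "q25": q25, "q75": q75,
                    }
    except Exception as e:
        raise PipelineError("summarize", e)

    try:
        report = train_and_evaluate(matrix, rf)
        importances = (
            permutation_importance(matrix, rf) if config.get("importances", True) else None
        )
    except Exception as e:
        raise PipelineError("classify", e)

    bundle = {
        "seed": seed,
        "synth_config": json.loads(synth.to_json()),
        "n_cells": len(matrix),
        "matrix": matrix,
        "ks_tables": ks,
        "summary": summary,
        "classification": report,
        "importances": importances,
        "median_curves": med_curves,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["matrix"].to_csv(out_dir / "features.csv")
    (out_dir / "schema.json").write_text(bundle["matrix"].schema.to_json())
    bundle["ks_tables"].to_csv(out_dir / "ks_tables.csv", index=False)
    if bundle["importances"] is not None:
        bundle["importances"].to_csv(out_dir / "importances.csv", index=False)
    bundle["classification"].per_fold.to_csv(out_dir / "cv_folds.csv", index=False)
    summary = {
        "seed": bundle["seed"],
        "n_cells": bundle["n_cells"],
        "synth_config": bundle["synth_config"],
        "cohort": bundle["summary"].to_dict(),
        "classification": bundle["classification"].to_dict(),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    curves = []
    for key, c in bundle["median_curves"].items():
        df = pd.DataFrame({"time_s": c["time"], "median": c["median"], "q25": c["q25"], "q75": c["q75"]})
        df.insert(0, "group", key)
        curves.append(df)
    if curves:
        pd.concat(curves).to_csv(out_dir / "median_curves.csv", index=False)
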