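"""Per-cell feature matrix assembly.

One row per cell, combining morphology descriptors, end-of-stretch
deformation metrics, all Kelvin-Voigt fit parameters (2 signals x 2
windows x 2 models), shape restoration and the laser power.  Features of
non-converged fits are masked (NaN with an explicit mask), never silently
defaulted; the classifier imputes them inside each training fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import StretchProtocol
from .rheology import (
    KVFit,
    RestorationResult,
    elliptic_deformation,
    fit_kv,
    relative_deformation,
    shape_restoration,
)
from .tracking import AxisTrace, Morphology, compute_morphology

__all__ = [
    "FeatureDescriptor",
    "FeatureSchema",
    "FeatureRow",
    "FeatureMatrix",
    "default_schema",
    "build_feature_vector",
    "featurize_trace",
    "assemble_matrix",
]

SIGNALS = ("relative", "elliptic")
WINDOWS = ("full", "first2s")
MODELS = ("passive", "active")

_MORPH_ATTRS = {
    "radius_um": "effective_radius",
    "area_um2": "area",
    "rel_brightness": "mean_brightness",
    "initial_ellipticity": "initial_ellipticity",
    "rotation_deg": "rotation_degree",
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """One named feature and where it comes from.

    ``source`` is one of morphology / curve / fit / restoration /
    protocol; ``signal``, ``window`` and ``model`` qualify curve and fit
    features; ``attr`` names the attribute read from the source object.
    """

    name: str
    source: str
    attr: str
    signal: str | None = None
    window: str | None = None
    model: str | None = None


@dataclass(frozen=True)
class FeatureSchema:
    features: tuple[FeatureDescriptor, ...]
    version: str = "default-1"

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "features": [vars(f) for f in self.features]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(
            features=tuple(FeatureDescriptor(**f) for f in d["features"]),
            version=d.get("version", "custom"),
        )


def default_schema() -> FeatureSchema:
    """The shipped feature schema (45 features).

    Covers every feature family used in the analysis: morphology (radius,
    area, brightness, resting ellipticity, degree of rotation),
    end-of-stretch relative and elliptic deformation, the full fit grid
    (E, eta, tau, fit error, plus activity for the active model, for each
    signal x window combination), shape restoration and laser power.
    """
    feats: list[FeatureDescriptor] = [
        FeatureDescriptor(name, "morphology", attr)
        for name, attr in _MORPH_ATTRS.items()
    ]
    for sig in SIGNALS:
        feats.append(
            FeatureDescriptor(f"{sig}_def_end_stretch", "curve", "end_of_stretch_value", signal=sig)
        )
    for sig in SIGNALS:
        for win in WINDOWS:
            for model in MODELS:
                tag = f"{sig}_{win}_{model}"
                params = ["E", "eta", "tau", "fit_error"] + (["a"] if model == "active" else [])
                for p in params:
                    feats.append(
                        FeatureDescriptor(f"{p}_{tag}", "fit", p, signal=sig, window=win, model=model)
                    )
    feats.append(FeatureDescriptor("shape_restoration", "restoration", "shape_restoration"))
    feats.append(FeatureDescriptor("laser_power_mw", "protocol", "laser_power"))
    return FeatureSchema(features=tuple(feats))


@dataclass
class FeatureRow:
    """One cell's feature values with an explicit missing mask."""

    cell_id: str
    values: np.ndarray
    mask: np.ndarray  # True where the value is missing
    schema: FeatureSchema
    class_label: str | None = None
    laser_power: float = float("nan")


def build_feature_vector(
    morph: Morphology,
    curves: dict[str, "object"],
    fits: list[KVFit],
    restoration: RestorationResult,
    protocol: StretchProtocol,
    schema: FeatureSchema,
    cell_id: str = "",
    class_label: str | None = None,
) -> FeatureRow:
    """Resolve every schema descriptor against one cell's analysis outputs."""
    fit_index = {(f.signal, f.window, f.model): f for f in fits}
    values = np.full(len(schema), np.nan)
    mask = np.zeros(len(schema), dtype=bool)
    for i, desc in enumerate(schema.features):
        if desc.source == "morphology":
            values[i] = getattr(morph, desc.attr)
        elif desc.source == "curve":
            if desc.signal not in curves:
                raise KeyError(f"schema needs missing curve signal {desc.signal!r}")
            values[i] = getattr(curves[desc.signal], desc.attr)
        elif desc.source == "fit":
            key = (desc.signal, desc.window, desc.model)
            if key not in fit_index:
                raise KeyError(f"schema needs missing fit {key}")
            fit = fit_index[key]
            v = getattr(fit, desc.attr)
            if not fit.converged or not np.isfinite(v):
                mask[i] = True
            else:
                values[i] = v
        elif desc.source == "restoration":
            values[i] = getattr(restoration, desc.attr)
        elif desc.source == "protocol":
            values[i] = getattr(protocol, desc.attr)
        else:
            raise KeyError(f"unknown feature source {desc.source!r}")
    return FeatureRow(
        cell_id=cell_id,
        values=values,
        mask=mask,
        schema=schema,
        class_label=class_label,
        laser_power=protocol.laser_power,
    )


def featurize_trace(
    trace: AxisTrace, schema: FeatureSchema | None = None, class_label: str | None = None
) -> FeatureRow:
    """Full single-cell analysis: morphology, curves, 8 fits, restoration."""
    if not trace.valid:
        raise ValueError(f"trace {trace.cell_id!r} is invalid")
    if schema is None:
        schema = default_schema()
    morph = compute_morphology(trace)
    curves = {"relative": relative_deformation(trace), "elliptic": elliptic_deformation(trace)}
    fits = [
        fit_kv(curves[sig], window=win, model=model)
        for sig in SIGNALS
        for win in WINDOWS
        for model in MODELS
    ]
    restoration = shape_restoration(curves["relative"])
    return build_feature_vector(
        morph, curves, fits, restoration, trace.protocol, schema,
        cell_id=trace.cell_id, class_label=class_label,
    )


@dataclass
class FeatureMatrix:
    """Cells x features with labels, laser power and an explicit mask."""

    X: pd.DataFrame  # NaN where masked
    y: pd.Series
    laser_power: pd.Series
    schema: FeatureSchema

    @property
    def mask(self) -> pd.DataFrame:
        return self.X.isna()

    def __len__(self) -> int:
        return len(self.X)

    def to_csv(self, path) -> None:
        df = self.X.copy()
        df.insert(0, "cell_id", self.X.index)
        df["class_label"] = self.y.values
        df["laser_power"] = self.laser_power.values
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: FeatureSchema) -> "FeatureMatrix":
        df = pd.read_csv(path)
        df = df.set_index("cell_id")
        X = df[schema.names].astype(float)
        return cls(
            X=X,
            y=df["class_label"],
            laser_power=df["laser_power"].astype(float),
            schema=schema,
        )


def assemble_matrix(rows: list[FeatureRow], mode: str = "pooled"):
    """Stack feature rows into one pooled matrix or one matrix per power.

    Pooled mode keeps the laser power as a feature column (the schema
    already contains it); per-power mode partitions rows by laser power
    and returns ``{power: FeatureMatrix}``.
    """
    if mode not in ("pooled", "per_power"):
        raise ValueError(f"unknown mode {mode!r}")
    if rows:
        schema = rows[0].schema
        if any(r.schema is not schema and r.schema != schema for r in rows):
            raise ValueError("all rows must share one schema")
    else:
        schema = default_schema()
    X = pd.DataFrame(
        np.vstack([r.values for r in rows]) if rows else np.empty((0, len(schema))),
        columns=schema.names,
        index=pd.Index([r.cell_id for r in rows], name="cell_id"),
    )
    y = pd.Series([r.class_label for r in rows], index=X.index, name="class_label")
    power = pd.Series([r.laser_power for r in rows], index=X.index, name="laser_power", dtype=float)
    pooled = FeatureMatrix(X=X, y=y, laser_power=power, schema=schema)
    if mode == "pooled":
        return pooled
    return {
        p: FeatureMatrix(
            X=X[power == p], y=y[power == p], laser_power=power[power == p], schema=schema
        )
        for p in sorted(power.unique())
    }
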