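"""Feature-vector assembly and min-max normalisation.

Each patient's 25 histogram curves (20 OVH + 5 TVH, 11 samples each)
are concatenated in a frozen layout order into a 275-value feature
vector.  Inputs and the 21 dose objectives (cGy) are normalised with
per-feature min-max scalers fitted on training rows only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histograms import CurveId, HistogramCurve, SamplingSpec, default_sampling_config

log = logging.getLogger(__name__)

#: entry of a feature layout: which curve, which sample on that curve
LayoutEntry = tuple[CurveId, int]


def build_layout(
    config: dict[CurveId, SamplingSpec] | None = None,
) -> list[LayoutEntry]:
    """Frozen feature layout: curves in config order, distances ascending."""
    config = config if config is not None else default_sampling_config()
    layout: list[LayoutEntry] = []
    for cid, spec in config.items():
        layout.extend((cid, i) for i in range(spec.n_samples))
    return layout


@dataclass
class FeatureVector:
    patient_id: str
    values: np.ndarray
    layout: list[LayoutEntry]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.layout):
            raise ValueError(
                f"feature vector length {len(self.values)} does not match "
                f"layout length {len(self.layout)}"
            )


def assemble_features(
    curves: list[HistogramCurve],
    layout: list[LayoutEntry],
    patient_id: str = "",
) -> FeatureVector:
    """Concatenate curve values into the fixed layout order.

    The input list order is irrelevant; each layout curve must be
    supplied exactly once.
    """
    by_id: dict[CurveId, HistogramCurve] = {}
    for c in curves:
        if c.curve_id in by_id:
            raise ValueError(f"duplicate curve {c.curve_id}")
        by_id[c.curve_id] = c
    values = np.empty(len(layout))
    for pos, (cid, idx) in enumerate(layout):
        if cid not in by_id:
            raise ValueError(f"missing curve {cid}")
        curve = by_id[cid]
        if idx >= len(curve.values):
            raise ValueError(f"curve {cid} has no sample index {idx}")
        values[pos] = curve.values[idx]
    return FeatureVector(patient_id, values, layout)


@dataclass
class FeatureScaler:
    """Per-feature min-max scaler mapping the training range to [0, 1]."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != self.maxs.shape:
            raise ValueError("mins and maxs must have equal length")
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in scaler")

    @property
    def n_features(self) -> int:
        return len(self.mins)


def fit_scaler(X: np.ndarray) -> FeatureScaler:
    """Column-wise min and max over the training rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scaler requires a 2-D matrix with at least 2 rows")
    return FeatureScaler(X.min(axis=0), X.max(axis=0))


def apply_scaler(scaler: FeatureScaler, x: np.ndarray, clip: bool = False) -> np.ndarray:
    """Normalize ``(x - min) / (max - min)`` per feature.

    Degenerate features (max == min) map to 0.  With ``clip`` on,
    out-of-range values are clamped to [0, 1] and a warning is logged —
    this keeps network inputs inside the trained domain.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != scaler.n_features:
        raise ValueError(
            f"length mismatch: vector has {x.shape[-1]} features, "
            f"scaler has {scaler.n_features}"
        )
    span = scaler.maxs - scaler.mins
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - scaler.mins) / span
    out = np.where(span == 0, 0.0, out)
    if clip:
        n_out = int(np.sum((out < 0) | (out > 1)))
        if n_out:
            log.warning("clamping %d out-of-range feature value(s) to [0, 1]", n_out)
        out = np.clip(out, 0.0, 1.0)
    return out


def inverse_scaler(scaler: FeatureScaler, x: np.ndarray) -> np.ndarray:
    """Map normalized values back: ``min + x * (max - min)``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != scaler.n_features:
        raise ValueError(
            f"length mismatch: vector has {x.shape[-1]} features, "
            f"scaler has {scaler.n_features}"
        )
    return scaler.mins + x * (scaler.maxs - scaler.mins)


def scaler_to_dict(scaler: FeatureScaler) -> dict:
    return {"mins": scaler.mins.tolist(), "maxs": scaler.maxs.tolist()}


def scaler_from_dict(d: dict) -> FeatureScaler:
    return FeatureScaler(np.array(d["mins"]), np.array(d["maxs"]))


def scaler_to_json(scaler: FeatureScaler) -> str:
    return json.dumps(scaler_to_dict(scaler))


def scaler_from_json(text: str) -> FeatureScaler:
    return scaler_from_dict(json.loads(text))


@dataclass
class LibraryMatrix:
    """A training (or test) library: stacked features and objectives.

    ``X`` is patients x features; ``Y`` is patients x 21 objective doses
    in cGy.  Row order is chronological (treatment-date order), which
    the fold split relies on.
    """

    patient_ids: list[str]
    X: np.ndarray
    Y: np.ndarray
    layout: list[LayoutEntry] = field(default_factory=build_layout)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if self.X.shape[0] != len(self.patient_ids):
            raise ValueError("patient_ids length does not match X rows")
        if self.X.shape[1] != len(self.layout):
            raise ValueError("X column count does not match layout length")

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]


def layout_column_names(layout: list[LayoutEntry]) -> list[str]:
    return [f"{cid.kind}|{cid.subject}|{cid.reference}|{idx}" for cid, idx in layout]


def layout_from_column_names(names: list[str]) -> list[LayoutEntry]:
    layout: list[LayoutEntry] = []
    for name in names:
        kind, subject, reference, idx = name.split("|")
        layout.append((CurveId(kind, subject, reference), int(idx)))
    return layout


def library_to_csv(lib: LibraryMatrix, features_path: str, objectives_path: str) -> None:
    feat = pd.DataFrame(lib.X, columns=layout_column_names(lib.layout))
    feat.insert(0, "patient_id", lib.patient_ids)
    feat.to_csv(features_path, index=False)
    obj = pd.DataFrame(lib.Y, columns=[f"objective_{i + 1}" for i in range(lib.Y.shape[1])])
    obj.insert(0, "patient_id", lib.patient_ids)
    obj.to_csv(objectives_path, index=False)


def library_from_csv(features_path: str, objectives_path: str) -> LibraryMatrix:
    feat = pd.read_csv(features_path)
    obj = pd.read_csv(objectives_path)
    if list(feat["patient_id"]) != list(obj["patient_id"]):
        raise ValueError("features and objectives list different patients")
    layout = layout_from_column_names(list(feat.columns[1:]))
    return LibraryMatrix(
        [str(p) for p in feat["patient_id"]],
        feat.iloc[:, 1:].to_numpy(float),
        obj.iloc[:, 1:].to_numpy(float),
        layout,
    )


def features_to_csv(fv: FeatureVector, path: str) -> None:
    df = pd.DataFrame([fv.values], columns=layout_column_names(fv.layout))
    df.insert(0, "patient_id", [fv.patient_id])
    df.to_csv(path, index=False)


def features_from_csv(path: str) -> FeatureVector:
    df = pd.read_csv(path)
    layout = layout_from_column_names(list(df.columns[1:]))
    return FeatureVector(str(df["patient_id"].iloc[0]), df.iloc[0, 1:].to_numpy(float), layout)
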