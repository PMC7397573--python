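"""Overlap volume histograms (OVH) and target volume histograms (TVH).

The OVH of an organ at risk (OAR) with respect to a target volume gives,
for each signed distance t, the fraction of the OAR covered by the
target uniformly expanded (t > 0) or contracted (t < 0) by |t|.  It
summarises the 3-D spatial relationship between OAR and target as a
monotone curve in [0, 1].  The TVH is the analogous relative volume of
a target itself under uniform expansion/contraction, normalised to the
original target volume.

Sampling distances are specified in cm and converted to mm internally
(factor 10).  The default configuration samples 20 OVH curves and 5 TVH
curves at 11 distances each, giving the 275 geometric descriptors used
as network inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .volumes import (
    StructureError,
    StructureMask,
    StructureSet,
    distance_from_complement,
    distance_from_structure,
)

CM_TO_MM = 10.0


@dataclass(frozen=True)
class SamplingSpec:
    """Arithmetic distance ladder ``start, start+step, ..., end`` in cm."""

    start_cm: float
    step_cm: float
    end_cm: float

    def __post_init__(self) -> None:
        if self.step_cm <= 0:
            raise ValueError("step_cm must be positive")
        if self.end_cm < self.start_cm:
            raise ValueError("end_cm must be >= start_cm")

    @property
    def n_samples(self) -> int:
        return int(round((self.end_cm - self.start_cm) / self.step_cm)) + 1

    def distances_cm(self) -> np.ndarray:
        return self.start_cm + self.step_cm * np.arange(self.n_samples)


class CurveId(NamedTuple):
    """Identity of one histogram curve.

    ``kind`` is "OVH" or "TVH"; ``subject`` is the OAR (OVH) or the
    target itself (TVH); ``reference`` is the morphed target volume.
    """

    kind: str
    subject: str
    reference: str


@dataclass
class HistogramCurve:
    """One sampled OVH or TVH curve."""

    kind: str
    subject: str
    reference_target: str
    distances_cm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.distances_cm = np.asarray(self.distances_cm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances_cm.shape != self.values.shape:
            raise ValueError("distances and values must have equal length")

    @property
    def curve_id(self) -> CurveId:
        return CurveId(self.kind, self.subject, self.reference_target)


def _morph_mask_from_fields(
    target: StructureMask,
    t_mm: float,
    dist_out: np.ndarray | None,
    dist_in: np.ndarray | None,
) -> np.ndarray:
    """Boolean mask of the target expanded/contracted by ``t_mm``.

    Identical to ``expand``/``contract`` in :mod:`kbplan.volumes` but
    reuses precomputed distance fields so a whole curve costs two
    distance transforms.
    """
    if t_mm > 0:
        if dist_out is None:
            dist_out = distance_from_structure(target)
        return dist_out <= t_mm
    if t_mm < 0:
        if dist_in is None:
            dist_in = distance_from_complement(target)
        return dist_in > -t_mm
    return target.voxels


class MorphCache:
    """Caches the inward/outward distance fields of reference targets."""

    def __init__(self) -> None:
        self._out: dict[str, np.ndarray] = {}
        self._in: dict[str, np.ndarray] = {}

    def morph(self, target: StructureMask, t_mm: float) -> np.ndarray:
        key = target.name
        if t_mm > 0 and key not in self._out:
            self._out[key] = distance_from_structure(target)
        if t_mm < 0 and key not in self._in:
            self._in[key] = distance_from_complement(target)
        return _morph_mask_from_fields(
            target, t_mm, self._out.get(key), self._in.get(key)
        )


def compute_ovh(
    oar: StructureMask,
    target: StructureMask,
    spec: SamplingSpec,
    cache: MorphCache | None = None,
) -> HistogramCurve:
    """Overlap volume histogram of ``oar`` versus ``target``.

    At each sampled distance t (cm; negative = contraction) the value is
    |oar ∩ morph(target, t)| / |oar|.  Values lie in [0, 1] and are
    non-decreasing in t.  If contraction empties the target the value is
    0, not an error.
    """
    if oar.is_empty:
        raise StructureError(f"empty structure {oar.name!r}")
    if target.is_empty:
        raise StructureError(f"empty structure {target.name!r}")
    if oar.grid != target.grid:
        raise StructureError(
            f"grid mismatch between {oar.name!r} and {target.name!r}"
        )
    cache = cache or MorphCache()
    n_oar = oar.voxel_count
    values = []
    for t_cm in spec.distances_cm():
        morphed = cache.morph(target, float(t_cm) * CM_TO_MM)
        values.append((oar.voxels & morphed).sum() / n_oar)
    return HistogramCurve("OVH", oar.name, target.name,
                          spec.distances_cm(), np.array(values))


def compute_tvh(
    target: StructureMask,
    spec: SamplingSpec,
    cache: MorphCache | None = None,
) -> HistogramCurve:
    """Target volume histogram: |morph(target, t)| / |target| per distance."""
    if target.is_empty:
        raise StructureError(f"empty structure {target.name!r}")
    cache = cache or MorphCache()
    n_target = target.voxel_count
    values = []
    for t_cm in spec.distances_cm():
        morphed = cache.morph(target, float(t_cm) * CM_TO_MM)
        values.append(morphed.sum() / n_target)
    return HistogramCurve("TVH", target.name, target.name,
                          spec.distances_cm(), np.array(values))


def default_sampling_config() -> dict[CurveId, SamplingSpec]:
    """The default OVH/TVH sampling table.

    20 OVH pairs and 5 TVH targets, each sampled at 11 distances.
    Bilateral rows ("left/right ...") expand to two curves, left first.
    Order is preserved and defines the feature layout.
    """
    ovh_rows: list[tuple[list[str], str, SamplingSpec]] = [
        (["left parotid", "right parotid"], "CTV_ALL", SamplingSpec(-1.0, 0.2, 1.0)),
        (["brainstem"], "CTV_ALL", SamplingSpec(-1.0, 0.2, 1.0)),
        (["spinal cord"], "CTV_ALL", SamplingSpec(0.0, 0.2, 2.0)),
        (["left optic lens", "right optic lens"], "CTV_ALL", SamplingSpec(0.0, 0.4, 4.0)),
        (["left optic nerve", "right optic nerve"], "CTV_ALL", SamplingSpec(-1.0, 0.3, 2.0)),
        (["pituitary"], "CTV_ALL", SamplingSpec(-1.0, 0.3, 2.0)),
        (["optic chiasm"], "CTV_ALL", SamplingSpec(-1.0, 0.3, 2.0)),
        (["CTV1_P"], "GTV_T_P", SamplingSpec(-1.0, 0.2, 1.0)),
        (["CTV2_P"], "CTV1_P", SamplingSpec(-1.0, 0.2, 1.0)),
        (["CTV_NL_P"], "GTV_NL_P", SamplingSpec(-1.0, 0.2, 1.0)),
        (["CTV_NR_P"], "GTV_NR_P", SamplingSpec(-1.0, 0.2, 1.0)),
        (["left parotid"], "GTV_NL_P", SamplingSpec(-1.0, 0.3, 2.0)),
        (["right parotid"], "GTV_NR_P", SamplingSpec(-1.0, 0.3, 2.0)),
        (["left parotid", "right parotid"], "GTV_T_P", SamplingSpec(0.0, 0.3, 3.0)),
        (["pituitary"], "GTV_T_P", SamplingSpec(0.0, 0.3, 3.0)),
        (["optic chiasm"], "GTV_T_P", SamplingSpec(0.0, 0.3, 3.0)),
    ]
    tvh_targets = ["GTV_T_P", "GTV_NL_P", "GTV_NR_P", "CTV1_P", "CTV2_P"]

    config: dict[CurveId, SamplingSpec] = {}
    for subjects, reference, spec in ovh_rows:
        for subject in subjects:
            config[CurveId("OVH", subject, reference)] = spec
    for target in tvh_targets:
        config[CurveId("TVH", target, target)] = SamplingSpec(-1.0, 0.2, 1.0)
    return config


def compute_curves(
    s: StructureSet,
    config: dict[CurveId, SamplingSpec] | None = None,
) -> list[HistogramCurve]:
    """Compute every configured curve for one patient's structure set.

    Distance fields of each reference target are computed once and
    shared across curves.  The structure set must already contain the
    auxiliary structures (notably CTV_ALL).
    """
    config = config if config is not None else default_sampling_config()
    cache = MorphCache()
    curves = []
    for cid, spec in config.items():
        if cid.kind == "OVH":
            curves.append(compute_ovh(s[cid.subject], s[cid.reference], spec, cache))
        elif cid.kind == "TVH":
            curves.append(compute_tvh(s[cid.reference], spec, cache))
        else:
            raise ValueError(f"unknown curve kind {cid.kind!r}")
    return curves


# ---------------------------------------------------------------------------
# Serialization


def curves_to_frame(patient_id: str, curves: Iterable[HistogramCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for d, v in zip(c.distances_cm, c.values):
            rows.append((patient_id, c.kind, c.subject, c.reference_target, d, v))
    return pd.DataFrame(
        rows, columns=["patient_id", "kind", "subject", "reference", "distance_cm", "value"]
    )


def curves_to_json(curves: Iterable[HistogramCurve]) -> str:
    payload = [
        {
            "kind": c.kind,
            "subject": c.subject,
            "reference": c.reference_target,
            "distances_cm": c.distances_cm.tolist(),
            "values": c.values.tolist(),
        }
        for c in curves
    ]
    return json.dumps(payload, indent=2)


def sampling_config_to_yaml(config: dict[CurveId, SamplingSpec]) -> str:
    rows = [
        {
            "kind": cid.kind,
            "subject": cid.subject,
            "reference": cid.reference,
            "start_cm": spec.start_cm,
            "step_cm": spec.step_cm,
            "end_cm": spec.end_cm,
        }
        for cid, spec in config.items()
    ]
    return yaml.safe_dump(rows, sort_keys=False)


def sampling_config_from_yaml(text: str) -> dict[CurveId, SamplingSpec]:
    rows = yaml.safe_load(text)
    return {
        CurveId(r["kind"], r["subject"], r["reference"]): SamplingSpec(
            r["start_cm"], r["step_cm"], r["end_cm"]
        )
        for r in rows
    }
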