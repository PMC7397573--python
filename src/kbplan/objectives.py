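"""The inverse-planning objective template and its resolution.

The clinical template fixes the ROI list, objective types, volume
points and weights; only 21 target-dose values (cGy) are tunable and
are what the network predicts.  The remaining doses are either fixed
constants or derived from a free value by a printed offset — e.g. each
primary-target MaxDVH sits 100 cGy above its MinDVH, and the
UniformDose objective sits a configurable 50 (alternatively 75) cGy
above it.  Resolution substitutes the free values and evaluates the
derived/fixed doses into a complete objective list ready for export to
a planning system.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)

N_FREE_OBJECTIVES = 21
DEFAULT_UNIFORM_OFFSET_CGY = 50.0
ALTERNATIVE_UNIFORM_OFFSET_CGY = 75.0


@dataclass(frozen=True)
class FreeDose:
    """A tunable target dose, index 1..21."""

    index: int


@dataclass(frozen=True)
class FixedDose:
    """A constant dose in cGy."""

    value_cGy: float


@dataclass(frozen=True)
class DerivedDose:
    """Free value #base_index plus an offset in cGy.

    ``offset_cGy=None`` marks the UniformDose entries whose offset is
    the configurable uniform offset (50 or 75 cGy).
    """

    base_index: int
    offset_cGy: float | None


DoseRule = FreeDose | FixedDose | DerivedDose


@dataclass(frozen=True)
class ObjectiveTemplateEntry:
    roi: str
    objective_type: str  # MinDVH | MaxDVH | UniformDose
    dose_rule: DoseRule
    volume_percent: float | None
    weight: float | None

    def __post_init__(self) -> None:
        if self.objective_type not in ("MinDVH", "MaxDVH", "UniformDose"):
            raise ValueError(f"unknown objective type {self.objective_type!r}")
        if self.objective_type == "UniformDose" and self.volume_percent is not None:
            raise ValueError("UniformDose objectives carry no volume point")
        if self.objective_type != "UniformDose" and self.volume_percent is None:
            raise ValueError(f"{self.objective_type} objective requires a volume point")


def default_template() -> list[ObjectiveTemplateEntry]:
    """The clinical objective template (21 free doses among 31 entries)."""
    E = ObjectiveTemplateEntry
    return [
        E("GTV_T_P", "MinDVH", FreeDose(1), 98, 90),
        E("GTV_T_P", "MaxDVH", DerivedDose(1, 100), 2, 80),
        E("GTV_T_P", "UniformDose", DerivedDose(1, None), None, None),
        E("CTV1_GTV", "MinDVH", FreeDose(2), 98, 85),
        E("CTV1_GTV", "MaxDVH", DerivedDose(1, 0), 2, 80),
        E("CTV2_CTV1", "MinDVH", FreeDose(3), 98, 85),
        E("CTV2_CTV1", "MaxDVH", FixedDose(6100), 2, 80),
        E("GTV_NL_P", "MinDVH", FreeDose(4), 98, 90),
        E("GTV_NL_P", "MaxDVH", DerivedDose(4, 100), 2, 80),
        E("GTV_NL_P", "UniformDose", DerivedDose(4, None), None, None),
        E("GTV_NR_P", "MinDVH", FreeDose(5), 98, 90),
        E("GTV_NR_P", "MaxDVH", DerivedDose(5, 100), 2, 80),
        E("GTV_NR_P", "UniformDose", DerivedDose(5, None), None, None),
        E("CTV_GTV_NL_P", "MinDVH", FreeDose(6), 98, 85),
        E("CTV_GTV_NL_P", "MaxDVH", FixedDose(6600), 2, 80),
        E("CTV_GTV_NR_P", "MinDVH", FreeDose(7), 98, 85),
        E("CTV_GTV_NR_P", "MaxDVH", FixedDose(6600), 2, 80),
        E("left parotid", "MaxDVH", FreeDose(8), 50, 50),
        E("right parotid", "MaxDVH", FreeDose(9), 50, 50),
        E("brainstem", "MaxDVH", FreeDose(10), 0, 50),
        E("spinal cord", "MaxDVH", FreeDose(11), 0, 50),
        E("left optic lens", "MaxDVH", FreeDose(12), 0, 50),
        E("right optic lens", "MaxDVH", FreeDose(13), 0, 50),
        E("left optic nerve", "MaxDVH", FreeDose(14), 0, 50),
        E("right optic nerve", "MaxDVH", FreeDose(15), 0, 50),
        E("pituitary", "MaxDVH", FreeDose(16), 0, 50),
        E("optic chiasm", "MaxDVH", FreeDose(17), 0, 50),
        E("R5200", "MaxDVH", FreeDose(18), 2, 50),
        E("R4500", "MaxDVH", FreeDose(19), 2, 50),
        E("R3600", "MaxDVH", FreeDose(20), 2, 50),
        E("R3100", "MaxDVH", FreeDose(21), 2, 50),
    ]


def free_indices(template: Sequence[ObjectiveTemplateEntry]) -> list[int]:
    return [
        e.dose_rule.index for e in template if isinstance(e.dose_rule, FreeDose)
    ]


@dataclass
class ResolvedObjective:
    roi: str
    objective_type: str
    dose_cGy: float
    volume_percent: float | None
    weight: float | None


@dataclass
class ObjectiveSet:
    """21 free dose values and the fully resolved objective list."""

    patient_id: str
    free_values_cGy: np.ndarray
    resolved: list[ResolvedObjective]
    uniform_offset_cGy: float = DEFAULT_UNIFORM_OFFSET_CGY


def _evaluate_rule(
    rule: DoseRule, free: np.ndarray, uniform_offset_cGy: float
) -> float:
    if isinstance(rule, FreeDose):
        return float(free[rule.index - 1])
    if isinstance(rule, FixedDose):
        return float(rule.value_cGy)
    offset = rule.offset_cGy if rule.offset_cGy is not None else uniform_offset_cGy
    return float(free[rule.base_index - 1] + offset)


def resolve_objectives(
    free_values_cGy: np.ndarray,
    template: Sequence[ObjectiveTemplateEntry] | None = None,
    uniform_offset_cGy: float = DEFAULT_UNIFORM_OFFSET_CGY,
    patient_id: str = "",
) -> ObjectiveSet:
    """Substitute the 21 free values into the template.

    Derived doses become base value + offset; fixed doses are copied;
    volumes and weights come from the template unchanged.  Free values
    must be finite and non-negative.
    """
    template = template if template is not None else default_template()
    free = np.asarray(free_values_cGy, dtype=float)
    if free.shape != (N_FREE_OBJECTIVES,):
        raise ValueError(
            f"expected {N_FREE_OBJECTIVES} free dose values, got shape {free.shape}"
        )
    idx = sorted(free_indices(template))
    if idx != list(range(1, N_FREE_OBJECTIVES + 1)):
        raise ValueError("template free indices must be exactly 1..21, each once")
    for i, v in enumerate(free, start=1):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"free dose value ({i}) is invalid: {v}")
    resolved = [
        ResolvedObjective(
            e.roi,
            e.objective_type,
            _evaluate_rule(e.dose_rule, free, uniform_offset_cGy),
            e.volume_percent,
            e.weight,
        )
        for e in template
    ]
    return ObjectiveSet(patient_id, free, resolved, uniform_offset_cGy)


#: default bounds (cGy) on each free dose, loose envelopes around the
#: prescription levels (targets) and protocol dose limits (OARs/rings)
DEFAULT_CLAMP_BOUNDS_CGY: dict[int, tuple[float, float]] = {
    1: (6600, 7400),   # GTV_T_P MinDVH, prescription 6996
    2: (5800, 7200),   # CTV1_GTV MinDVH, prescription 6105
    3: (5300, 6400),   # CTV2_CTV1 MinDVH, prescription 5610
    4: (6200, 7000),   # GTV_NL_P MinDVH, prescription 6600
    5: (6200, 7000),   # GTV_NR_P MinDVH
    6: (5300, 6600),   # CTV_GTV_NL_P MinDVH, prescription 5610
    7: (5300, 6600),   # CTV_GTV_NR_P MinDVH
    8: (0, 5500),      # left parotid MaxDVH (V30 < 50% criterion)
    9: (0, 5500),      # right parotid MaxDVH
    10: (0, 6500),     # brainstem MaxDVH (D1cc < 65 Gy)
    11: (0, 4500),     # spinal cord MaxDVH (D1 < 45 Gy)
    12: (0, 800),      # left optic lens MaxDVH (Dmax < 8 Gy)
    13: (0, 800),      # right optic lens MaxDVH
    14: (0, 6200),     # left optic nerve MaxDVH (Dmax < 62 Gy)
    15: (0, 6200),     # right optic nerve MaxDVH
    16: (0, 6600),     # pituitary MaxDVH (Dmax < 66 Gy)
    17: (0, 6600),     # optic chiasm MaxDVH
    18: (0, 6000),     # R5200 ring
    19: (0, 5200),     # R4500 ring
    20: (0, 4300),     # R3600 ring
    21: (0, 3700),     # R3100 ring
}


def clamp_objectives(
    objset: ObjectiveSet,
    bounds: dict[int, tuple[float, float]] | None = None,
    template: Sequence[ObjectiveTemplateEntry] | None = None,
) -> ObjectiveSet:
    """Clamp free values into per-index bounds and re-resolve.

    Guards against network extrapolation outside the plausible dose
    range; any clamping is logged.  Derived doses are recomputed from
    the clamped bases so internal relations keep holding exactly.
    """
    bounds = bounds if bounds is not None else DEFAULT_CLAMP_BOUNDS_CGY
    free = objset.free_values_cGy.copy()
    for i in range(1, N_FREE_OBJECTIVES + 1):
        lo, hi = bounds.get(i, (0.0, np.inf))
        v = free[i - 1]
        clamped = min(max(v, lo), hi)
        if clamped != v:
            log.warning(
                "free dose (%d) clamped from %.1f to %.1f cGy", i, v, clamped
            )
            free[i - 1] = clamped
    return resolve_objectives(
        free, template, objset.uniform_offset_cGy, objset.patient_id
    )


# ---------------------------------------------------------------------------
# Export


@dataclass
class PlanningConfig:
    """Pass-through planning metadata; never consumed by computation."""

    beam_angles_deg: tuple[float, ...] = (210, 260, 310, 0, 52, 104, 156)
    beam_energy: str = "6MV"
    prescriptions: dict = field(default_factory=lambda: {
        "GTV_T_P": {"dose_Gy": 69.96, "fractions": 33},
        "GTV_NL_P": {"dose_Gy": 66.0, "fractions": 33},
        "GTV_NR_P": {"dose_Gy": 66.0, "fractions": 33},
        "CTV1_P": {"dose_Gy": 61.05, "fractions": 33},
        "CTV2_P": {"dose_Gy": 56.1, "fractions": 33},
        "CTV_NL_P": {"dose_Gy": 56.1, "fractions": 33},
        "CTV_NR_P": {"dose_Gy": 56.1, "fractions": 33},
    })
    optimization: dict = field(default_factory=lambda: {
        "type": "DMPO",
        "max_segments": 60,
        "min_segment_area_cm2": 9,
        "min_segment_mu": 9,
        "max_iterations": 100,
        "convolution_dose_iteration": 40,
    })


def _format_dose(d: float) -> str:
    return str(int(d)) if float(d).is_integer() else f"{d:.2f}"


def _format_opt(v: float | None) -> str:
    return "" if v is None else _format_dose(float(v))


CSV_COLUMNS = ["roi", "type", "dose_cGy", "volume_percent", "weight"]


def export_objectives_csv(objset: ObjectiveSet, path: str) -> None:
    """Write the resolved list as CSV with fixed column order.

    Doses are in cGy and serialized as integers when integral; absent
    volume/weight fields are left empty.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in objset.resolved:
            writer.writerow([
                r.roi,
                r.objective_type,
                _format_dose(r.dose_cGy),
                _format_opt(r.volume_percent),
                _format_opt(r.weight),
            ])


def read_objectives_csv(path: str) -> list[ResolvedObjective]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CSV_COLUMNS:
            raise ValueError(f"unexpected objective CSV columns: {reader.fieldnames}")
        for row in reader:
            out.append(ResolvedObjective(
                row["roi"],
                row["type"],
                float(row["dose_cGy"]),
                float(row["volume_percent"]) if row["volume_percent"] else None,
                float(row["weight"]) if row["weight"] else None,
            ))
    return out


def export_planning_block(
    objset: ObjectiveSet, config: PlanningConfig | None, path: str
) -> None:
    """Write a key-value planning block a TPS adapter could consume.

    One ``objective`` line per resolved entry (doses in cGy) plus the
    pass-through metadata; the metadata block is omitted when no config
    is given.
    """
    lines = [f"# kbplan planning block, patient {objset.patient_id}", "unit dose=cGy"]
    for r in objset.resolved:
        fieldsep = [
            f"roi={r.roi}",
            f"type={r.objective_type}",
            f"dose={_format_dose(r.dose_cGy)}",
        ]
        if r.volume_percent is not None:
            fieldsep.append(f"volume={_format_dose(float(r.volume_percent))}")
        if r.weight is not None:
            fieldsep.append(f"weight={_format_dose(float(r.weight))}")
        lines.append("objective " + " ".join(fieldsep))
    if config is not None:
        lines.append("metadata " + yaml.safe_dump({
            "beam_angles_deg": list(config.beam_angles_deg),
            "beam_energy": config.beam_energy,
            "prescriptions": config.prescriptions,
            "optimization": config.optimization,
        }, default_flow_style=True, sort_keys=True).strip())
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _rule_to_dict(rule: DoseRule) -> dict:
    if isinstance(rule, FreeDose):
        return {"free": rule.index}
    if isinstance(rule, FixedDose):
        return {"fixed_cGy": rule.value_cGy}
    return {"base": rule.base_index, "offset_cGy": rule.offset_cGy}


def _rule_from_dict(d: dict) -> DoseRule:
    if "free" in d:
        return FreeDose(int(d["free"]))
    if "fixed_cGy" in d:
        return FixedDose(float(d["fixed_cGy"]))
    return DerivedDose(int(d["base"]),
                       None if d.get("offset_cGy") is None else float(d["offset_cGy"]))


def template_to_yaml(template: Sequence[ObjectiveTemplateEntry]) -> str:
    """Serialize a template (for overriding rows in config files)."""
    return yaml.safe_dump([
        {
            "roi": e.roi, "type": e.objective_type,
            "dose": _rule_to_dict(e.dose_rule),
            "volume_percent": e.volume_percent, "weight": e.weight,
        }
        for e in template
    ], sort_keys=False)


def template_from_yaml(text: str) -> list[ObjectiveTemplateEntry]:
    rows = yaml.safe_load(text)
    return [
        ObjectiveTemplateEntry(r["roi"], r["type"], _rule_from_dict(r["dose"]),
                               r.get("volume_percent"), r.get("weight"))
        for r in rows
    ]


def clamp_bounds_to_yaml(bounds: dict[int, tuple[float, float]]) -> str:
    return yaml.safe_dump({int(i): [float(lo), float(hi)]
                           for i, (lo, hi) in bounds.items()})


def clamp_bounds_from_yaml(text: str) -> dict[int, tuple[float, float]]:
    raw = yaml.safe_load(text)
    return {int(i): (float(v[0]), float(v[1])) for i, v in raw.items()}


def replace_free_value(objset: ObjectiveSet, index: int, value_cGy: float,
                       template: Sequence[ObjectiveTemplateEntry] | None = None
                       ) -> ObjectiveSet:
    """Convenience: change one free value and re-resolve."""
    free = objset.free_values_cGy.copy()
    free[index - 1] = value_cGy
    return resolve_objectives(free, template, objset.uniform_offset_cGy,
                              objset.patient_id)
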