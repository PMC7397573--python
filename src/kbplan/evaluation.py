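"""Plan-quality evaluation: DVH metrics, conformity/homogeneity, criteria.

Dose is carried on the same voxel grid as the structure masks (Gy).
D_x is the minimum dose received by the hottest x% of a structure,
computed on descending-sorted voxel doses with linear interpolation at
the fractional voxel rank: for N voxels the hottest x% spans
f = x/100 * N voxels and D_x is the sorted dose at 0-based fractional
index f - 1 (clipped to [0, N-1]).  D_xcc is the absolute-volume
analogue; V_x is the percentage of the structure receiving at least
x Gy.  The conformity index CI = (A/|PTV|) * (A/B), where A is the PTV
volume at or above the prescription isodose and B the total volume at
or above it; the homogeneity index HI = D5/D95.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import yaml

from .volumes import StructureError, StructureMask, StructureSet, VoxelGrid, grid_from_nifti

log = logging.getLogger(__name__)


@dataclass
class DoseGrid:
    """A dose distribution (Gy) co-registered with a voxel grid."""

    grid: VoxelGrid
    dose_Gy: np.ndarray

    def __post_init__(self) -> None:
        self.dose_Gy = np.asarray(self.dose_Gy, dtype=float)
        if self.dose_Gy.shape != self.grid.shape:
            raise ValueError("dose array shape does not match grid shape")
        if not np.all(np.isfinite(self.dose_Gy)) or np.any(self.dose_Gy < 0):
            raise ValueError("doses must be finite and non-negative")


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of volume receiving at least each dose."""

    roi: str
    dose_bins_Gy: np.ndarray
    cumulative_volume_fraction: np.ndarray


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if mask.is_empty:
        raise StructureError(f"empty structure {mask.name!r}")
    if mask.grid != dose.grid:
        raise StructureError(
            f"grid mismatch between dose grid and structure {mask.name!r}"
        )
    return dose.dose_Gy[mask.voxels]


def compute_dvh(dose: DoseGrid, mask: StructureMask, n_bins: int = 200,
                max_dose_Gy: float | None = None) -> DVHCurve:
    d = _structure_doses(dose, mask)
    top = max_dose_Gy if max_dose_Gy is not None else max(float(d.max()), 1e-9)
    bins = np.linspace(0.0, top, n_bins + 1)
    frac = np.array([(d >= b).mean() for b in bins])
    return DVHCurve(mask.name, bins, frac)


def _dose_at_fractional_count(sorted_desc: np.ndarray, f: float) -> float:
    """Dose at 0-based fractional index f-1 on the descending sort."""
    idx = np.clip(f - 1.0, 0.0, len(sorted_desc) - 1.0)
    lo = int(np.floor(idx))
    hi = int(np.ceil(idx))
    if lo == hi:
        return float(sorted_desc[lo])
    w = idx - lo
    return float((1 - w) * sorted_desc[lo] + w * sorted_desc[hi])


def dose_at_volume(dose: DoseGrid, mask: StructureMask, x_percent: float) -> float:
    """D_x: minimum dose (Gy) of the hottest x% of the structure."""
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must be in (0, 100]")
    d = np.sort(_structure_doses(dose, mask))[::-1]
    return _dose_at_fractional_count(d, x_percent / 100.0 * len(d))


def volume_at_dose(dose: DoseGrid, mask: StructureMask, d_Gy: float) -> float:
    """V_x: percentage of the structure receiving at least ``d_Gy``."""
    d = _structure_doses(dose, mask)
    return 100.0 * int((d >= d_Gy).sum()) / len(d)


def dose_at_cc(dose: DoseGrid, mask: StructureMask, cc: float) -> float:
    """D_xcc: minimum dose (Gy) of the hottest ``cc`` cm^3."""
    d = _structure_doses(dose, mask)
    vol_cc = len(d) * mask.grid.voxel_volume_cc
    if not 0 < cc <= vol_cc:
        raise ValueError(
            f"requested {cc} cc exceeds structure volume {vol_cc:.2f} cc"
        )
    d = np.sort(d)[::-1]
    return _dose_at_fractional_count(d, cc / mask.grid.voxel_volume_cc)


def max_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Dmax: maximum voxel dose (Gy) in the structure."""
    return float(_structure_doses(dose, mask).max())


def conformity_index(dose: DoseGrid, ptv: StructureMask,
                     prescription_Gy: float) -> float:
    """CI = (A/|PTV|) * (A/B); 0 when nothing reaches prescription."""
    if prescription_Gy <= 0:
        raise ValueError("prescription must be positive")
    d_in = _structure_doses(dose, ptv)
    covered = int((d_in >= prescription_Gy).sum())
    total = int((dose.dose_Gy >= prescription_Gy).sum())
    if total == 0:
        return 0.0
    return (covered / len(d_in)) * (covered / total)


def homogeneity_index(dose: DoseGrid, ptv: StructureMask) -> float:
    """HI = D5/D95 within the target; >= 1, with 1 perfectly uniform."""
    d95 = dose_at_volume(dose, ptv, 95)
    if d95 == 0:
        raise ValueError("undefined HI: D95 is zero")
    return dose_at_volume(dose, ptv, 5) / d95


# ---------------------------------------------------------------------------
# Protocol criteria


@dataclass(frozen=True)
class Criterion:
    """One protocol criterion: metric of a ROI against strict bounds.

    ``metric`` is one of D% (arg = volume percent), V (arg = dose Gy,
    value in %), Dcc (arg = cm^3) and Dmax.  Bounds are strict: a value
    exactly on a threshold fails.
    """

    roi: str
    metric: str
    arg: float | None
    lower_Gy: float | None = None
    upper_Gy: float | None = None

    def describe(self) -> str:
        if self.metric == "Dmax":
            name = "Dmax"
        elif self.metric == "Dcc":
            name = f"D{self.arg:g}cc"
        else:
            name = f"{'D' if self.metric == 'D%' else 'V'}{self.arg:g}"
        unit = "%" if self.metric == "V" else "Gy"
        if self.lower_Gy is not None and self.upper_Gy is not None:
            return f"{self.lower_Gy}{unit} < {name} < {self.upper_Gy}{unit}"
        if self.lower_Gy is not None:
            return f"{name} > {self.lower_Gy}{unit}"
        return f"{name} < {self.upper_Gy}{unit}"


def default_criteria() -> list[Criterion]:
    """The institutional planning criteria for locally advanced NPC."""
    return [
        Criterion("GTV_T_P", "D%", 95, lower_Gy=68.96, upper_Gy=70.96),
        Criterion("CTV1_P", "D%", 95, lower_Gy=61.05),
        Criterion("CTV2_P", "D%", 95, lower_Gy=56.1),
        Criterion("GTV_NL_P", "D%", 95, lower_Gy=65.5, upper_Gy=67.0),
        Criterion("GTV_NR_P", "D%", 95, lower_Gy=65.5, upper_Gy=67.0),
        Criterion("CTV_NL_P", "D%", 95, lower_Gy=52.8),
        Criterion("CTV_NR_P", "D%", 95, lower_Gy=52.8),
        Criterion("left parotid", "V", 30, upper_Gy=50.0),
        Criterion("right parotid", "V", 30, upper_Gy=50.0),
        Criterion("brainstem", "Dcc", 1, upper_Gy=65.0),
        Criterion("spinal cord", "D%", 1, upper_Gy=45.0),
        Criterion("left optic lens", "Dmax", None, upper_Gy=8.0),
        Criterion("right optic lens", "Dmax", None, upper_Gy=8.0),
        Criterion("left optic nerve", "Dmax", None, upper_Gy=62.0),
        Criterion("right optic nerve", "Dmax", None, upper_Gy=62.0),
        Criterion("pituitary", "Dmax", None, upper_Gy=66.0),
        Criterion("optic chiasm", "Dmax", None, upper_Gy=66.0),
    ]


@dataclass
class CriterionResult:
    criterion: Criterion
    value: float
    passed: bool


def evaluate_metric(dose: DoseGrid, mask: StructureMask, c: Criterion) -> float:
    if c.metric == "D%":
        return dose_at_volume(dose, mask, c.arg)
    if c.metric == "V":
        return volume_at_dose(dose, mask, c.arg)
    if c.metric == "Dcc":
        return dose_at_cc(dose, mask, c.arg)
    if c.metric == "Dmax":
        return max_dose(dose, mask)
    raise ValueError(f"unknown metric {c.metric!r}")


def check_criteria(
    dose: DoseGrid,
    structures: StructureSet,
    criteria: list[Criterion] | None = None,
) -> list[CriterionResult]:
    """Evaluate every criterion; comparisons are strict as printed."""
    criteria = criteria if criteria is not None else default_criteria()
    results = []
    for c in criteria:
        mask = structures[c.roi]  # raises naming the missing structure
        value = evaluate_metric(dose, mask, c)
        passed = True
        if c.lower_Gy is not None and not value > c.lower_Gy:
            passed = False
        if c.upper_Gy is not None and not value < c.upper_Gy:
            passed = False
        if not passed:
            log.info("criterion failed: %s %s, measured %.3f",
                     c.roi, c.describe(), value)
        results.append(CriterionResult(c, value, passed))
    return results


# ---------------------------------------------------------------------------
# Report and criteria-spec serialization


def results_to_json(results: list[CriterionResult]) -> str:
    return json.dumps([
        {
            "roi": r.criterion.roi,
            "criterion": r.criterion.describe(),
            "value": round(r.value, 6),
            "passed": r.passed,
        }
        for r in results
    ], indent=2)


def results_to_text(results: list[CriterionResult]) -> str:
    lines = [f"{'ROI':<20} {'criterion':<28} {'value':>10}  result"]
    for r in results:
        lines.append(
            f"{r.criterion.roi:<20} {r.criterion.describe():<28} "
            f"{r.value:>10.3f}  {'PASS' if r.passed else 'FAIL'}"
        )
    return "\n".join(lines)


def criteria_to_yaml(criteria: list[Criterion]) -> str:
    return yaml.safe_dump([
        {
            "roi": c.roi, "metric": c.metric, "arg": c.arg,
            "lower_Gy": c.lower_Gy, "upper_Gy": c.upper_Gy,
        }
        for c in criteria
    ], sort_keys=False)


def criteria_from_yaml(text: str) -> list[Criterion]:
    rows = yaml.safe_load(text)
    return [
        Criterion(r["roi"], r["metric"], r.get("arg"),
                  r.get("lower_Gy"), r.get("upper_Gy"))
        for r in rows
    ]


def read_dose_nifti(path: str, grid: VoxelGrid | None = None) -> DoseGrid:
    img = nib.load(path)
    file_grid = grid_from_nifti(img)
    if grid is not None and (
        file_grid.shape != grid.shape or file_grid.spacing_mm != grid.spacing_mm
    ):
        raise StructureError(f"dose grid in {path} does not match structure grid")
    return DoseGrid(grid or file_grid, np.asarray(img.dataobj, dtype=float))


def write_dose_nifti(dose: DoseGrid, path: str) -> None:
    img = nib.Nifti1Image(dose.dose_Gy.astype(np.float32), dose.grid.affine)
    nib.save(img, path)
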