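"""Virtual head-and-neck patients for end-to-end pipeline validation.

The generator emulates the geometry the pipeline consumes: nested
target volumes (primary tumour with two clinical margin shells,
bilateral nodal targets), the ten protocol organs at risk placed at
anatomically plausible offsets, and a cylindrical body contour — all as
boolean masks on a common anisotropic grid (3 mm slice axis by
default).  Geometry is randomised by uniform jitter of centres, radii
and margins so the OVH/TVH curves vary across patients.

A synthetic knowledge library couples each patient's geometric feature
vector to 21 dose objectives through a known (linear by default, by
design sparse) ground-truth mapping, so the learning machinery can be
validated by parameter recovery.  A companion dose-grid generator
produces a smooth "planned" dose (prescription inside each target,
exponential falloff outside) for exercising the plan-evaluation
metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .features import (
    FeatureVector,
    LayoutEntry,
    LibraryMatrix,
    assemble_features,
    build_layout,
)
from .histograms import CurveId, SamplingSpec, compute_curves, default_sampling_config
from .evaluation import DoseGrid
from .volumes import (
    StructureError,
    StructureMask,
    StructureSet,
    VoxelGrid,
    distance_from_structure,
    expand,
    make_auxiliary_structures,
)

log = logging.getLogger(__name__)

BODY_NAME = "BODY"


@dataclass(frozen=True)
class GeometryParams:
    """Layout of the virtual patient (all lengths in mm).

    ``centers_mm``/``radii_mm`` describe ellipsoids for the gross
    targets and OARs; the clinical target volumes are built by true
    Euclidean expansion of the gross volumes (margin + 3 mm setup
    margin), which guarantees the protocol nesting.  ``jitter`` scales
    the random perturbation applied per patient.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    body_radius_mm: float = 82.0
    centers_mm: dict = field(default_factory=lambda: {
        "GTV_T_P": (96.0, 90.0, 120.0),
        "GTV_NL_P": (62.0, 108.0, 80.0),
        "GTV_NR_P": (130.0, 108.0, 80.0),
        "left parotid": (43.0, 98.0, 112.0),
        "right parotid": (149.0, 98.0, 112.0),
        "brainstem": (96.0, 122.0, 138.0),
        "spinal cord": (96.0, 130.0, 57.0),
        "left optic lens": (70.0, 38.0, 152.0),
        "right optic lens": (122.0, 38.0, 152.0),
        "left optic nerve": (80.0, 58.0, 150.0),
        "right optic nerve": (112.0, 58.0, 150.0),
        "pituitary": (96.0, 88.0, 152.0),
        "optic chiasm": (96.0, 74.0, 152.0),
    })
    radii_mm: dict = field(default_factory=lambda: {
        "GTV_T_P": (20.0, 18.0, 15.0),
        "GTV_NL_P": (11.0, 11.0, 13.0),
        "GTV_NR_P": (11.0, 11.0, 13.0),
        "left parotid": (10.0, 14.0, 18.0),
        "right parotid": (10.0, 14.0, 18.0),
        "brainstem": (10.0, 10.0, 26.0),
        "spinal cord": (5.0, 5.0, 33.0),
        "left optic lens": (4.5, 4.5, 4.5),
        "right optic lens": (4.5, 4.5, 4.5),
        "left optic nerve": (10.0, 8.0, 3.0),
        "right optic nerve": (10.0, 8.0, 3.0),
        "pituitary": (5.0, 5.0, 5.0),
        "optic chiasm": (10.0, 5.0, 3.0),
    })
    ctv1_margin_mm: float = 8.0       # 5-10 mm clinical margin around GTV_T
    ctv2_margin_mm: float = 8.0       # second shell around CTV1
    nodal_ctv_margin_mm: float = 5.0  # margin around the nodal GTVs
    ptv_margin_mm: float = 3.0        # setup margin applied to every CTV
    center_jitter_mm: float = 4.0
    radius_jitter_fraction: float = 0.15
    margin_jitter_mm: float = 2.0
    seed: int = 0


def _perturbed(params: GeometryParams, rng: np.random.Generator) -> GeometryParams:
    centers = {
        k: tuple(np.array(v) + rng.uniform(
            -params.center_jitter_mm, params.center_jitter_mm, 3))
        for k, v in params.centers_mm.items()
    }
    radii = {
        k: tuple(np.array(v) * rng.uniform(
            1 - params.radius_jitter_fraction, 1 + params.radius_jitter_fraction, 3))
        for k, v in params.radii_mm.items()
    }
    j = params.margin_jitter_mm
    return replace(
        params,
        centers_mm=centers,
        radii_mm=radii,
        ctv1_margin_mm=params.ctv1_margin_mm + rng.uniform(-j, j),
        ctv2_margin_mm=params.ctv2_margin_mm + rng.uniform(-j, j),
        nodal_ctv_margin_mm=params.nodal_ctv_margin_mm + rng.uniform(-j / 2, j / 2),
    )


def _ellipsoid(grid: VoxelGrid, center_mm, radii_mm) -> np.ndarray:
    xs, ys, zs = grid.coordinates_mm()
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return (
        ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 + ((zs - cz) / rz) ** 2
    ) <= 1.0


def _cylinder_z(grid: VoxelGrid, center_xy_mm, radius_mm) -> np.ndarray:
    xs, ys, _ = grid.coordinates_mm()
    cx, cy = center_xy_mm
    disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_mm**2
    return np.broadcast_to(disk, grid.shape).copy()


def generate_patient(params: GeometryParams) -> StructureSet:
    """Build one virtual patient's structure set (deterministic per seed).

    CTVs come from Euclidean expansion of the GTVs, so the nesting
    GTV_T_P ⊆ CTV1_P ⊆ CTV2_P and GTV_N ⊆ CTV_N holds by construction.
    Raises :class:`StructureError` if a structure leaves the body/grid.
    """
    rng = np.random.default_rng(params.seed)
    p = _perturbed(params, rng)
    grid = VoxelGrid(p.shape, p.spacing_mm)
    extent = np.array(grid.shape) * np.array(grid.spacing_mm)
    center_xy = (extent[0] / 2.0, extent[1] / 2.0)

    s = StructureSet(f"synth-{params.seed}", grid)
    body = StructureMask(BODY_NAME, grid, _cylinder_z(grid, center_xy, p.body_radius_mm))
    s.add(body)

    for name in p.centers_mm:
        voxels = _ellipsoid(grid, p.centers_mm[name], p.radii_mm[name])
        if not voxels.any():
            # structure thinner than the voxel spacing: it degenerates to
            # the voxel whose centre is nearest the structure centre
            idx = tuple(
                int(np.clip(round(c / sp), 0, n - 1))
                for c, sp, n in zip(p.centers_mm[name], grid.spacing_mm, grid.shape)
            )
            voxels[idx] = True
        s.add(StructureMask(name, grid, voxels))

    gtv_t = s["GTV_T_P"]
    ctv1 = expand(gtv_t, p.ctv1_margin_mm + p.ptv_margin_mm).with_name("CTV1_P")
    ctv2 = expand(ctv1, p.ctv2_margin_mm).with_name("CTV2_P")
    s.add(ctv1)
    s.add(ctv2)
    s.add(expand(s["GTV_NL_P"], p.nodal_ctv_margin_mm + p.ptv_margin_mm).with_name("CTV_NL_P"))
    s.add(expand(s["GTV_NR_P"], p.nodal_ctv_margin_mm + p.ptv_margin_mm).with_name("CTV_NR_P"))

    for name in ("CTV2_P", "CTV_NL_P", "CTV_NR_P"):
        outside = s[name].voxels & ~body.voxels
        if outside.any():
            raise StructureError(
                f"target {name!r} extends outside the body contour"
            )
    return s


@dataclass
class GroundTruthMapping:
    """Known feature-to-objective map: Y = A x + b (+ options), in cGy.

    Linear by default.  An optional quadratic term along one feature
    direction (``quad_direction``) demonstrates that the hidden layer
    adds capacity beyond a linear readout.  Gaussian noise of
    ``noise_sd_cGy`` emulates planner variability.  Outputs are clamped
    to ``clamp_cGy``; a well-conditioned mapping is designed so the
    clamp never engages for the sampled geometry distribution.
    """

    A: np.ndarray                 # 21 x n_features
    b: np.ndarray                 # 21
    noise_sd_cGy: float = 0.0
    clamp_cGy: tuple[float, float] = (0.0, 8000.0)
    quad_direction: np.ndarray | None = None   # n_features
    quad_center: float = 0.0
    quad_coeff_cGy: np.ndarray | None = None   # 21

    def objectives(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.A @ x + self.b
        if self.quad_direction is not None:
            s = float(self.quad_direction @ x) - self.quad_center
            y = y + self.quad_coeff_cGy * s * s
        if self.noise_sd_cGy > 0:
            if rng is None:
                raise ValueError("noise requires an rng")
            y = y + rng.normal(0.0, self.noise_sd_cGy, size=y.shape)
        return np.clip(y, *self.clamp_cGy)


#: nominal dose level (cGy) of each of the 21 tunable objectives, used
#: as the intercept around which the synthetic mapping varies
BASE_OBJECTIVES_CGY = np.array([
    6996, 6105, 5610, 6600, 6600, 5610, 5610,   # target MinDVH levels
    3200, 3200, 5000, 4000, 600, 600,           # parotids, brainstem, cord, lenses
    4500, 4500, 5200, 5200,                     # optic nerves, pituitary, chiasm
    5200, 4500, 3600, 3100,                     # dose-falloff rings
], dtype=float)


def sparse_random_mapping(
    layout: list[LayoutEntry] | None = None,
    seed: int = 7,
    noise_sd_cGy: float = 0.0,
    n_active_features: int = 10,
    coefficient_scale_cGy: float = 120.0,
) -> GroundTruthMapping:
    """A sparse random linear ground truth around the nominal doses.

    Each objective depends on ``n_active_features`` randomly chosen
    features with uniform coefficients up to ``coefficient_scale_cGy``;
    intercepts centre the objectives near their nominal values for
    mid-range features.  Useful as a stress case: nothing guarantees
    the chosen features vary in the sampled population, so this mapping
    is not necessarily well-conditioned for recovery.
    """
    layout = layout if layout is not None else build_layout()
    n_features = len(layout)
    rng = np.random.default_rng(seed)
    A = np.zeros((len(BASE_OBJECTIVES_CGY), n_features))
    for j in range(A.shape[0]):
        idx = rng.choice(n_features, size=n_active_features, replace=False)
        A[j, idx] = rng.uniform(-coefficient_scale_cGy, coefficient_scale_cGy,
                                n_active_features)
    b = BASE_OBJECTIVES_CGY - A @ np.full(n_features, 0.5)
    return GroundTruthMapping(A, b, noise_sd_cGy)


def principal_component_mapping(
    X: np.ndarray,
    seed: int = 7,
    n_components: int = 10,
    objective_sd_cGy: float = 150.0,
    noise_sd_cGy: float = 0.0,
    quadratic_sd_cGy: float = 0.0,
) -> GroundTruthMapping:
    """A well-conditioned linear ground truth for a feature population.

    Objectives are random linear combinations of the population's top
    ``n_components`` principal feature-variation modes, scaled so each
    objective has standard deviation ``objective_sd_cGy`` over the
    population and mean equal to its nominal dose.  Coupling the
    objectives to the dominant geometric variation emulates how
    achievable dose levels track anatomy, and guarantees the mapping is
    well conditioned with respect to the generated library.  A nonzero
    ``quadratic_sd_cGy`` adds a quadratic term in the leading mode.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, int((S > 1e-9).sum()))
    comps = Vt[:k]
    score_sd = S[:k] / np.sqrt(X.shape[0])
    R = rng.normal(size=(len(BASE_OBJECTIVES_CGY), k))
    R /= np.linalg.norm(R, axis=1, keepdims=True)
    A = (R * (objective_sd_cGy / score_sd)) @ comps
    b = BASE_OBJECTIVES_CGY - A @ mean
    quad_dir = quad_coeff = None
    quad_center = 0.0
    if quadratic_sd_cGy > 0:
        quad_dir = comps[0] / score_sd[0]
        quad_center = float(quad_dir @ mean)
        # unit-variance score s => Var(s^2) = 2 for Gaussian s
        quad_coeff = rng.normal(size=len(BASE_OBJECTIVES_CGY))
        quad_coeff *= quadratic_sd_cGy / np.sqrt(2.0)
    return GroundTruthMapping(A, b, noise_sd_cGy,
                              quad_direction=quad_dir,
                              quad_center=quad_center,
                              quad_coeff_cGy=quad_coeff)


def extract_features(
    s: StructureSet,
    config: dict[CurveId, SamplingSpec] | None = None,
    body_name: str = BODY_NAME,
) -> FeatureVector:
    """Auxiliary structures -> histogram curves -> ordered feature vector."""
    config = config if config is not None else default_sampling_config()
    if "CTV_ALL" not in s:
        s = make_auxiliary_structures(s, body_name)
    curves = compute_curves(s, config)
    return assemble_features(curves, build_layout(config), s.patient_id)


def generate_library(
    n: int,
    mapping: GroundTruthMapping | None = None,
    seed: int = 0,
    params: GeometryParams | None = None,
    keep_structures: bool = False,
    noise_sd_cGy: float = 0.0,
) -> tuple[LibraryMatrix, list[StructureSet]]:
    """Generate an n-patient knowledge library through the full pipeline.

    Each patient's geometry is independently randomised; features go
    through the real volumes → histograms → features pipeline and
    objectives come from the ground-truth mapping.  When no mapping is
    given, a :func:`principal_component_mapping` is built from the
    generated feature population (deterministic given ``seed``) with
    noise ``noise_sd_cGy``.  Chronological order is generation order.
    Structure sets are only retained with ``keep_structures`` (memory).
    """
    if n < 2:
        raise ValueError("a library needs at least 2 patients")
    base = params if params is not None else GeometryParams()
    layout = build_layout()
    rng = np.random.default_rng(seed)
    patient_seeds = rng.integers(0, 2**31 - 1, size=n)
    noise_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    mapping_seed = int(rng.integers(0, 2**31 - 1))

    ids, X, kept = [], [], []
    for i in range(n):
        try:
            s = generate_patient(replace(base, seed=int(patient_seeds[i])))
            s.patient_id = f"synth-{i:03d}"
            fv = extract_features(s)
        except StructureError as exc:
            raise StructureError(f"patient {i}: {exc}") from exc
        ids.append(s.patient_id)
        X.append(fv.values)
        if keep_structures:
            kept.append(s)
    X = np.array(X)
    if mapping is None:
        mapping = principal_component_mapping(
            X, seed=mapping_seed, noise_sd_cGy=noise_sd_cGy
        )
    Y = np.array([mapping.objectives(x, noise_rng) for x in X])
    return LibraryMatrix(ids, X, Y, layout), kept


#: default prescriptions (Gy) used by the synthetic dose generator;
#: slightly above the protocol minima so D95-type criteria are met with
#: strict comparators on a noiseless grid
DEFAULT_DOSE_PRESCRIPTIONS_GY = {
    "GTV_T_P": 70.0,
    "GTV_NL_P": 66.3,
    "GTV_NR_P": 66.3,
    "CTV1_P": 61.5,
    "CTV2_P": 56.6,
    "CTV_NL_P": 56.6,
    "CTV_NR_P": 56.6,
}


def generate_dose_grid(
    s: StructureSet,
    prescriptions_Gy: dict[str, float] | None = None,
    falloff_mm: float = 8.0,
    seed: int = 0,
    noise_sd_fraction: float = 0.0,
) -> DoseGrid:
    """Smooth synthetic "planned" dose for plan-metric fixtures.

    Each target contributes its prescription inside itself and an
    exponential falloff ``Rx * exp(-d / falloff_mm)`` outside; the dose
    is the voxelwise maximum over targets.  Optional multiplicative
    Gaussian noise (fraction of local dose) is seeded.
    """
    prescriptions = (
        prescriptions_Gy if prescriptions_Gy is not None
        else DEFAULT_DOSE_PRESCRIPTIONS_GY
    )
    present = [t for t in prescriptions if t in s]
    if not present:
        raise StructureError("structure set has none of the prescribed targets")
    dose = np.zeros(s.grid.shape)
    for t in present:
        dist = distance_from_structure(s[t])
        np.maximum(dose, prescriptions[t] * np.exp(-dist / falloff_mm), out=dose)
    if noise_sd_fraction > 0:
        rng = np.random.default_rng(seed)
        dose = dose * (1.0 + rng.normal(0.0, noise_sd_fraction, size=dose.shape))
        dose = np.clip(dose, 0.0, None)
    return DoseGrid(s.grid, dose)
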