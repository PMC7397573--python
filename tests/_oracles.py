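"""Brute-force oracles, independent of the package's distance-transform path.

All distances here are computed as explicit per-voxel minima over
pairwise Euclidean distances between voxel centres (physical mm), never
via scipy's distance transform, so they can certify the implementation
on small grids.
"""

from __future__ import annotations

import numpy as np


def _voxel_centers_mm(shape, spacing) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T
    return idx * np.asarray(spacing, dtype=float)


def brute_min_distances(voxels: np.ndarray, spacing) -> np.ndarray:
    """For every voxel, the min distance (mm) to any True voxel centre."""
    pts = _voxel_centers_mm(voxels.shape, spacing)
    targets = pts[voxels.ravel()]
    out = np.empty(pts.shape[0])
    chunk = 4096
    for i in range(0, pts.shape[0], chunk):
        diff = pts[i : i + chunk, None, :] - targets[None, :, :]
        out[i : i + chunk] = np.sqrt((diff**2).sum(-1)).min(axis=1)
    return out.reshape(voxels.shape)


def brute_expand(voxels: np.ndarray, spacing, d_mm: float) -> np.ndarray:
    return brute_min_distances(voxels, spacing) <= d_mm


def brute_contract(voxels: np.ndarray, spacing, d_mm: float) -> np.ndarray:
    return voxels & (brute_min_distances(~voxels, spacing) > d_mm)


def brute_morph(voxels: np.ndarray, spacing, t_mm: float) -> np.ndarray:
    if t_mm > 0:
        return brute_expand(voxels, spacing, t_mm)
    if t_mm < 0:
        return brute_contract(voxels, spacing, -t_mm)
    return voxels


def brute_ovh_value(oar: np.ndarray, target: np.ndarray, spacing, t_mm: float) -> float:
    morphed = brute_morph(target, spacing, t_mm)
    return (oar & morphed).sum() / oar.sum()


def brute_tvh_value(target: np.ndarray, spacing, t_mm: float) -> float:
    return brute_morph(target, spacing, t_mm).sum() / target.sum()


class BruteMorpher:
    """Caches the two brute-force distance fields of one target."""

    def __init__(self, target: np.ndarray, spacing) -> None:
        self.target = target
        self.dist_out = brute_min_distances(target, spacing)
        self.dist_in = brute_min_distances(~target, spacing)

    def morph(self, t_mm: float) -> np.ndarray:
        if t_mm > 0:
            return self.dist_out <= t_mm
        if t_mm < 0:
            return self.target & (self.dist_in > -t_mm)
        return self.target

    def ovh_value(self, oar: np.ndarray, t_mm: float) -> float:
        return (oar & self.morph(t_mm)).sum() / oar.sum()

    def tvh_value(self, t_mm: float) -> float:
        return self.morph(t_mm).sum() / self.target.sum()


# ---------------------------------------------------------------------------
# DVH metric oracles (same documented interpolation rule, explicit loops)


def oracle_dose_at_fraction(doses: np.ndarray, f: float) -> float:
    """Dose at fractional voxel count f on the descending sort."""
    d = np.sort(np.asarray(doses, dtype=float))[::-1]
    idx = min(max(f - 1.0, 0.0), len(d) - 1.0)
    lo, hi = int(np.floor(idx)), int(np.ceil(idx))
    if lo == hi:
        return float(d[lo])
    w = idx - lo
    return float((1 - w) * d[lo] + w * d[hi])


def oracle_dose_at_volume(doses: np.ndarray, x_percent: float) -> float:
    return oracle_dose_at_fraction(doses, x_percent / 100.0 * len(doses))


def oracle_volume_at_dose(doses: np.ndarray, d_Gy: float) -> float:
    doses = np.asarray(doses, dtype=float)
    return 100.0 * sum(1 for v in doses if v >= d_Gy) / len(doses)


def oracle_dose_at_cc(doses: np.ndarray, cc: float, voxel_volume_cc: float) -> float:
    return oracle_dose_at_fraction(doses, cc / voxel_volume_cc)


def oracle_ci(dose_grid: np.ndarray, ptv: np.ndarray, rx: float) -> float:
    covered = int(((dose_grid >= rx) & ptv).sum())
    total = int((dose_grid >= rx).sum())
    if total == 0:
        return 0.0
    return (covered / ptv.sum()) * (covered / total)


def random_blob(rng: np.random.Generator, shape, spacing,
                n_seeds: int = 3, radius_range=(4.0, 12.0)) -> np.ndarray:
    """Union of a few random ellipsoids; retried until nonempty."""
    spacing = np.asarray(spacing, dtype=float)
    extent = np.asarray(shape) * spacing
    while True:
        out = np.zeros(shape, dtype=bool)
        xs, ys, zs = np.meshgrid(
            *[np.arange(s) * sp for s, sp in zip(shape, spacing)],
            indexing="ij", sparse=True,
        )
        for _ in range(n_seeds):
            c = rng.uniform(0.2, 0.8, 3) * extent
            r = rng.uniform(*radius_range, 3)
            out |= (
                ((xs - c[0]) / r[0]) ** 2
                + ((ys - c[1]) / r[1]) ** 2
                + ((zs - c[2]) / r[2]) ** 2
            ) <= 1.0
        if out.any():
            return out
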