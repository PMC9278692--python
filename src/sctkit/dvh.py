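"""Plan comparison: cumulative DVHs, gamma analysis, difference histograms.

The gamma index of Low combines a dose-difference criterion dD (percent of a
normalization dose) with a distance-to-agreement criterion dd (mm).  For a
reference point r_r, every evaluated position r_e within a search radius is
scored

    Gamma(r_e, r_r) = sqrt( |r_e - r_r|^2 / dd^2 + (D_e(r_e) - D_r(r_r))^2 / dD^2 )

and gamma(r_r) is the minimum over r_e, here taken over a sub-grid of spacing
dd/3 with trilinear interpolation of the evaluated dose, then capped (default
2).  Points below a low-dose threshold (default 10% of the normalization,
itself defaulting to the reference maximum — a global gamma) are excluded
from the pass rate.  The pass rate is the percentage of evaluated points with
gamma <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .grid import DoseGrid, StructureMask

__all__ = [
    "DVHCurve", "compute_dvh", "dvh_stats",
    "GammaParams", "GammaMap", "gamma_map", "gamma_plane",
    "resample_dose", "gamma_histogram", "dose_diff_histogram",
    "isodose_contours", "contour_divergence",
]


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure receiving >= each dose."""

    dose_gy: np.ndarray
    volume_fraction: np.ndarray
    structure: str = ""

    def v_at(self, dose_gy: float) -> float:
        """Volume fraction receiving at least ``dose_gy`` (right-continuous)."""
        return float(np.interp(dose_gy, self.dose_gy, self.volume_fraction))


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH of ``mask`` with dose axis step ``bin_width_gy``."""
    dose.require_same_grid(mask, "dose and mask")
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0")
    vals = dose.data[mask.data]
    top = max(float(vals.max()), bin_width_gy)
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = (vals[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(edges, frac, structure=mask.name)


def dvh_stats(dose: DoseGrid, mask: StructureMask,
              prescription_gy: float | None = None) -> dict:
    """Min/mean/max structure dose as percent of prescription, plus V100.

    V100 is the fraction of the structure receiving at least the full
    prescription dose, reported in percent.
    """
    dose.require_same_grid(mask, "dose and mask")
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    pres = dose.prescription_gy if prescription_gy is None else prescription_gy
    if pres <= 0:
        raise ValueError("prescription must be > 0")
    vals = dose.data[mask.data]
    return {
        "min_pct": 100.0 * float(vals.min()) / pres,
        "mean_pct": 100.0 * float(vals.mean()) / pres,
        "max_pct": 100.0 * float(vals.max()) / pres,
        "v100_pct": 100.0 * float((vals >= pres).mean()),
    }


# ---------------------------------------------------------------------------
# Gamma analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaParams:
    """Gamma criteria; defaults are the common clinical 3%/2 mm, 10% threshold."""

    dd_pct: float = 3.0          # dose-difference criterion, % of normalization
    dta_mm: float = 2.0          # distance-to-agreement criterion
    threshold_pct: float = 10.0  # low-dose exclusion, % of normalization
    normalization_gy: float | None = None  # None -> max of reference (global)
    search_factor: float = 3.0   # search radius in multiples of dta
    interp_fraction: int = 3     # sub-grid spacing = dta / interp_fraction
    cap: float = 2.0

    def __post_init__(self):
        if self.dd_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose and distance criteria must be > 0")
        if self.cap < 1:
            raise ValueError("gamma cap must be >= 1")


@dataclass
class GammaMap:
    """Per-voxel capped gamma values plus pass/fail statistics."""

    gamma: np.ndarray          # NaN where not evaluated
    evaluated: np.ndarray      # bool: above threshold, valid, searchable
    pass_rate_pct: float
    params: GammaParams
    spacing: tuple
    origin: tuple

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated.sum())


def _candidate_offsets(p: GammaParams, axes: tuple[int, ...]) -> np.ndarray:
    """Search offsets (mm, (n,3)) on the sub-grid, sorted by distance."""
    delta = p.dta_mm / p.interp_fraction
    radius = p.search_factor * p.dta_mm
    k = int(np.floor(radius / delta + 1e-9))
    ax_offsets = [np.arange(-k, k + 1) * delta if a in axes else np.array([0.0])
                  for a in range(3)]
    oz, oy, ox = np.meshgrid(*ax_offsets, indexing="ij")
    offs = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)
    norms = np.linalg.norm(offs, axis=1)
    offs = offs[norms <= radius + 1e-9]
    norms = np.linalg.norm(offs, axis=1)
    order = np.argsort(norms, kind="stable")
    return offs[order]


def gamma_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    params: GammaParams = GammaParams(),
    axes: tuple[int, ...] = (0, 1, 2),
    region: np.ndarray | None = None,
) -> GammaMap:
    """Gamma of ``evaluated`` against ``reference`` on a common grid.

    Both grids must already share a geometry (see :func:`resample_dose`).
    ``axes`` restricts the spatial search (e.g. in-plane only for 2D gamma);
    ``region`` optionally limits the evaluation to a boolean sub-region.

    The search enumerates every sub-grid offset within the radius, sorted by
    distance so each voxel can stop as soon as the distance term alone
    exceeds its current best — which cannot change the minimum.
    """
    reference.require_same_grid(evaluated, "reference and evaluated dose")
    norm = params.normalization_gy
    if norm is None:
        norm = float(reference.data[reference.valid].max())
    if norm <= 0:
        raise ValueError("normalization dose must be > 0")
    dd_abs = params.dd_pct / 100.0 * norm
    thresh = params.threshold_pct / 100.0 * norm

    eval_mask = reference.valid & evaluated.valid & (reference.data >= thresh)
    if region is not None:
        eval_mask &= region

    gamma = np.full(reference.shape, np.nan)
    if not eval_mask.any():
        return GammaMap(gamma, eval_mask, 100.0, params,
                        reference.spacing, reference.origin)

    spacing = np.asarray(reference.spacing)
    idx = np.argwhere(eval_mask).astype(float)          # (n, 3) voxel coords
    ref_vals = reference.data[eval_mask]
    eval_data = evaluated.data.astype(float)
    eval_valid = evaluated.valid.astype(float)

    offs = _candidate_offsets(params, axes)
    dist2 = (np.linalg.norm(offs, axis=1) / params.dta_mm) ** 2

    best = np.full(idx.shape[0], np.inf)
    seen = np.zeros(idx.shape[0], dtype=bool)  # voxel had >=1 admissible candidate
    active = np.arange(idx.shape[0])
    for o, d2 in zip(offs, dist2):
        if active.size == 0:
            break
        coords = (idx[active] + o / spacing).T
        dvals = ndimage.map_coordinates(eval_data, coords, order=1,
                                        mode="constant", cval=np.nan)
        vvals = ndimage.map_coordinates(eval_valid, coords, order=1,
                                        mode="constant", cval=0.0)
        ok = np.isfinite(dvals) & (vvals > 0.999)
        g2 = np.where(ok, d2 + ((dvals - ref_vals[active]) / dd_abs) ** 2, np.inf)
        better = g2 < best[active]
        best[active[better]] = g2[better]
        seen[active[ok]] = True
        # later offsets have a larger distance term; voxels already at or
        # below it are finished
        active = active[best[active] > d2]

    g = np.sqrt(best)
    g = np.minimum(g, params.cap)
    evaluated_final = eval_mask.copy()
    flat = np.argwhere(eval_mask)
    drop = ~seen
    if drop.any():
        evaluated_final[tuple(flat[drop].T)] = False
        g = g[~drop]
        flat = flat[~drop]
    gamma[tuple(flat.T)] = g
    n = g.size
    pass_rate = 100.0 * float((g <= 1.0).sum()) / n if n else 100.0
    return GammaMap(gamma, evaluated_final, pass_rate, params,
                    reference.spacing, reference.origin)


def gamma_plane(
    reference: DoseGrid,
    evaluated: DoseGrid,
    params: GammaParams = GammaParams(),
    plane: str = "axial",
    index: int | None = None,
) -> GammaMap:
    """2D gamma on one orthogonal plane (default: the central slice).

    The spatial search is restricted to the plane, matching planar gamma
    tools operating on exported orthogonal dose slices.
    """
    axis = {"axial": 0, "coronal": 1, "sagittal": 2}.get(plane)
    if axis is None:
        raise ValueError(f"plane must be axial/coronal/sagittal, got {plane!r}")
    if index is None:
        index = reference.shape[axis] // 2
    region = np.zeros(reference.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = index
    region[tuple(sl)] = True
    axes = tuple(a for a in range(3) if a != axis)
    return gamma_map(reference, evaluated, params, axes=axes, region=region)


def resample_dose(dose: DoseGrid, target) -> DoseGrid:
    """Trilinearly resample a dose grid onto the geometry of ``target``.

    ``target`` is any object with shape/spacing/origin.  Voxels whose sample
    point falls outside the source extent are zeroed and marked invalid so
    gamma excludes them.
    """
    t_shape = tuple(target.shape)
    t_spacing = np.asarray(target.spacing, dtype=float)
    t_origin = np.asarray(target.origin, dtype=float)
    s_spacing = np.asarray(dose.spacing, dtype=float)
    s_origin = np.asarray(dose.origin, dtype=float)

    idx = np.indices(t_shape, dtype=float)
    world = t_origin[:, None, None, None] + idx * t_spacing[:, None, None, None]
    src_idx = (world - s_origin[:, None, None, None]) / s_spacing[:, None, None, None]

    inside = np.ones(t_shape, dtype=bool)
    for a in range(3):
        inside &= (src_idx[a] >= 0) & (src_idx[a] <= dose.shape[a] - 1)
    if not inside.any():
        raise ValueError("target grid does not overlap the source dose extent")

    flat = src_idx.reshape(3, -1)
    data = ndimage.map_coordinates(dose.data, flat, order=1, mode="constant",
                                   cval=0.0).reshape(t_shape)
    vsrc = ndimage.map_coordinates(dose.valid.astype(float), flat, order=1,
                                   mode="constant", cval=0.0).reshape(t_shape)
    valid = inside & (vsrc > 0.999)
    data = np.where(valid, data, 0.0)
    return DoseGrid(np.clip(data, 0.0, None),
                    tuple(t_spacing), tuple(t_origin),
                    prescription_gy=dose.prescription_gy,
                    fractions=dose.fractions, valid=valid)


# ---------------------------------------------------------------------------
# Histograms and isodose contours
# ---------------------------------------------------------------------------

def gamma_histogram(g: GammaMap, bins: int = 256) -> pd.DataFrame:
    """Histogram of gamma values over evaluated voxels; default 256 bins."""
    vals = g.gamma[g.evaluated]
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, g.params.cap))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def dose_diff_histogram(
    reference: DoseGrid,
    evaluated: DoseGrid,
    threshold_pct: float = 10.0,
    bins: int = 1024,
    normalization_gy: float | None = None,
    range_pct: tuple[float, float] = (-100.0, 100.0),
) -> tuple[pd.DataFrame, float]:
    """Percent dose-difference histogram above a low-dose threshold.

    Differences are ``100 (evaluated - reference) / normalization`` at every
    valid voxel whose reference dose exceeds the threshold; returns the
    histogram (default 1024 bins) and the mean percent difference.
    """
    reference.require_same_grid(evaluated, "reference and evaluated dose")
    norm = normalization_gy
    if norm is None:
        norm = float(reference.data[reference.valid].max())
    sel = reference.valid & evaluated.valid & (
        reference.data >= threshold_pct / 100.0 * norm
    )
    diff = 100.0 * (evaluated.data[sel] - reference.data[sel]) / norm
    counts, edges = np.histogram(np.clip(diff, *range_pct), bins=bins, range=range_pct)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
    return hist, float(diff.mean()) if diff.size else 0.0


def isodose_contours(
    dose: DoseGrid,
    levels_gy: list[float],
    plane: str = "axial",
    index: int | None = None,
) -> dict[float, list[np.ndarray]]:
    """Iso-level polylines on one orthogonal plane, in world mm.

    Contours are extracted by marching squares; a level outside the plane's
    dose range yields an empty list.  Each polyline is an (n, 2) array of
    (row mm, col mm) in-plane coordinates.
    """
    axis = {"axial": 0, "coronal": 1, "sagittal": 2}.get(plane)
    if axis is None:
        raise ValueError(f"plane must be axial/coronal/sagittal, got {plane!r}")
    if index is None:
        index = dose.shape[axis] // 2
    sl = [slice(None)] * 3
    sl[axis] = index
    img = dose.data[tuple(sl)]
    inplane_axes = [a for a in range(3) if a != axis]
    sp = [dose.spacing[a] for a in inplane_axes]
    og = [dose.origin[a] for a in inplane_axes]

    out: dict[float, list[np.ndarray]] = {}
    for level in levels_gy:
        if level <= img.min() or level >= img.max():
            out[float(level)] = []
            continue
        polys = measure.find_contours(img, level)
        out[float(level)] = [
            np.stack([og[0] + c[:, 0] * sp[0], og[1] + c[:, 1] * sp[1]], axis=1)
            for c in polys
        ]
    return out


def contour_divergence(a: list[np.ndarray], b: list[np.ndarray]) -> float:
    """Max in-plane distance between two matched contour sets (mm).

    Symmetric directed max-min point distance; 0 for identical sets, NaN if
    either set is empty.
    """
    from scipy.spatial import cKDTree

    if not a or not b:
        return float("nan")
    pa = np.concatenate(a, axis=0)
    pb = np.concatenate(b, axis=0)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    return float(max(d_ab.max(), d_ba.max()))
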