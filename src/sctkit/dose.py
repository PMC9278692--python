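"""Stand-in dose engine: divergent-beam exponential attenuation ray tracing.

This is explicitly NOT a clinical dose algorithm (no Boltzmann transport,
scatter kernels, buildup or MLC modelling).  Its job in the assessment loop
is narrower: a deterministic operator, smooth in the electron-density map,
that converts HU/ED errors into dose errors so that plan-comparison
statistics (DVH, gamma) respond to image fidelity the way they would under a
clinical engine.  All dose numbers it produces are labelled stand-in.

Each beam deposits ``weight * exp(-mu * d_rad)`` at voxels inside its
divergent rectangular field, where ``d_rad`` is the water-equivalent depth —
the line integral of relative electron density from the source to the voxel.
An arc is approximated by equally spaced static beams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import DoseGrid, ImageVolume, StructureMask

__all__ = [
    "Beam", "arc_beams", "radiological_depth", "compute_dose",
    "dose_sensitivity_report",
]


@dataclass(frozen=True)
class Beam:
    """One static divergent beam in the axial plane.

    Gantry angle 0 deg points down onto the anterior surface (source at
    negative y); angles increase clockwise when viewed from the feet.
    """

    gantry_deg: float
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x)
    field_width_mm: float = 60.0   # lateral, at the isocenter plane
    field_height_mm: float = 60.0  # along z, at the isocenter plane
    weight: float = 1.0
    mu_per_mm: float = 0.005
    sad_mm: float = 1000.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("beam weight must be >= 0")
        if self.mu_per_mm <= 0:
            raise ValueError("attenuation coefficient mu must be > 0")

    @property
    def source_mm(self) -> np.ndarray:
        """Source position (z, y, x) in world mm."""
        theta = np.deg2rad(self.gantry_deg)
        iso = np.asarray(self.isocenter_mm, dtype=float)
        # gantry 0: source anterior (-y); rotation in the (y, x) plane
        dy, dx = -np.cos(theta), np.sin(theta)
        return iso + self.sad_mm * np.array([0.0, dy, dx])


def arc_beams(
    n_beams: int = 12,
    arc_start_deg: float = 181.0,
    arc_stop_deg: float = 539.0,
    **beam_kwargs,
) -> list[Beam]:
    """Approximate a (partial) arc by equally spaced static beams."""
    if n_beams < 1:
        raise ValueError("need at least one beam")
    angles = np.linspace(arc_start_deg, arc_stop_deg, n_beams, endpoint=False)
    return [Beam(gantry_deg=float(a) % 360.0, **beam_kwargs) for a in angles]


def _ray_box_entry(source: np.ndarray, targets: np.ndarray,
                   lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Parameter t in [0, 1] where each source->target segment enters the box."""
    d = targets - source
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - source) / d
        t2 = (hi - source) / d
    tmin = np.where(np.isfinite(t1), np.minimum(t1, t2), -np.inf)
    t_entry = np.clip(np.nanmax(tmin, axis=1), 0.0, 1.0)
    return t_entry


def radiological_depth(
    ed: ImageVolume,
    source_mm,
    targets_mm: np.ndarray,
    step_mm: float | None = None,
) -> np.ndarray:
    """Water-equivalent depth from the source to each target point (mm).

    Line integral of relative ED along the straight ray, midpoint-sampled
    with a step no larger than half the smallest voxel spacing.  ED outside
    the grid counts as vacuum, so the portion of the ray before the grid
    contributes nothing — consistent with a source sitting in air.
    """
    source = np.asarray(source_mm, dtype=float)
    targets = np.atleast_2d(np.asarray(targets_mm, dtype=float))
    if step_mm is None:
        step_mm = 0.5 * min(ed.spacing)

    origin = np.asarray(ed.origin)
    spacing = np.asarray(ed.spacing)
    lo = origin - 0.5 * spacing
    hi = origin + (np.asarray(ed.shape) - 0.5) * spacing

    t_entry = _ray_box_entry(source, targets, lo, hi)
    seg_start = source + t_entry[:, None] * (targets - source)
    seg = targets - seg_start
    length = np.linalg.norm(seg, axis=1)

    n_steps = max(int(np.ceil(length.max() / step_mm)), 1) if length.max() > 0 else 1
    # midpoint rule with a per-ray step <= step_mm
    frac = (np.arange(n_steps) + 0.5) / n_steps
    pts = seg_start[:, None, :] + frac[None, :, None] * seg[:, None, :]
    idx = (pts - origin) / spacing  # (n, n_steps, 3) voxel coordinates
    vals = ndimage.map_coordinates(
        ed.data.astype(float),
        idx.reshape(-1, 3).T,
        order=1, mode="constant", cval=0.0,
    ).reshape(idx.shape[:2])
    return vals.sum(axis=1) * (length / n_steps)


def _beam_dose(ed: ImageVolume, beam: Beam, body: np.ndarray | None) -> np.ndarray:
    iso = np.asarray(beam.isocenter_mm, dtype=float)
    source = beam.source_mm
    axis = iso - source
    axis /= np.linalg.norm(axis)
    # in-plane unit vector perpendicular to the beam axis (z stays separate)
    perp = np.array([0.0, -axis[2], axis[1]])

    zax, yax, xax = (
        np.asarray(o) + np.arange(n) * s
        for n, s, o in zip(ed.shape, ed.spacing, ed.origin)
    )
    zz, yy, xx = np.meshgrid(zax, yax, xax, indexing="ij")
    rel = np.stack([zz - source[0], yy - source[1], xx - source[2]], axis=-1)

    s_axis = rel @ axis                       # distance along beam axis
    u = rel @ perp                            # lateral offset
    v = zz - iso[0]                           # offset along z from isocenter plane
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = s_axis / beam.sad_mm
    infield = (
        (s_axis > 0)
        & (np.abs(u) <= 0.5 * beam.field_width_mm * scale)
        & (np.abs(v) <= 0.5 * beam.field_height_mm * scale)
    )
    if body is not None:
        infield &= body

    dose = np.zeros(ed.shape, dtype=float)
    if not infield.any():
        return dose
    targets = np.stack([zz[infield], yy[infield], xx[infield]], axis=1)
    depth = radiological_depth(ed, source, targets)
    dose[infield] = beam.weight * np.exp(-beam.mu_per_mm * depth)
    return dose


def compute_dose(
    ed: ImageVolume,
    beams: list[Beam],
    prescription_gy: float = 50.0,
    fractions: int = 5,
    ptv: StructureMask | None = None,
    body: StructureMask | None = None,
) -> DoseGrid:
    """Sum per-beam dose and optionally scale mean PTV dose to prescription.

    With a PTV mask the grid is rescaled so the mean PTV dose equals the
    prescription; without one the raw beam-weight sum is returned in
    prescription-free units.  Restricting to a ``body`` mask skips dose in
    surrounding air (where it is physically meaningless anyway).
    """
    if not beams:
        raise ValueError("need at least one beam")
    bodym = body.data if body is not None else None
    total = np.zeros(ed.shape, dtype=float)
    for beam in beams:
        total += _beam_dose(ed, beam, bodym)
    if ptv is not None:
        if ptv.is_empty():
            raise ValueError("PTV mask is empty; cannot scale to prescription")
        mean_ptv = total[ptv.data].mean()
        if mean_ptv <= 0:
            raise ValueError("no dose reaches the PTV; check beam geometry")
        total *= prescription_gy / mean_ptv
    return DoseGrid(total, ed.spacing, ed.origin,
                    prescription_gy=prescription_gy, fractions=fractions)


def dose_sensitivity_report(
    doses: dict[str, DoseGrid],
    masks: dict[str, StructureMask],
    reference: str = "ct",
) -> pd.DataFrame:
    """Per-structure dose statistics for each plan, plus deltas vs a reference.

    One row per (plan, structure) with min/mean/max voxel dose as percent of
    prescription, and the mean percent-dose difference to the reference plan
    over the same structure.
    """
    if reference not in doses:
        raise KeyError(f"reference plan {reference!r} not among {list(doses)}")
    ref = doses[reference]
    for label, d in doses.items():
        ref.require_same_grid(d, f"dose grids ({reference} vs {label})")
    rows = []
    for label, d in doses.items():
        for sname, m in masks.items():
            d.require_same_grid(m, "dose grid and mask")
            vals = d.data[m.data]
            if vals.size == 0:
                raise ValueError(f"mask {sname!r} is empty")
            pres = d.prescription_gy
            diff = 100.0 * (vals - ref.data[m.data]).mean() / pres
            rows.append({
                "plan": label, "structure": sname,
                "min_pct": 100.0 * vals.min() / pres,
                "mean_pct": 100.0 * vals.mean() / pres,
                "max_pct": 100.0 * vals.max() / pres,
                "mean_diff_vs_ref_pct": diff,
            })
    return pd.DataFrame(rows)
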