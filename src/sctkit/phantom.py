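"""Seeded digital abdominal phantoms: planning CT, degraded CBCT, daily anatomy.

The assessment pipeline needs three linked inputs per subject that no public
archive provides in paired form:

* a planning CT with known organ HU statistics,
* a same-day CBCT counterpart whose organ means drift and whose images carry
  cupping, noise and streak artifacts, and
* a "deformed CT" surrogate: the daily anatomy with a bounded smooth residual
  misalignment, standing in for a deformable registration with target
  registration error.

Phantoms are built from ellipsoid / cylinder / sphere primitives painted in
listed order (later organs overwrite earlier ones) over a soft-tissue body on
an air background.  Every generator output is a pure function of its spec and
seed.  Default organ means and standard deviations follow measured abdominal
CT statistics (aorta 40, spinal canal 22, heart 36, bones 349, kidney 21,
lungs -719, liver 54 HU); the default degradation drifts organ means toward
the corresponding on-board-imager CBCT statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ImageVolume, StructureMask, StructureSet

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "DegradationSpec",
    "AnatomyPerturbation",
    "make_phantom_ct",
    "degrade_to_cbct",
    "perturb_anatomy",
    "make_ctdef_surrogate",
    "generate_dataset",
    "default_phantom_spec",
    "default_degradation_spec",
    "TABLE_CT_HU",
    "TABLE_CBCT_HU",
]

# Measured abdominal organ HU (mean, STD) on planning CT and on CBCT.
TABLE_CT_HU = {
    "aorta": (40.0, 4.0),
    "spinal_canal": (22.0, 6.0),
    "heart": (36.0, 2.0),
    "bones": (349.0, 64.0),
    "kidney": (21.0, 7.0),
    "lungs": (-719.0, 11.0),
    "liver": (54.0, 3.0),
}
TABLE_CBCT_HU = {
    "aorta": (63.0, 14.0),
    "spinal_canal": (26.0, 2.0),
    "heart": (74.0, 13.0),
    "bones": (385.0, 44.0),
    "kidney": (8.0, 12.0),
    "lungs": (-600.0, 97.0),
    "liver": (38.0, 13.0),
}

AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0


@dataclass(frozen=True)
class OrganSpec:
    """One painted primitive.

    ``shape`` is one of ``ellipsoid``, ``sphere``, ``cylinder`` (axis along
    z).  ``center_mm`` is (z, y, x) in world mm; ``size_mm`` gives semi-axes
    (z, y, x) for ellipsoids, the radius (scalar) for spheres, and
    (half-length z, semi-axis y, semi-axis x) for cylinders.
    """

    name: str
    shape: str
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    mean_hu: float
    std_hu: float

    def __post_init__(self):
        if self.shape not in ("ellipsoid", "sphere", "cylinder"):
            raise ValueError(f"unknown organ shape {self.shape!r}")
        if self.std_hu < 0:
            raise ValueError("organ HU std must be >= 0")

    @property
    def semi_axes(self) -> np.ndarray:
        s = np.asarray(self.size_mm, dtype=float).ravel()
        if self.shape == "sphere":
            return np.full(3, float(s[0]))
        if s.size != 3:
            raise ValueError(f"{self.name}: size_mm must give 3 values for {self.shape}")
        return s


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue statistics of one digital subject."""

    grid_shape: tuple[int, int, int] = (40, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 3.5, 3.5)
    body_semiaxes_mm: tuple[float, float] = (95.0, 105.0)  # (y, x); body spans z
    organs: tuple[OrganSpec, ...] = ()
    ptv_center_mm: tuple[float, float, float] = (5.0, -5.0, 45.0)
    ptv_radius_mm: float = 15.0
    background_hu: float = SOFT_TISSUE_HU
    background_std_hu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be >= 16 voxels per axis")

    @property
    def origin(self) -> tuple[float, float, float]:
        # body-centred frame: world (0,0,0) at the grid centre
        sh = np.asarray(self.grid_shape, dtype=float)
        sp = np.asarray(self.spacing, dtype=float)
        o = -(sh - 1) * sp / 2.0
        return (float(o[0]), float(o[1]), float(o[2]))

    def world_axes(self):
        o = self.origin
        return tuple(
            o[i] + np.arange(self.grid_shape[i]) * self.spacing[i] for i in range(3)
        )

    def half_extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing) / 2.0


def _default_organs() -> tuple[OrganSpec, ...]:
    t = TABLE_CT_HU
    return (
        OrganSpec("lungs", "ellipsoid", (45, -25, -55), (28, 42, 36), *t["lungs"]),
        OrganSpec("lungs_r", "ellipsoid", (45, -25, 55), (28, 42, 36), *t["lungs"]),
        OrganSpec("liver", "ellipsoid", (5, -5, 45), (38, 52, 48), *t["liver"]),
        OrganSpec("heart", "ellipsoid", (48, -12, -10), (20, 26, 26), *t["heart"]),
        OrganSpec("kidney", "ellipsoid", (-30, 40, -45), (22, 18, 16), *t["kidney"]),
        OrganSpec("kidney_r", "ellipsoid", (-30, 40, 45), (22, 18, 16), *t["kidney"]),
        OrganSpec("aorta", "cylinder", (0, 18, -8), (68, 9, 9), *t["aorta"]),
        OrganSpec("bones", "cylinder", (0, 60, 0), (70, 16, 16), *t["bones"]),
        OrganSpec("spinal_canal", "cylinder", (0, 60, 0), (70, 6, 6), *t["spinal_canal"]),
    )


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Desk-scale abdominal phantom with the measured CT organ statistics."""
    kw = dict(organs=_default_organs(), seed=seed)
    kw.update(overrides)
    return PhantomSpec(**kw)


def _primitive_mask(spec: PhantomSpec, organ: OrganSpec) -> np.ndarray:
    zax, yax, xax = spec.world_axes()
    cz, cy, cx = organ.center_mm
    az, ay, ax = organ.semi_axes
    if organ.shape == "cylinder":
        inplane = (
            ((yax[:, None] - cy) / ay) ** 2 + ((xax[None, :] - cx) / ax) ** 2
        ) <= 1.0
        along = np.abs(zax - cz) <= az
        return along[:, None, None] & inplane[None, :, :]
    return (
        ((zax[:, None, None] - cz) / az) ** 2
        + ((yax[None, :, None] - cy) / ay) ** 2
        + ((xax[None, None, :] - cx) / ax) ** 2
    ) <= 1.0


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    _, yax, xax = spec.world_axes()
    by, bx = spec.body_semiaxes_mm
    inplane = ((yax[:, None] / by) ** 2 + (xax[None, :] / bx) ** 2) <= 1.0
    return np.broadcast_to(inplane[None, :, :], spec.grid_shape).copy()


def _check_inside_grid(spec: PhantomSpec, organ: OrganSpec) -> None:
    half = spec.half_extent_mm()
    c = np.asarray(organ.center_mm, dtype=float)
    s = organ.semi_axes
    if np.any(np.abs(c) + s > half + 1e-9):
        raise ValueError(
            f"organ {organ.name!r} extends outside the grid "
            f"(|center|+size={np.abs(c) + s} vs half extent {half})"
        )


def make_phantom_ct(spec: PhantomSpec) -> tuple[ImageVolume, StructureSet]:
    """Paint the planning-CT phantom and return it with its structure set.

    Organs are painted in listed order (later organs win on overlap) as
    ``mean + N(0, std)`` per voxel; the body outside any organ is soft tissue
    and everything outside the body is air.  Masks are returned for every
    organ, the PTV, and the body.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    body = _body_mask(spec)
    vol = np.full(spec.grid_shape, AIR_HU, dtype=float)
    vol[body] = spec.background_hu + rng.normal(
        0.0, spec.background_std_hu, size=int(body.sum())
    )

    structs = StructureSet()
    origin, spacing = spec.origin, spec.spacing
    structs.add(StructureMask("body", body, spacing, origin))

    organ_masks: dict[str, np.ndarray] = {}
    for organ in spec.organs:
        _check_inside_grid(spec, organ)
        mask = _primitive_mask(spec, organ) & body
        vol[mask] = organ.mean_hu + rng.normal(0.0, organ.std_hu, size=int(mask.sum()))
        # later organs own the overlap, so earlier masks shed those voxels
        for prev in organ_masks:
            organ_masks[prev] &= ~mask
        organ_masks[organ.name] = mask
    for name, mask in organ_masks.items():
        structs.add(StructureMask(name, mask, spacing, origin))

    ptv = OrganSpec("ptv", "sphere", spec.ptv_center_mm,
                    (spec.ptv_radius_mm,) * 3, 0.0, 0.0)
    _check_inside_grid(spec, ptv)
    structs.add(StructureMask("ptv", _primitive_mask(spec, ptv) & body, spacing, origin))

    return ImageVolume(vol, spacing, origin), structs


# ---------------------------------------------------------------------------
# CBCT degradation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegradationSpec:
    """Artifact model turning a planning-quality CT into a CBCT look-alike.

    cupping_hu
        HU depression at the body centre (0 at the surface), the scatter
        cupping artifact.
    tissue_bias_hu
        Organ-class name -> additive HU shift; ``"background"`` shifts
        soft tissue outside every listed organ.
    """

    cupping_hu: float = 25.0
    noise_sigma_hu: float = 12.0
    streak_count: int = 6
    streak_amplitude_hu: float = 60.0
    streak_width_mm: float = 2.0
    tissue_bias_hu: dict = field(default_factory=dict)
    blur_fwhm_mm: float = 2.0
    fov_crop_z: int = 0  # slices blanked to air at each z end; 0 = off
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma_hu < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.streak_count < 0:
            raise ValueError("streak count must be >= 0")
        if self.blur_fwhm_mm < 0:
            raise ValueError("blur FWHM must be >= 0")


def default_degradation_spec(seed: int = 0, **overrides) -> DegradationSpec:
    """Degradation calibrated so organ means drift toward the CBCT column."""
    bias = {
        name: TABLE_CBCT_HU[key][0] - TABLE_CT_HU[key][0]
        for name, key in [
            ("aorta", "aorta"), ("spinal_canal", "spinal_canal"),
            ("heart", "heart"), ("bones", "bones"),
            ("kidney", "kidney"), ("kidney_r", "kidney"),
            ("lungs", "lungs"), ("lungs_r", "lungs"),
            ("liver", "liver"),
        ]
    }
    kw = dict(tissue_bias_hu=bias, seed=seed)
    kw.update(overrides)
    return DegradationSpec(**kw)


def degrade_to_cbct(
    ct: ImageVolume,
    body: StructureMask,
    spec: DegradationSpec,
    structs: StructureSet | None = None,
) -> ImageVolume:
    """Apply cupping, per-tissue bias, blur, streaks and noise inside the body.

    Air outside the body is left untouched.  ``structs`` supplies the organ
    masks referenced by ``spec.tissue_bias_hu``; with no structures only the
    ``"background"`` bias (if any) applies.  Deterministic given ``spec.seed``.
    """
    ct.require_same_grid(body, "ct and body mask")
    rng = np.random.default_rng(spec.seed)
    bodym = body.data
    out = ct.data.astype(float).copy()

    if spec.blur_fwhm_mm > 0:
        sigma_vox = spec.blur_fwhm_mm / 2.3548 / np.asarray(ct.spacing)
        out = ndimage.gaussian_filter(out, sigma=sigma_vox)

    if spec.cupping_hu != 0 and bodym.any():
        depth = ndimage.distance_transform_edt(bodym, sampling=ct.spacing)
        dmax = depth.max()
        if dmax > 0:
            out -= spec.cupping_hu * depth / dmax

    if spec.tissue_bias_hu:
        organ_union = np.zeros(ct.shape, dtype=bool)
        if structs is not None:
            for name, shift in spec.tissue_bias_hu.items():
                if name == "background" or name not in structs:
                    continue
                m = structs[name].data
                out[m] += shift
                organ_union |= m
        bg_shift = spec.tissue_bias_hu.get("background", 0.0)
        if bg_shift:
            out[bodym & ~organ_union] += bg_shift

    if spec.streak_count > 0 and spec.streak_amplitude_hu != 0:
        _, yax, xax = (
            np.arange(n) * s + o
            for n, s, o in zip(ct.shape, ct.spacing, ct.origin)
        )
        yy, xx = np.meshgrid(yax, xax, indexing="ij")
        nz = ct.shape[0]
        for _ in range(spec.streak_count):
            theta = rng.uniform(0, np.pi)
            # line through a random interior point of the body cross-section
            iy, ix = rng.uniform(-0.5, 0.5, 2)
            py, px = iy * (yax[-1] - yax[0]) * 0.6, ix * (xax[-1] - xax[0]) * 0.6
            dist = np.abs(
                -np.sin(theta) * (yy - py) + np.cos(theta) * (xx - px)
            )
            profile = np.exp(-0.5 * (dist / max(spec.streak_width_mm, 1e-6)) ** 2)
            sign = rng.choice([-1.0, 1.0])
            z0 = rng.integers(0, nz)
            z1 = rng.integers(z0 + 1, nz + 1)
            out[z0:z1] += sign * spec.streak_amplitude_hu * profile[None, :, :]

    if spec.noise_sigma_hu > 0:
        out += rng.normal(0.0, spec.noise_sigma_hu, size=ct.shape)

    out = np.where(bodym, out, ct.data)

    if spec.fov_crop_z > 0:
        k = int(spec.fov_crop_z)
        out[:k] = AIR_HU
        if k > 0:
            out[-k:] = AIR_HU

    return ct.with_data(out)


# ---------------------------------------------------------------------------
# Inter-fraction anatomy changes and the deformed-CT surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnatomyPerturbation:
    """Inter-fraction changes: organ shifts, new air pockets, smooth deformation."""

    organ_shifts_mm: dict = field(default_factory=dict)  # name -> (dz, dy, dx)
    air_pockets: tuple = ()  # ((center z,y,x mm), radius mm) pairs
    deform_amplitude_mm: float = 0.0
    deform_correlation_mm: float = 40.0
    max_shift_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name, shift in self.organ_shifts_mm.items():
            if np.linalg.norm(np.asarray(shift, dtype=float)) > self.max_shift_mm + 1e-9:
                raise ValueError(
                    f"shift for {name!r} exceeds the {self.max_shift_mm} mm bound"
                )
        for center, radius in self.air_pockets:
            if radius <= 0:
                raise ValueError("air pocket radius must be > 0")


def _smooth_unit_field(shape, spacing, correlation_mm, rng) -> np.ndarray:
    """Random smooth displacement directions, max magnitude normalized to 1."""
    sigma_vox = np.maximum(np.asarray(correlation_mm, dtype=float) / np.asarray(spacing), 1.0)
    field3 = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox) for _ in range(3)]
    )
    mag = np.sqrt((field3**2).sum(axis=0))
    peak = mag.max()
    if peak <= 0:
        return np.zeros_like(field3)
    return field3 / peak


def _warp(data: np.ndarray, disp_mm: np.ndarray, spacing, is_mask: bool,
          fill: float) -> np.ndarray:
    """Pull-back warp: out(i) = in(i + d(i)/spacing)."""
    idx = np.indices(data.shape, dtype=float)
    coords = idx + disp_mm / np.asarray(spacing)[:, None, None, None]
    if is_mask:
        w = ndimage.map_coordinates(data.astype(float), coords, order=1, mode="constant",
                                    cval=0.0)
        return w > 0.5
    return ndimage.map_coordinates(data.astype(float), coords, order=1, mode="constant",
                                   cval=fill)


def perturb_anatomy(
    spec: PhantomSpec, p: AnatomyPerturbation
) -> tuple[ImageVolume, StructureSet]:
    """Daily anatomy: regenerate with shifted organs, air pockets, deformation.

    The phantom is parametric, so organ motion is simulated exactly by
    shifting the primitive centres and re-painting; air pockets are carved as
    -1000 HU spheres (each must lie inside the body) and returned as masks;
    a smooth random displacement of bounded amplitude is applied last to both
    image and masks.  Deterministic given ``p.seed``.
    """
    new_organs = []
    for organ in spec.organs:
        shift = np.asarray(p.organ_shifts_mm.get(organ.name, (0.0, 0.0, 0.0)), dtype=float)
        new_organs.append(
            dataclasses.replace(organ, center_mm=tuple(np.asarray(organ.center_mm) + shift))
        )
    ptv_shift = np.asarray(p.organ_shifts_mm.get("ptv", p.organ_shifts_mm.get("liver", (0, 0, 0))),
                           dtype=float)
    new_spec = dataclasses.replace(
        spec,
        organs=tuple(new_organs),
        ptv_center_mm=tuple(np.asarray(spec.ptv_center_mm) + ptv_shift),
    )
    vol, structs = make_phantom_ct(new_spec)

    body = structs["body"].data
    for i, (center, radius) in enumerate(p.air_pockets):
        pocket = OrganSpec(f"air_pocket_{i}", "sphere", tuple(center),
                           (float(radius),) * 3, AIR_HU, 0.0)
        m = _primitive_mask(new_spec, pocket)
        if not (m <= body).all() or not m.any():
            raise ValueError(f"air pocket {i} at {center} is not inside the body")
        vol.data[m] = AIR_HU
        structs.add(StructureMask(pocket.name, m, vol.spacing, vol.origin))

    if p.deform_amplitude_mm > 0:
        rng = np.random.default_rng(p.seed)
        disp = p.deform_amplitude_mm * _smooth_unit_field(
            vol.shape, vol.spacing, p.deform_correlation_mm, rng
        )
        warped = _warp(vol.data, disp, vol.spacing, is_mask=False, fill=AIR_HU)
        vol = vol.with_data(warped)
        new_structs = StructureSet()
        for name, m in structs.items():
            new_structs.add(m.with_data(_warp(m.data, disp, vol.spacing, True, 0.0)))
        structs = new_structs

    return vol, structs


def make_ctdef_surrogate(
    daily: ImageVolume,
    structs_daily: StructureSet,
    err_mm: float,
    seed: int = 0,
    correlation_mm: float = 50.0,
) -> tuple[ImageVolume, StructureSet]:
    """Deformed-planning-CT surrogate with controlled residual misalignment.

    Returns the daily phantom warped by a smooth random displacement field
    whose maximum magnitude equals ``err_mm`` — the controlled analogue of a
    deformable registration whose target registration error peaks at
    ``err_mm`` — with the contours carrying the same misalignment.
    """
    if err_mm < 0:
        raise ValueError("err_mm must be >= 0")
    if err_mm == 0:
        return daily.copy(), structs_daily.copy()
    rng = np.random.default_rng(seed)
    disp = err_mm * _smooth_unit_field(daily.shape, daily.spacing, correlation_mm, rng)
    vol = daily.with_data(_warp(daily.data, disp, daily.spacing, False, AIR_HU))
    out = StructureSet()
    for _, m in structs_daily.items():
        out.add(m.with_data(_warp(m.data, disp, daily.spacing, True, 0.0)))
    return vol, out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _subject_seeds(master_seed: int, subject: int) -> dict[str, int]:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(subject),))
    names = ("phantom", "perturb", "degrade", "ctdef")
    state = ss.generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _jitter_spec(template: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Per-subject anatomical variation: jitter organ centres and sizes.

    Sizes scale a few percent and centres shift a few mm; the result is
    clamped so every organ stays inside the grid.
    """
    half = template.half_extent_mm()
    organs = []
    for organ in template.organs:
        dc = rng.uniform(-4.0, 4.0, 3) * np.array([0.5, 1.0, 1.0])
        scale = rng.uniform(0.94, 1.06)
        size = np.minimum(organ.semi_axes * scale, half - 1e-6)
        center = np.clip(np.asarray(organ.center_mm) + dc,
                         -(half - size), half - size)
        organs.append(dataclasses.replace(
            organ,
            center_mm=tuple(center),
            size_mm=tuple(size),
            shape="ellipsoid" if organ.shape == "sphere" else organ.shape,
        ))
    return dataclasses.replace(template, organs=tuple(organs), seed=seed)


def _random_perturbation(template: PhantomSpec, rng: np.random.Generator,
                         seed: int) -> AnatomyPerturbation:
    half = template.half_extent_mm()
    shifts = {}
    for organ in template.organs:
        if organ.name in ("bones", "spinal_canal"):
            continue  # bony anatomy is rigid between fractions
        v = rng.normal(0.0, 2.0, 3)
        if organ.shape == "cylinder":
            v[0] = 0.0  # vessels stay in-plane
        n = np.linalg.norm(v)
        if n > 8.0:
            v *= 8.0 / n
        center = np.asarray(organ.center_mm)
        size = organ.semi_axes
        v = np.clip(v, -(half - size) - center, (half - size) - center)
        shifts[organ.name] = tuple(v)
    pockets = []
    if rng.random() < 0.5:
        pockets.append(((float(rng.uniform(-20, 10)),
                         float(rng.uniform(20, 45)),
                         float(rng.uniform(-40, -10))),
                        float(rng.uniform(6, 10))))
    return AnatomyPerturbation(
        organ_shifts_mm=shifts,
        air_pockets=tuple(pockets),
        deform_amplitude_mm=2.0,
        seed=seed,
    )


def generate_dataset(
    n_subjects: int,
    out_dir,
    template: PhantomSpec | None = None,
    degradation: DegradationSpec | None = None,
    master_seed: int = 0,
    train_fraction: float = 11.0 / 17.0,
    ctdef_err_mm: float = 7.0,
    write_volumes: bool = True,
) -> dict:
    """Generate a paired CT / CBCT / CTdef cohort and write it with a manifest.

    Per-subject seeds derive from ``master_seed`` through a fixed spawn-key
    scheme so each stage is independently reproducible.  The split follows an
    11-train / 6-test ratio; at least one subject lands on each side.
    """
    import json
    from pathlib import Path

    from . import io as sct_io

    if n_subjects < 2:
        raise ValueError("need at least 2 subjects to form a train/test split")
    template = template or default_phantom_spec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_train = int(round(n_subjects * train_fraction))
    n_train = min(max(n_train, 1), n_subjects - 1)

    subjects = []
    for i in range(n_subjects):
        seeds = _subject_seeds(master_seed, i)
        rng = np.random.default_rng(seeds["phantom"])
        spec_i = _jitter_spec(template, rng, seed=seeds["phantom"])
        ct, structs_plan = make_phantom_ct(spec_i)

        prng = np.random.default_rng(seeds["perturb"])
        pert = _random_perturbation(spec_i, prng, seed=seeds["perturb"])
        daily, structs_daily = perturb_anatomy(spec_i, pert)

        deg = degradation or default_degradation_spec()
        deg = dataclasses.replace(deg, seed=seeds["degrade"])
        cbct = degrade_to_cbct(daily, structs_daily["body"], deg, structs_daily)

        ctdef, structs_ctdef = make_ctdef_surrogate(
            daily, structs_daily, ctdef_err_mm, seed=seeds["ctdef"]
        )

        sid = f"sub-{i:02d}"
        entry = {"id": sid, "seeds": seeds,
                 "split": "train" if i < n_train else "test"}
        if write_volumes:
            sdir = out_dir / sid
            sdir.mkdir(exist_ok=True)
            for tag, vol in (("ct", ct), ("daily", daily), ("cbct", cbct), ("ctdef", ctdef)):
                path = sdir / f"{tag}.nii.gz"
                sct_io.write_volume(vol, path, sidecar={"seed": seeds, "stage": tag,
                                                        "master_seed": master_seed})
                entry[tag] = str(path.relative_to(out_dir))
            for tag, ss in (("masks_planning", structs_plan),
                            ("masks_daily", structs_daily),
                            ("masks_ctdef", structs_ctdef)):
                mdir = sdir / tag
                mdir.mkdir(exist_ok=True)
                for name, m in ss.items():
                    sct_io.write_mask(m, mdir / f"{name}.nii.gz")
                entry[tag] = str(mdir.relative_to(out_dir))
        subjects.append(entry)

    manifest = {
        "master_seed": int(master_seed),
        "n_subjects": int(n_subjects),
        "n_train": int(n_train),
        "n_test": int(n_subjects - n_train),
        "ctdef_err_mm": float(ctdef_err_mm),
        "subjects": subjects,
        "root": str(out_dir),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
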