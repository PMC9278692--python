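"""HU -> relative electron density conversion.

Dose algorithms operate on electron density, not on CT numbers, so every
imaging device needs a calibration curve mapping Hounsfield units to
relative electron density (water = 1).  The curve is a piecewise-linear
interpolation between measured knots; two curves ship with the package:

``obi_catphan504``
    Measured on a linac on-board imager with a Catphan 504 insert phantom
    (half-fan bowtie), six material inserts plus a clamped maximum point.
``ct_default``
    A generic CT-simulator style curve for planning-CT images, documented
    as a synthetic stand-in for a site-specific scanner curve.

Outside the knot range the conversion clamps to the end knots.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import ImageVolume

__all__ = [
    "CalibrationCurve",
    "build_curve",
    "hu_to_density",
    "density_map",
    "load_bundled_curve",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordered (HU, relative ED) knots, optionally with mass density."""

    hu: np.ndarray
    relative_ed: np.ndarray
    mass_density: np.ndarray | None = None
    materials: tuple[str, ...] = ()
    label: str = "calibration"

    def __post_init__(self):
        object.__setattr__(self, "hu", np.asarray(self.hu, dtype=float))
        object.__setattr__(self, "relative_ed", np.asarray(self.relative_ed, dtype=float))
        if self.hu.ndim != 1 or self.hu.size < 2:
            raise ValueError("a calibration curve needs at least 2 knots")
        if self.hu.size != self.relative_ed.size:
            raise ValueError("hu and relative_ed must have the same length")
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("knot HU values must be strictly increasing")
        if np.any(self.relative_ed < 0):
            raise ValueError("relative electron density must be >= 0")

    @property
    def n_knots(self) -> int:
        return int(self.hu.size)

    def __call__(self, hu):
        return hu_to_density(self, hu)

    def to_frame(self) -> pd.DataFrame:
        d = {"material": list(self.materials) or [""] * self.n_knots,
             "hu": self.hu, "relative_ed": self.relative_ed}
        if self.mass_density is not None:
            d["mass_density"] = self.mass_density
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_curve(rows: Iterable[Sequence] | pd.DataFrame, label: str = "calibration") -> CalibrationCurve:
    """Build a curve from (material, HU, relative ED[, mass density]) rows.

    Rows are sorted by HU; duplicate HU values are rejected because they
    would make the interpolation ambiguous.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.rename(columns=str.lower)
        mats = df["material"].astype(str).tolist() if "material" in df else [""] * len(df)
        hu = df["hu"].to_numpy(dtype=float)
        ed = df["relative_ed"].to_numpy(dtype=float)
        md = df["mass_density"].to_numpy(dtype=float) if "mass_density" in df else None
    else:
        rows = [tuple(r) for r in rows]
        if not rows:
            raise ValueError("no calibration rows given")
        mats = [str(r[0]) for r in rows]
        hu = np.array([float(r[1]) for r in rows])
        ed = np.array([float(r[2]) for r in rows])
        md = (np.array([float(r[3]) for r in rows])
              if all(len(r) > 3 for r in rows) else None)
    if hu.size < 2:
        raise ValueError("a calibration curve needs at least 2 rows")
    uniq, counts = np.unique(hu, return_counts=True)
    if np.any(counts > 1):
        dupes = uniq[counts > 1]
        raise ValueError(f"duplicate HU knot(s): {dupes.tolist()}")
    order = np.argsort(hu)
    return CalibrationCurve(
        hu=hu[order],
        relative_ed=ed[order],
        mass_density=None if md is None else md[order],
        materials=tuple(mats[i] for i in order),
        label=label,
    )


def load_bundled_curve(name: str = "obi_catphan504") -> CalibrationCurve:
    """Load one of the curves shipped with the package.

    ``obi_catphan504`` carries the on-board-imager Catphan 504 measurement
    table; ``ct_default`` is the generic planning-CT curve.
    """
    res = importlib.resources.files("sctkit").joinpath("data", f"{name}.csv")
    with importlib.resources.as_file(res) as p:
        if not Path(p).exists():
            raise FileNotFoundError(f"no bundled curve named {name!r}")
        return build_curve(pd.read_csv(p), label=name)


def hu_to_density(curve: CalibrationCurve, hu):
    """Piecewise-linear interpolation of relative ED, clamped beyond the knots.

    Exactly reproduces every knot; a scalar input returns a scalar.
    """
    out = np.interp(np.asarray(hu, dtype=float), curve.hu, curve.relative_ed)
    return float(out) if np.isscalar(hu) or np.asarray(hu).ndim == 0 else out


def density_map(vol: ImageVolume, curve: CalibrationCurve) -> ImageVolume:
    """Voxelwise HU -> relative ED conversion; grid metadata preserved."""
    return vol.with_data(np.interp(vol.data.astype(float), curve.hu, curve.relative_ed))
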