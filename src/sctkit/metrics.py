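"""Image-quality and HU-accuracy assessment.

Signal-to-noise ratio, RMSE and MAE compare a test image ``t`` against a
reference image ``r`` (the planning CT):

    SNR  = 10 log10( sum r^2 / sum (r - t)^2 )        [dB]
    RMSE = sqrt( mean (r - t)^2 )                     [HU]
    MAE  = mean |r - t|                               [HU]

By default all three are evaluated inside the body mask when one is given
(air otherwise dominates the sums); pass ``mask=None`` for whole-grid mode.
Anatomical fidelity is inspected with checkerboard composites, and HU
accuracy with whole-volume histograms and organ-wise statistics across
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ImageVolume, StructureMask, StructureSet

__all__ = [
    "snr", "rmse", "mae", "metric_report", "checkerboard",
    "hu_histogram", "organ_hu_stats",
]


def _pair(r: ImageVolume, t: ImageVolume, mask: StructureMask | None):
    r.require_same_grid(t, "reference and test volumes")
    rv, tv = r.data.astype(float), t.data.astype(float)
    if mask is not None:
        r.require_same_grid(mask, "volume and mask")
        sel = mask.data
        return rv[sel], tv[sel]
    return rv.ravel(), tv.ravel()


def snr(r: ImageVolume, t: ImageVolume, mask: StructureMask | None = None) -> float:
    """Signal-to-noise ratio in dB; identical images return ``inf``."""
    rv, tv = _pair(r, t, mask)
    err = float(np.sum((rv - tv) ** 2))
    if err == 0.0:
        return float("inf")
    return 10.0 * np.log10(float(np.sum(rv**2)) / err)


def rmse(r: ImageVolume, t: ImageVolume, mask: StructureMask | None = None) -> float:
    rv, tv = _pair(r, t, mask)
    return float(np.sqrt(np.mean((rv - tv) ** 2)))


def mae(r: ImageVolume, t: ImageVolume, mask: StructureMask | None = None) -> float:
    rv, tv = _pair(r, t, mask)
    return float(np.mean(np.abs(rv - tv)))


def metric_report(
    pairs: dict[str, tuple[ImageVolume, ImageVolume]],
    mask: StructureMask | None = None,
) -> pd.DataFrame:
    """Per-subject SNR/RMSE/MAE table with a mean +/- STD summary row.

    ``pairs`` maps a subject label to (reference, test).
    """
    rows = []
    for label, (r, t) in pairs.items():
        rows.append({"subject": label, "snr_db": snr(r, t, mask),
                     "rmse_hu": rmse(r, t, mask), "mae_hu": mae(r, t, mask)})
    df = pd.DataFrame(rows)
    finite = df.replace([np.inf, -np.inf], np.nan)
    summary = {"subject": "mean"}
    for col in ("snr_db", "rmse_hu", "mae_hu"):
        summary[col] = finite[col].mean()
        summary[col + "_std"] = finite[col].std(ddof=1) if len(df) > 1 else 0.0
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def checkerboard(a: ImageVolume, b: ImageVolume, n: int = 8) -> ImageVolume:
    """Per-slice composite alternating ``n x n`` blocks from ``a`` and ``b``.

    The top-left block comes from ``a``; block width is the integer division
    of the slice dimension by ``n`` with the remainder folded into the last
    block, mirroring the usual fusion display.
    """
    a.require_same_grid(b, "checkerboard inputs")
    if n < 1:
        raise ValueError("n must be >= 1")
    _, ny, nx = a.shape
    if n > min(ny, nx):
        raise ValueError(f"n={n} exceeds the slice dimensions {(ny, nx)}")
    iy = np.minimum(np.arange(ny) // (ny // n), n - 1)
    ix = np.minimum(np.arange(nx) // (nx // n), n - 1)
    from_b = ((iy[:, None] + ix[None, :]) % 2).astype(bool)
    out = np.where(from_b[None, :, :], b.data, a.data)
    return a.with_data(out)


def hu_histogram(
    vol: ImageVolume,
    bins: int = 256,
    range: tuple[float, float] = (-1000.0, 3000.0),
    mask: StructureMask | None = None,
) -> pd.DataFrame:
    """Whole-volume (or masked) HU histogram as (bin_left, bin_right, count).

    Values outside ``range`` are clipped into the end bins so the counts
    always sum to the number of voxels considered.
    """
    lo, hi = range
    if not hi > lo:
        raise ValueError("histogram range must have positive width")
    data = vol.data[mask.data] if mask is not None else vol.data.ravel()
    counts, edges = np.histogram(np.clip(data, lo, hi), bins=bins, range=(lo, hi))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def organ_hu_stats(
    subjects: dict[str, tuple[ImageVolume, StructureSet]],
    organs: list[str] | None = None,
) -> pd.DataFrame:
    """Organ-wise HU statistics across subjects.

    Returns one row per organ with the cross-subject mean of per-subject
    means, the mean of per-subject STDs, and the segment HU variability
    reported as the sum over subjects of the per-subject variances.
    """
    if not subjects:
        raise ValueError("no subjects given")
    first_structs = next(iter(subjects.values()))[1]
    organs = organs or [n for n in first_structs.names() if n not in ("body", "ptv")]

    per_subject: dict[str, list[tuple[float, float]]] = {o: [] for o in organs}
    for label, (vol, structs) in subjects.items():
        for organ in organs:
            if organ not in structs:
                raise KeyError(f"subject {label} has no mask {organ!r}")
            m = structs[organ]
            if m.is_empty():
                raise ValueError(f"mask {organ!r} of subject {label} is empty")
            vol.require_same_grid(m, "volume and organ mask")
            vals = vol.data[m.data]
            per_subject[organ].append((float(vals.mean()), float(vals.std(ddof=0))))

    rows = []
    for organ in organs:
        means = np.array([m for m, _ in per_subject[organ]])
        stds = np.array([s for _, s in per_subject[organ]])
        rows.append({
            "organ": organ,
            "mean_hu": means.mean(),
            "std_hu": stds.mean(),
            "sum_variance": float((stds**2).sum()),
            "n_subjects": len(means),
        })
    return pd.DataFrame(rows)
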