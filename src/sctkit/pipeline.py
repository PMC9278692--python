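"""End-to-end orchestration of the assessment loop on a generated cohort.

Given a dataset manifest and a fitted translation model, the evaluator
reproduces the study sequence for every test subject: synthetic-CT
translation, image-quality metrics (SNR/RMSE/MAE vs the daily ground-truth
anatomy), contour overlap (Dice / mean Hausdorff / delta-V, CBCT anatomy as
reference), organ HU statistics, and stand-in dosimetry (DVH statistics and
gamma analysis of CBCT-, synthetic- and deformed-CT-based plans).

Contours "drawn on" the synthetic image are emulated by a small (default
1 mm) misalignment surrogate — slice-wise translation cannot move anatomy,
so contour differences in practice come from independent contouring
variability; the deformed-CT candidate carries the full registration-error
surrogate already present in the dataset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sct_io
from .calibration import density_map, load_bundled_curve
from .contours import compare_contour_sets
from .dose import arc_beams, compute_dose
from .dvh import (
    GammaParams,
    dose_diff_histogram,
    dvh_stats,
    gamma_histogram,
    gamma_map,
    gamma_plane,
)
from .grid import StructureSet
from .metrics import organ_hu_stats
from .phantom import make_ctdef_surrogate

__all__ = ["load_manifest", "load_subject", "evaluate_cohort", "plan_dose"]


def load_manifest(manifest) -> tuple[dict, Path]:
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            m = json.load(fh)
        return m, Path(manifest).parent
    return manifest, Path(manifest.get("root", "."))


def load_subject(entry: dict, root: Path) -> dict:
    out = {tag: sct_io.read_volume(root / entry[tag])
           for tag in ("ct", "daily", "cbct", "ctdef")}
    for tag in ("masks_planning", "masks_daily", "masks_ctdef"):
        ss = StructureSet()
        for p in sorted((root / entry[tag]).glob("*.nii.gz")):
            ss.add(sct_io.read_mask(p))
        out[tag] = ss
    return out


def plan_dose(image, structs, curve, beams=None, prescription_gy=50.0,
              scale: float | None = None):
    """Stand-in plan: ED conversion + arc dose; returns (DoseGrid, scale).

    With ``scale`` None the plan is normalized so the mean PTV dose equals
    the prescription and the factor is returned; passing a previous factor
    re-uses the same "monitor units" on a different image.
    """
    ed = density_map(image, curve)
    iso = structs["ptv"].centroid_mm()
    if beams is None:
        beams = arc_beams(isocenter_mm=tuple(iso))
    else:
        beams = [b for b in beams]
    dose = compute_dose(ed, beams, prescription_gy=prescription_gy,
                        ptv=None, body=structs["body"])
    if scale is None:
        mean_ptv = dose.data[structs["ptv"].data].mean()
        if mean_ptv <= 0:
            raise ValueError("no dose reaches the PTV")
        scale = prescription_gy / mean_ptv
    return dose.with_data(dose.data * scale), scale


def evaluate_cohort(
    manifest,
    results=None,
    out_dir=None,
    gamma_params: GammaParams = GammaParams(),
    prescription_gy: float = 50.0,
    n_arc_beams: int = 12,
    contouring_err_mm: float = 1.0,
    max_test_subjects: int | None = None,
    sct_shortcut: bool = False,
    with_dose: bool = True,
) -> dict:
    """Run the full assessment on the manifest's test split.

    ``results`` is a fitted :class:`~sctkit.model.CycleGanResults`;
    ``sct_shortcut=True`` instead takes the daily ground truth as the
    synthetic CT (an identity run useful for validating the loop itself).
    Returns a dict of DataFrames; with ``out_dir`` every table is also
    written as CSV.
    """
    if results is None and not sct_shortcut:
        raise ValueError("need fitted results (or sct_shortcut=True)")
    m, root = load_manifest(manifest)
    test = [s for s in m["subjects"] if s["split"] == "test"]
    if max_test_subjects:
        test = test[:max_test_subjects]
    if not test:
        raise ValueError("manifest has no test subjects")

    ct_curve = load_bundled_curve("ct_default")
    obi_curve = load_bundled_curve("obi_catphan504")

    iq_pairs_cbct, iq_pairs_sct = {}, {}
    hu_subjects = {"ct": {}, "cbct": {}, "sct": {}}
    contour_rows, dose_rows, gamma_rows = [], [], []
    hist_bundle = {}

    for entry in test:
        sid = entry["id"]
        sub = load_subject(entry, root)
        daily, cbct, ctdef = sub["daily"], sub["cbct"], sub["ctdef"]
        structs = sub["masks_daily"]
        body = structs["body"]

        if sct_shortcut:
            sct = daily.copy()
        else:
            sct = results.translate_volume(cbct, "cbct2ct")

        # image quality against the daily ground-truth anatomy, body-masked
        iq_pairs_cbct[sid] = (daily, cbct, body)
        iq_pairs_sct[sid] = (daily, sct, body)

        # organ HU statistics
        hu_subjects["ct"][sid] = (daily, structs)
        hu_subjects["cbct"][sid] = (cbct, structs)
        hu_subjects["sct"][sid] = (sct, structs)

        # contour overlap, CBCT anatomy (= daily masks) as the reference
        if sct_shortcut or contouring_err_mm == 0:
            sct_structs = structs
        else:
            _, sct_structs = make_ctdef_surrogate(
                daily, structs, contouring_err_mm,
                seed=entry["seeds"]["ctdef"] + 1)
        ctab = compare_contour_sets(
            structs, {"sct": sct_structs, "ctdef": sub["masks_ctdef"]})
        ctab.insert(0, "subject", sid)
        contour_rows.append(ctab)

        if not with_dose:
            continue

        # stand-in plans: same arc, same monitor units, different images
        iso = structs["ptv"].centroid_mm()
        beams = arc_beams(n_beams=n_arc_beams, isocenter_mm=tuple(iso))
        ref_dose, scale = plan_dose(daily, structs, ct_curve, beams,
                                    prescription_gy)
        plans = {"ct": ref_dose}
        plans["cbct"], _ = plan_dose(cbct, structs, obi_curve, beams,
                                     prescription_gy, scale=scale)
        plans["sct"], _ = plan_dose(sct, structs, ct_curve, beams,
                                    prescription_gy, scale=scale)
        plans["ctdef"], _ = plan_dose(ctdef, structs, ct_curve, beams,
                                      prescription_gy, scale=scale)

        for label, dg in plans.items():
            for sname in ("ptv", "liver"):
                st = dvh_stats(dg, structs[sname], prescription_gy)
                ptv_ref = ref_dose.data[structs[sname].data]
                dev = 100.0 * (dg.data[structs[sname].data] - ptv_ref).mean() \
                    / prescription_gy
                dose_rows.append({"subject": sid, "plan": label,
                                  "structure": sname, **st,
                                  "mean_dev_vs_ct_pct": dev})

        # gamma vs the deformed-CT plan, as in clinical verification
        ref = plans["ctdef"]
        for label in ("cbct", "sct"):
            g3 = gamma_map(ref, plans[label], gamma_params)
            g2 = gamma_plane(ref, plans[label], gamma_params, plane="axial")
            _, mean_dd = dose_diff_histogram(ref, plans[label],
                                             gamma_params.threshold_pct)
            gamma_rows.append({"subject": sid, "plan": label,
                               "pass_rate_3d_pct": g3.pass_rate_pct,
                               "pass_rate_2d_axial_pct": g2.pass_rate_pct,
                               "mean_dose_diff_pct": mean_dd})
            hist_bundle[f"{sid}_{label}_gamma_hist"] = gamma_histogram(g3)

    def _iq_table(pairs):
        from .metrics import mae, rmse, snr

        rows = [{"subject": sid, "snr_db": snr(r, t, bm),
                 "rmse_hu": rmse(r, t, bm), "mae_hu": mae(r, t, bm)}
                for sid, (r, t, bm) in pairs.items()]
        df = pd.DataFrame(rows)
        summary = {"subject": "mean"}
        finite = df.replace([np.inf, -np.inf], np.nan)
        for col in ("snr_db", "rmse_hu", "mae_hu"):
            summary[col] = finite[col].mean()
            summary[col + "_std"] = finite[col].std(ddof=1) if len(df) > 1 else 0.0
        return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)

    report = {
        "image_quality_cbct": _iq_table(iq_pairs_cbct),
        "image_quality_sct": _iq_table(iq_pairs_sct),
        "contours": pd.concat(contour_rows, ignore_index=True),
        "organ_hu_ct": organ_hu_stats(hu_subjects["ct"]),
        "organ_hu_cbct": organ_hu_stats(hu_subjects["cbct"]),
        "organ_hu_sct": organ_hu_stats(hu_subjects["sct"]),
    }
    if with_dose:
        report["dose_stats"] = pd.DataFrame(dose_rows)
        report["gamma"] = pd.DataFrame(gamma_rows)
        report.update(hist_bundle)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, obj in report.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out_dir / f"{name}.csv", index=False)
    return report
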