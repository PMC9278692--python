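# sctkit

Synthetic-CT generation and dosimetric assessment for CBCT-based adaptive
radiotherapy, reproduced end-to-end at digital-phantom scale.

## The problem

Daily cone-beam CT (CBCT) shows where a patient's anatomy actually is at
treatment time, but scatter-induced artifacts (cupping, streaks, noise,
HU drift) make its Hounsfield units unreliable for dose calculation. The
clinical workaround — deforming the planning CT onto the CBCT anatomy
("CTdef") — inherits the planning CT's HU fidelity but carries residual
registration error, especially around air pockets and mobile abdominal
organs. An alternative is to *translate* the CBCT into a synthetic CT (sCT)
with a cycle-consistent generative adversarial network trained on unpaired
CBCT/CT slices, keeping the daily anatomy while restoring CT-quality HU.

`sctkit` implements that whole assessment loop for researchers who want to
study it quantitatively without patient data:

| stage | module |
|---|---|
| paired CT / CBCT / deformed-CT digital phantoms | `sctkit.phantom` |
| cycle-consistent CBCT↔CT translation (five-loss objective) | `sctkit.model` (NumPy autodiff in `sctkit.nn`) |
| SNR / RMSE / MAE, checkerboards, HU histograms, organ statistics | `sctkit.metrics` |
| Hausdorff / Dice / ΔV contour comparison | `sctkit.contours` |
| HU → relative electron density calibration (Catphan-504 table bundled) | `sctkit.calibration` |
| stand-in divergent-beam dose engine | `sctkit.dose` |
| DVH statistics, 2D/3D gamma (3%/2 mm), dose-difference histograms, isodose contours | `sctkit.dvh` |
| orchestration + CLI (`sctkit simulate/train/translate/evaluate/...`) | `sctkit.pipeline`, `sctkit.cli` |

## The model

Two generators G<sub>CBCT→CT</sub>, G<sub>CT→CBCT</sub> and two patch
discriminators D<sub>CT</sub>, D<sub>CBCT</sub> are trained on unpaired
axial patches with the objective

L = λ<sub>cycle</sub>·L<sub>cycle</sub> + λ<sub>adv</sub>·L<sub>adv</sub> +
λ<sub>grad</sub>·L<sub>grad</sub> + λ<sub>idem</sub>·L<sub>idem</sub> +
λ<sub>tv</sub>·L<sub>tv</sub>,  (λ = 10, 1, 1, 1, 1)

with L1 cycle consistency, least-squares adversarial loss, a gradient-
magnitude edge-preservation loss, an idempotency loss (a generator applied
to an image already in its target domain should change nothing) and
anisotropic total variation. Dose accuracy is compared with cumulative
DVHs, dose statistics as percent of prescription, and the gamma index

γ(r<sub>r</sub>) = min<sub>r<sub>e</sub></sub> √( |r<sub>e</sub>−r<sub>r</sub>|²/Δd² + (D<sub>e</sub>(r<sub>e</sub>)−D<sub>r</sub>(r<sub>r</sub>))²/ΔD² ),

at the clinical 3%/2 mm criteria with a 10% low-dose threshold and a cap
at 2.

## Worked example

```python
import sctkit

# a seeded abdominal phantom with known organ HU statistics
spec = sctkit.default_phantom_spec(seed=1)
ct, structs = sctkit.make_phantom_ct(spec)
cbct = sctkit.degrade_to_cbct(ct, structs["body"],
                              sctkit.default_degradation_spec(seed=2), structs)

print(round(ct.data[structs["liver"].data].mean(), 1))   # 54.0  (liver HU)
print(round(cbct.data[structs["heart"].data].mean(), 1)) # 61.6  (drifted heart HU)
print(round(sctkit.mae(ct, cbct, structs["body"]), 1))   # 21.6  (HU error in body)

# HU -> relative electron density on the on-board-imager curve
curve = sctkit.load_bundled_curve("obi_catphan504")
print(sctkit.hu_to_density(curve, 888))                  # 1.868 (Teflon insert)
```

The liver paints at its specified 54 HU mean; the degradation drifts the
heart from 36 toward its measured CBCT value and leaves ≈22 HU mean
absolute error inside the body — the gap the translation model is trained
to close. Training at desk scale and the full table/gamma report are driven
by the CLI:

```bash
sctkit simulate --n-subjects 3 --seed 0 --out cohort/
sctkit train cohort/manifest.json --epochs 30 --checkpoint ckpt.npz
sctkit evaluate cohort/manifest.json --checkpoint ckpt.npz --out report/
```

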