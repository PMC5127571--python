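# wmquant

Multi-parametric quantitative MRI of white-matter microstructure, as a
single verifiable pipeline.

Clinical and research protocols increasingly combine several quantitative
MRI contrasts to characterise white matter whose myelin architecture
differs between regions — e.g. the tightly packed, heavily myelinated,
parallel fibres of the cortico-spinal tract in the posterior limb of the
internal capsule (CST-PLIC) versus crossing-fibre regions in the centrum
semiovale (CST-CS) and frontal white matter.  `wmquant` implements the
model-fitting side of such a protocol, plus a synthetic multi-modal
phantom that makes every estimator testable by parameter recovery:

* **DTI** — log-linear least squares of the tensor model on the low
  (b = 700 s/mm^2) shell: MD, FA, axial (lambda_par) and radial
  (lambda_perp) diffusivities.
* **DKI** — constrained linear least squares of
  ln S = ln S0 − b d(n) + (1/6) b^2 d(n)^2 K_app(n) on both shells, with
  per-direction constraints d(n) >= 0.1 um^2/ms and
  0 <= K_app(n) <= 3/(b_max d(n)); MK, RK, AK.
* **NODDI** — the Watson stick / tortuous zeppelin / ball
  three-compartment model: S/S0 = (1−ISO)[ICVF·A_ic + (1−ICVF)·A_ec]
  + ISO·exp(−b d_iso), with ODI = (2/pi)·arctan(1/kappa) and fixed
  d_par = 1.7, d_iso = 3.0 um^2/ms.
* **Myelin water fraction** — regularized non-negative least squares of a
  32-echo CPMG train against an extended-phase-graph (EPG) basis that
  models stimulated echoes from imperfect refocusing pulses; 32
  log-spaced T2 values, chi^2 regularisation factor 1.01, two-step
  B1-anchored flip-angle handling; MWF = spectral fraction below 30 ms.
* **MTR** — 100·(non-MT − MT)/non-MT, percent.
* **R2\*** — Levenberg–Marquardt fit of the squared mono-exponential
  decay to 8-echo gradient-echo magnitudes.
* **Orientation dependence** — regressions of frequency-shift / R2\* maps
  against sin^2 / sin^4 of the fibre-to-B0 angle.
* **ROI statistics** — per-region mean/SD with hemisphere averaging and
  paired between-region t-tests (uncorrected, descriptive).

See `docs/methods.md` for models, assumptions, numerical choices and
limitations.

## Worked example

Noise-free recovery of the CST-PLIC ground truth from the phantom's
forward signals:

```python
import numpy as np
from wmquant import (REGION_DEFAULTS, default_gradient_table, fit_dti,
                     fit_noddi, fit_mwf_two_step)
from wmquant.phantom import (simulate_tensor_signal, simulate_noddi_signal,
                             simulate_cpmg_decay)

gtab = default_gradient_table()          # b=0 + 30 @ 700 + 64 @ 2000 s/mm^2
plic = REGION_DEFAULTS["cst_plic"]       # normative CST-PLIC ground truth

low = gtab.low_shell()
tensor_fit = fit_dti(simulate_tensor_signal(plic, low), low)
print(f"DTI   axial {tensor_fit.axial:.3f}  radial {tensor_fit.radial:.3f}  "
      f"FA {tensor_fit.fa:.3f}  MD {tensor_fit.md:.3f} um^2/ms")

noddi_fit = fit_noddi(simulate_noddi_signal(plic, gtab), gtab)
print(f"NODDI ICVF {noddi_fit.icvf:.3f}  ODI {noddi_fit.odi:.3f}  "
      f"ISO {noddi_fit.iso_fraction:.3f}")

cs = REGION_DEFAULTS["cst_cs"]
train = simulate_cpmg_decay(cs)          # 32 echoes, TE 10..320 ms
mwf, = fit_mwf_two_step(train[None, :], 10.0 * np.arange(1, 33))
print(f"MWF   {mwf.mwf:.3f}  (anchored flip {mwf.flip_angle:.1f} deg)")
```

Output:

```
DTI   axial 1.611  radial 0.318  FA 0.773  MD 0.749 um^2/ms
NODDI ICVF 0.745  ODI 0.104  ISO 0.106
MWF   0.120  (anchored flip 160.0 deg)
```

The tensor fit returns exactly the generating eigenvalues (axial
1.611, radial 0.318 um^2/ms — hence FA 0.773 and MD 0.749); the NODDI fit
recovers the generating neurite density, dispersion and free-water
fraction; and the EPG-corrected spectrum puts 0.120 of its amplitude
below the 30 ms cutoff for a train generated with a true short-T2
fraction of 0.125 at a 160-degree refocusing flip (the small deficit is
T2-grid discretisation).

The same thing end to end, from the shell:

```bash
wmquant run-all --seed 42 --out out/
# out/region_summary.tsv: per-region means/SDs and paired t-scores
```

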