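# qrelax

Quantitative MR relaxometry toolkit built around a single scientific
question: **does gadolinium contrast administration inflate the variation
of MR-fingerprinting T1 enough to destroy lesion discrimination in the
prostate transition zone?**

The package provides, as reusable library code with a thin CLI:

- **Sequence simulation** — closed-form IR-FSE, SPGR/VFA, multi-echo
  spin-echo and diffusion signal models, plus an extended-phase-graph (EPG)
  simulator of an inversion-prepared FISP fingerprinting train
  (979 excitations, TR 10 ms, TE 2.5 ms, 8π dephasing per TR) and a slow
  isochromat Bloch simulator that serves as its independent oracle.
- **Dictionary matching** — L2-normalised fingerprint dictionaries over a
  (T1, T2) grid; matching maximises |⟨s, atom⟩| and returns T1, T2, proton
  density and a match score, voxelwise over volumes.
- **Conventional fitting** — bounded nonlinear least squares for IR and
  VFA T1 (with magnitude-polarity restoration and the DESPOT1
  linearisation), MSE T2 and ADC.
- **Synthetic data** — a NIST-style calibration phantom and a virtual
  pelvis cohort (14 patients, 10 peripheral-zone + 9 transition-zone
  lesions) whose tissue distributions default to a published 3 T prostate
  cohort summary table, a gadolinium relaxivity model
  `1/T_post = 1/T_pre + r·C` with calibrated per-tissue uptake, and
  acquisition simulation with Rician noise.
- **ROI statistics** — coefficients of variation with the 25% rule,
  Bland–Altman limits of agreement, OLS regression, Shapiro–Wilk-annotated
  t-tests with Holm–Šidák adjustment, and report tables.

Everything runs from synthetic data; no downloads are required. Real
quantitative maps and ROI label maps can optionally be read from NIfTI.

## Worked example

Validate fingerprinting T1 against the inversion-recovery gold standard on
the synthetic calibration phantom, then run the contrast cohort study:

```python
from qrelax.pipeline import RunConfig, run_phantom_study, run_cohort_study

phantom = run_phantom_study(RunConfig(mode="phantom", seed=1, snr=100.0))
print(phantom["regressions"]["MRF_vs_IR_T1"])
# {'slope': 0.9991, 'intercept': -0.278, 'r_squared': 0.99999,
#  'p_value': 6.7e-33, 'n': 14}

cohort = run_cohort_study(RunConfig(mode="cohort", seed=1, snr=50.0))
print(cohort["headline"])
# {'tz_lesion_cv_pre_percent': 13.1,
#  'tz_lesion_cv_post_percent': 48.7,
#  'tz_lesion_cv_inflation_ratio': 3.71,
#  'all_tissues_shortened': True,
#  'p_values': {'PZ_lesion_vs_normal_pre': 3.0e-05,
#               'PZ_lesion_vs_normal_post': 6.5e-05,
#               'TZ_lesion_vs_normal_pre': 0.0097,
#               'TZ_lesion_vs_normal_post': 0.54, ...}}
```

Reading the numbers: on the phantom, fingerprinting T1 tracks the IR gold
standard essentially perfectly (slope ≈ 1, R² > 0.999). In the virtual
cohort, every tissue's T1 shortens after contrast; the coefficient of
variation of transition-zone lesion T1 inflates ≈ 3.7-fold (13% → 49%),
and while lesions are clearly separable from normal tissue before contrast
in both zones (paired p < 0.05), the transition-zone contrast is lost
afterwards (p ≈ 0.5) — the motivating argument for mapping T1 *before*
contrast injection.

The same studies run from the shell:

```bash
qrelax protocols list
qrelax protocols show mrf_default
qrelax phantom run --seed 1 --snr 100 --out out/phantom
qrelax cohort run --seed 1 --snr 50 --out out/cohort
qrelax cohort table-replay
qrelax mrf build-dict --grid default --out dict.npz
qrelax mrf match --dict dict.npz --in series.nii.gz --out-prefix maps_
qrelax fit vfa --in vfa_stack.nii.gz --protocol invivo_vfa --out t1.nii.gz
```

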