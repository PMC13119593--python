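# liversep

Noninvasive staging of liver fibrosis from multi-echo gradient-echo
(mGRE) MRI via magnetic-susceptibility source separation.

Fibrosis deposits collagen, which is *diamagnetic*; disease also often
deposits iron, which is *paramagnetic*. Conventional quantitative
susceptibility mapping (QSM) measures only their sum χ, and the
effective relaxation rate R2\* mixes both with everything else — neither
is specific to fibrosis. `liversep` implements the source-separation
approach for ex vivo liver specimens: per voxel,

```
χ  =  χ⁺ + χ⁻                (χ⁺ ≥ 0 iron,  χ⁻ ≤ 0 collagen)
R2* ≈  r · (χ⁺ + |χ⁻|)
```

where the dephasing constant r (Hz/ppm) couples both source magnitudes
to R2\*. Because r is tissue-specific, it is *learned* against
histological fibrosis stage: the specimen-mean |χ⁻| obtained by the
closed-form split of (R2\*, χ) at candidate r is scored by the joint
logistic log-loss of the F0–1 vs F2–3, F2–3 vs F4 and F0–1 vs F4 stage
models, minimized by exhaustive search over r ∈ [50, 300] Hz/ppm under
leave-one-out cross-validation. The resulting |χ⁻| map (computed by a
regularized joint inversion of the R2\* and dipole-field data) is the
fibrosis biomarker, evaluated with Mann–Whitney U, ROC/AUC with Youden
cutoffs, and Spearman correlation against stage.

The package contains the full chain — ARLO R2\* relaxometry, IDEAL
water–fat–field estimation, dipole forward physics, PDF background-field
removal, morphology-regularized dipole inversion with water-balloon
referencing, rapid and regularized source separation, decay-constant
learning, and the staging statistics — plus a digital liver-specimen
phantom that generates every test input, so the whole pipeline is
validated without any data download. See `docs/methods.md` for models,
parameter choices and limitations.

## Worked example

Simulate a 20-specimen cohort, learn the dephasing constant, and compare
the learned-r biomarker against the brain-literature default 262 Hz/ppm:

```python
import numpy as np
from liversep import CohortSpec, loocv_r, make_metric_cohort
from liversep.decay import DEFAULT_R_BRAIN
from liversep.separation import split_feature
from liversep.stats import roc_analysis, spearman_rho

cohort = make_metric_cohort(CohortSpec(seed=0))      # 20 samples, stages 0-4
res = loocv_r(cohort)
print(f"learned r: {res.summary['mean']:.1f} +- {res.summary['sd']:.1f} Hz/ppm"
      f"  (min {res.summary['min']:.0f}, max {res.summary['max']:.0f})")

stages = cohort.table["fibrosis_stage"].to_numpy()
advanced = np.isin(stages, (3, 4)).astype(int)        # F3-4 vs F0-2 split
f_opt = res.applied_feature.to_numpy()
f_def = np.array([split_feature(*cohort.voxels[s], np.array([DEFAULT_R_BRAIN]))[0]
                  for s in cohort.table["sample_id"]])
print(f"AUC |chi-| (learned r): {roc_analysis(f_opt, advanced).auc:.2f}")
print(f"AUC |chi-| (default 262): {roc_analysis(f_def, advanced).auc:.2f}")
print(f"Spearman rho vs stage:  {spearman_rho(f_opt, stages):.2f}")
```

Output:

```
learned r: 142.4 +- 8.1 Hz/ppm  (min 108, max 148)
AUC |chi-| (learned r): 0.88
AUC |chi-| (default 262): 0.68
Spearman rho vs stage:  0.69
```

The learned constant is tight across leave-one-out folds; the biomarker
computed with it separates advanced fibrosis (F3–4) from F0–2 better
than the same biomarker at the default constant, which subtracts part of
the stage-correlated iron signal — the motivation for tissue-specific
calibration.

The end-to-end pipeline (echo simulation → fitting → QSM → separation →
learning → statistics) runs from the shell:

```
liversep run-all --config cfg.yaml --out results/
```

writing NIfTI maps per sample, `metrics.csv`, and a staging report
(`report.csv`) with AUC, p, cutoff, sensitivity and specificity for all
seven metrics (|χ⁻| and χ⁺ at learned and default r, R2\*, χ, PDFF).

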