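# lesionfd

Lesion-aware white-matter fiber-density analysis for treated glioma cohorts.

After resection, radiotherapy and chemotherapy, glioma patients carry several
kinds of structural brain lesions — resection cavities, contrast-enhancing
(T1CE) recurrent tumor, regions of pathologically increased amino-acid
(FET-PET) uptake, and T2/FLAIR hyperintensities from edema or
radiation-induced gliosis. `lesionfd` quantifies how much white-matter fiber
architecture each lesion type destroys and what that loss costs the patient
functionally. It is written for neuroimaging analysts who already have
fiber-density (track-density) maps and lesion masks in a shared template
space, and for methodologists who want a fully simulated cohort with
recoverable ground truth.

## The quantities it computes

All images live on one voxel grid. For a patient's fiber-density map
FD<sub>pat</sub>, a lesion segment S, and a reference map
FD<sub>ref</sub> (the voxelwise mean FD of propensity-matched healthy
controls):

* **relative fiber density** — mean<sub>S</sub>(FD<sub>pat</sub>) /
  mean<sub>S</sub>(FD<sub>ref</sub>), the fraction of healthy fiber density
  surviving inside the lesion;
* **total fiber loss** — (1 − relative FD) × volume(S) in mm³, an absolute
  amount of lost fiber; absent lesion types contribute 0;
* **TBR models** — inside the FET lesion (TBR > 1.6), uptake is divided
  into bins (1.6–2.6, 2.6–3.6, 3.6–4.6, > 4.6]; relative FD is regressed on
  mean bin TBR by pooled OLS and by a linear mixed model with a per-patient
  random intercept (maximum likelihood). Bins under 0.25 mL are excluded,
  as are patients whose reference region is inhomogeneous (spatial SD ≥
  mean) or whose segment FD exceeds the reference;
* **edema vs. gliosis** — a T2/FLAIR lesion is *edema* when both the T1CE
  and FET lesions exceed 10 mL, *gliosis* when both are under 0.1 mL and
  more than 6 months have passed since radiotherapy;
* **ECOG models** — performance status dichotomized as 0 (normal) vs ≥ 1
  (impaired), modeled by univariate and multivariate logistic regression on
  the per-type total fiber loss, with clinical covariates as confounders;
* plus the nonparametric battery: Mann-Whitney U (patient vs reference FD),
  one-sample Wilcoxon signed-rank (relative FD vs 100%), Kruskal-Wallis
  with pairwise post-hoc tests across lesion types.

Because clinical imaging of this kind is not publicly distributable, the
package ships a first-class synthetic-cohort generator
(`lesionfd.synthetic`): smooth tract-like control fields (sums of oriented
Gaussian ridges), patient maps with lesion-type-specific multiplicative
suppression, TBR maps with a linear TBR→FD law, and ECOG outcomes drawn
from a logistic model on total fiber loss — every downstream estimate has a
known truth.

## Worked example

```python
from lesionfd import RunConfig, run_pipeline

res = run_pipeline(RunConfig().with_seed(1), out_dir="out")
print(res.lesion_summary[["lesion_type", "relative_fd_mean_pct", "p_relative"]])
```

With the default generator truth (suppression ratios 0.15 / 0.45 / 0.50 /
0.55 for cavity / T1CE / FET / FLAIR, 30 patients, 30 matched controls,
multiplicative noise SD 0.1) this prints:

```
lesion_type  n_subjects  volume_mean_mL  fd_healthy_mean  fd_patient_mean  relative_fd_mean_pct  p_relative
     cavity          30           1.158          146.117           21.916                14.999         0.0
         ce          30           1.038          113.345           50.948                44.952         0.0
        fet          30           1.086           73.246           36.671                50.066         0.0
      flair          30           1.198          208.279          114.558                55.000         0.0
```

i.e. the cohort-mean relative fiber density per lesion type recovers the
generating suppression ratio to a fraction of a percentage point, and the
Wilcoxon test against 100% of reference rejects decisively (p ≈ 2e-9,
printed as 0.0 at three decimals). The `out/` directory holds every stage's
table: manifest, matched pairs, segment statistics, TBR bins and fits,
fiber loss, lesion summaries, ECOG models and a plain-text run report.

The same analyses are available from the shell:

```bash
lesionfd run --seed 1 --out out/           # full pipeline
lesionfd simulate --seed 1 --out sim/      # cohort NIfTIs + manifest + truth
lesionfd tdi --tractogram t.tck --grid-like ref.nii.gz --out fd.nii.gz
lesionfd reference --manifest sim/manifest.csv --images sim/images --out ref.nii.gz
lesionfd report --run-dir out/
```

`examples/` contains one short narrative script per capability (simulation,
track-density mapping, matching, lesion metrics, TBR models, fiber
loss/ECOG, full pipeline).

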