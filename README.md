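# ctradiomics

Quantitative CT phenotype analysis for tumor prognosis studies.

Radiomics asks whether high-throughput quantitative descriptors of a
tumor's appearance on CT — texture, shape, intensity statistics — carry
predictive information about histology and stage, and prognostic
information about overall survival. This package implements that analysis
end to end for 3D CT volumes with aligned tumor masks:

1. **Segmentation** — seeded region growing under multi-scale smoothness
   constraints, evaluated by the Dice coefficient
   `DC = 2|A∩B| / (|A|+|B|)`.
2. **Derived images** — one-level 2D wavelet sub-bands (LL/LH/HL/HH) and a
   complex Gabor filter bank (magnitude "MTR" and phase "PTR" maps).
3. **Feature extraction** — gray-level co-occurrence features
   (correlation, contrast, variance, energy, entropy of `p(i,j)` at offset
   `(d_row, d_col)`), run-length emphases (SRE, LRE, LRLGE, LRHGE, run
   energy along 0°/45°/90°), first-order histogram statistics, and 3D
   shape descriptors (sphericity `π^{1/3}(6V)^{2/3}/A`, compactness
   `V/(√π A^{3/2})`) — 409 named features in the default catalog.
4. **Feature ranking** — each feature scored by the held-out accuracy of a
   single-feature linear SVM under stratified 5-fold cross-validation,
   plus top-k ROC/AUC stability curves.
5. **Survival analysis** — per-cohort [0, 1] normalization, median
   dichotomization into low/high status, univariate and adjusted Cox
   proportional-hazards models `h(t|x) = h₀(t)·exp(βx)` (Efron ties, Wald
   CIs), Kaplan-Meier curves, the Harrington–Fleming G-rho weighted
   log-rank test (ρ = 1), ICC(2,1) agreement and Kruskal-Wallis tests.

Real cohorts cannot ship with the code, so the package includes a
first-class **synthetic cohort generator**: ellipsoidal tumor phantoms
whose intratumoral texture heterogeneity is a tunable Gaussian random
field, class labels coupled to the texture parameter, and survival times
drawn under a proportional-hazards model with a chosen log-hazard ratio
and independent censoring. Every pipeline stage is validated by recovering
this planted structure; see `docs/methods.md` for the models and
conventions.

## Worked example

Simulate a 150-patient cohort in which smooth-texture tumors (class B)
carry a true hazard ratio of 2, extract a reduced feature catalog, rank
features by class-predictive ability, and test the best co-occurrence
correlation signature for prognostic value:

```python
import numpy as np
import ctradiomics as cr
from ctradiomics.texture import ExtractionConfig, extract_all

design = cr.CohortDesign(
    n_patients=150, seed=1, image_shape=(40, 40, 40),
    tumor_radius_range=(7.0, 11.0),
    texture_corr_length_by_class={"A": 1.0, "B": 3.0},
    class_probs={"A": 0.5, "B": 0.5},
    beta_feature=np.log(2.0), baseline_hazard=0.05, censor_rate=0.2,
)
patients, clinical = cr.generate_cohort(design)

cfg = ExtractionConfig(n_levels=16, glcm_offsets=((1, 1), (2, 2)),
                       rl_directions=(1, 3), include_gabor=False)
table = cr.FeatureTable.from_rows(
    {p.id: extract_all(p.volume, p.mask, cfg) for p in patients}
)
print(f"extracted {len(table.names)} features for {len(table.ids)} patients")

ranking = cr.rank_features(table, clinical["label"], cv_seed=0)
for r in ranking[:3]:
    print(f"rank {r.rank}: {r.name:30s} CV accuracy {r.score:.3f}")

signature = next(r.name for r in ranking if "CO_correlation" in r.name)
report = cr.signature_report(table.data, clinical, [signature])
uni = report["signatures"][signature]["univariate"]
print(f"{signature}: HR {uni['hr']:.2f} "
      f"(95% CI {uni['ci_low']:.2f}-{uni['ci_high']:.2f}), p = {uni['p']:.4f}")
print(f"G-rho log-rank p = {report['signatures'][signature]['grho_logrank']['p']:.4f}")
```

Output:

```
extracted 134 features for 150 patients
rank 1: hist_variance_HL               CV accuracy 0.993
rank 2: hist_variance_LH               CV accuracy 0.987
rank 3: CO_correlation_d1_a1_LL        CV accuracy 0.973
CO_correlation_d1_a1_LL: HR 2.10 (95% CI 1.43-3.07), p = 0.0001
G-rho log-rank p = 0.0002
```

Texture features separate the two classes almost perfectly (wavelet-band
variance and co-occurrence correlation top the ranking), and the
dichotomized co-occurrence correlation signature recovers the planted
hazard ratio of 2 with a strongly significant Cox and weighted log-rank
test — the planted prognostic structure survives the whole pipeline.

## Command line

The same pipeline is available as subcommands:

```bash
ctradiomics simulate --n 40 --seed 0 --out cohort/
ctradiomics segment  --volume v.nii.gz --seed 20,20,20 --params p.json --out mask.nii.gz
ctradiomics extract  --cohort cohort/ --config features.json --out features.csv
ctradiomics rank     --features features.csv --clinical cohort/clinical.csv \
                     --label label --out ranking.csv --curve curve.csv
ctradiomics survive  --features features.csv --clinical cohort/clinical.csv \
                     --signatures CO_correlation_d1_a1_LL --out report.json
ctradiomics report   --ranking ranking.csv --survival report.json --out summary.json
```

Volumes are read and written as NIfTI or NRRD (DICOM series read is
supported); feature and clinical tables are CSV; configs and reports are
JSON. Readers refuse geometry mismatches rather than resampling.

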