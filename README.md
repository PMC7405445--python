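# robustrad

Radiomic feature robustness screening and overall-survival (OS) class
benchmarking for multi-sequence brain MRI, aimed at glioblastoma (GBM)
studies where a model trained on one centre's homogeneous data must survive
transfer to heterogeneous multi-centre data.

Radiomic models for GBM survival routinely report near-perfect
cross-validated performance on single-centre cohorts and then collapse on
external data. `robustrad` implements the full pipeline needed to study and
mitigate this failure mode:

1. **Phantoms** — a synthetic cohort generator (nested-ellipsoid tumours with
   enhancement / necrosis / non-enhancement / edema compartments in a
   two-tissue brain, four MRI sequences, centre-specific acquisition
   profiles, and OS linked to tumour geometry and enhancement through a
   log-linear model), so every downstream stage is testable without any
   patient data.
2. **Regions** — the eight single and combined tumour labels
   (cet, net, nec, ed, wt, core, net_ncr, net_ed) plus Dice and normalized
   centroid-offset utilities.
3. **Features** — a handcrafted bank of 120 features per (sequence, region):
   shape (26), first-order (19), GLCM (24), GLRLM (16), GLSZM (16),
   NGTDM (5), GLDM (14); plus 7 enhancement-geometry features, 8 centroid
   features, patient age, and a pluggable 8192-unit deep-feature extractor
   (seeded random-weight stand-in, off by default).
4. **Perturbations** — six seeded families simulating multi-centre
   variability: additive Gaussian noise (calibrated against white-matter
   SNR), gray-level binning (30–130 bins), elastic label deformation
   calibrated to a target inter-rater Dice, isotropic voxel-size change
   (1–1.5 mm), axial slice-spacing change (1–4 mm for T2/FLAIR, 1–1.5 mm for
   T1/T1c), and random k-space subsampling (80–100 % of frequency bins).
5. **Robustness** — per feature and perturbation family, the two-way
   random-effects absolute-agreement single-rater intraclass correlation

   `ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`

   with its F-based 95 % confidence interval. A feature is *robust* when the
   CI lower bound is ≥ 0.85 in every family (binning is reported but exempt).
   A filter cascade then removes zero-MAD features, features non-zero in at
   most one case, and features with a direction-folded concordance index
   ≤ 0.55.
6. **Selection & benchmarking** — 13 feature selectors (ReliefF, Fisher
   score, Gini, χ², t-score, and the greedy mutual-information family MIM /
   MIFS / MRMR / JMI / CIFE / CMIM / ICAP / DISR) crossed with 12 classifier
   families (156 combinations) at the OS boundaries 304.2 / 365 / 425.8 /
   540 days, under stratified 10-fold cross-validation with imputation,
   standardization and selection fitted strictly inside the training folds.
7. **Transfer** — the best combination per boundary is refitted on the full
   training cohort and applied once to a second cohort; the per-metric
   decrease (`drop = single-centre CV mean − multi-centre value`) is reported
   with and without a *sequence prior* (T1c + FLAIR features only) and a
   *hand-picked prior* (intensity-free families: shape, enhancement
   geometry, centroids, plus age).

## Worked example

```python
import numpy as np
from robustrad.phantom import (PhantomParams, SurvivalModel, generate_cohort,
                               single_center_profile, multi_center_profile)
from robustrad.features import ExtractionConfig, extract_feature_table
from robustrad.bench import (OSBoundary, PriorSpec, Combo, binarize_os,
                             transfer_evaluate)
from robustrad.select import SelectorSpec

params = PhantomParams(grid_shape=(48, 48, 48))
surv = SurvivalModel(volume_coeff=-0.25, noise_sd=0.2)
train, clin_tr = generate_cohort(30, params, single_center_profile(), surv, seed=5)
test, clin_te = generate_cohort(30, params, multi_center_profile(), surv, seed=6)

cfg = ExtractionConfig(sequences=("T1c", "FLAIR"), regions=("cet", "wt", "core"))
tab_tr = extract_feature_table(train, cfg)   # 30 cases x 658 features
tab_te = extract_feature_table(test, cfg)

boundary = OSBoundary(float(np.median(clin_tr["os_days"])))
combo = Combo(SelectorSpec("MRMR", k=8), "random_forest")
full = transfer_evaluate(tab_tr, clin_tr["os_days"], tab_te, clin_te["os_days"],
                         combo, boundary, seed=0)
ids = PriorSpec("handpicked").apply(tab_tr.feature_ids)
hand = transfer_evaluate(tab_tr.subset(ids), clin_tr["os_days"],
                         tab_te.subset(ids), clin_te["os_days"],
                         combo, boundary, seed=0)
print(f"all features : single {full.single.auc:.2f}  multi {full.multi.auc:.2f}  "
      f"drop {full.drop['auc']:+.3f}")
print(f"hand-picked  : single {hand.single.auc:.2f}  multi {hand.multi.auc:.2f}  "
      f"drop {hand.drop['auc']:+.3f}")
```

Output from this exact script:

```
all features : single 0.85  multi 0.74  drop +0.113
hand-picked  : single 0.75  multi 0.90  drop -0.154
```

Training on the single-centre cohort with all 658 features gives a mean CV
AUC of 0.85 that loses 0.11 on the shifted-centre cohort, while the
intensity-free hand-picked set starts lower in-centre (0.75) but *gains*
AUC in transfer — the robustness-versus-performance trade-off the pipeline
is built to quantify.

The same experiment runs end to end from the shell:

```bash
robustrad phantom --n 10 --profile single --seed 0 --out cohort/
robustrad extract --cohort cohort/ --out features.csv
robustrad pipeline --seed 0 --out run/        # all stages, resumable
robustrad report --artifacts run/
```

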