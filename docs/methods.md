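# Methods

This note documents the models, conventions and numerical choices behind
`robustrad`, in the order the pipeline runs them.

## Synthetic cohorts (phantom)

The generator produces, per case, four co-registered sequences (T1, T1c,
T2, FLAIR) on a common isotropic grid, a four-compartment tumour label map,
a white-matter mask and clinical covariates. It is *not* an anatomical
simulator: its purpose is to give every downstream stage inputs with the
right statistical structure — nested tumour compartments, sequence-dependent
contrast, centre-dependent acquisition quality, and survival times carrying
a recoverable geometric signal.

**Geometry.** The brain is an ellipsoid filling 90 % of the grid extent,
with an inner ellipsoidal white-matter core occupying `wm_fraction` (default
0.55) of the brain volume. The tumour is four nested ellipsoids
(necrosis ⊂ enhancement ⊂ core ⊂ core+edema) with a per-case global size
factor `exp(N(0, size_sigma))` (default σ = 0.18), per-axis jitter (±8 %),
a uniform random 3-D rotation, and a jittered centre. Nesting is validated
at construction; a grid too small for the nominal tumour raises a sizing
error, and the stochastic size factor is clamped so a drawn tumour always
fits inside the brain.

**Intensities.** Each voxel gets its tissue's mean intensity (a per-sequence
contrast table mimicking the qualitative ordering of real sequences: edema
and necrosis bright on T2/FLAIR, the enhancing rim bright on T1c), plus a
smooth additive bias field (Gaussian-filtered white noise, correlation
length 12 mm, sd 2 intensity units) and per-sequence Gaussian noise. Two
per-case factors model biology and hardware:

- an *enhancement factor* `exp(N(0, enh_sigma))` (default σ = 0.35) scaling
  the contrast-enhancing tissue mean on T1c — strong enhancement is a known
  adverse prognostic marker in GBM, and this is the phantom's
  intensity-borne survival signal;
- a *scanner gain* `intensity_scale · exp(N(0, scale_jitter))` — MRI
  intensities are not quantitative, so absolute gray values are only
  comparable within a homogeneous acquisition. The single-centre profile
  uses `scale_jitter = 0.02`; the multi-centre profile (many scanners)
  uses 0.25.

**Centre profiles.** `single`: 1 mm axial spacing for all sequences, noise
sd 3, gain 1.0. `multi`: 1.5 mm (T1/T1c) and 3 mm (T2/FLAIR) axial spacing
simulated as a boxcar slice profile, noise sd 6, mean gain 1.15. These are
the two study conditions of every transfer experiment; they were chosen to
mirror thin-slice homogeneous research acquisitions versus routine clinical
multi-centre data.

**Survival.** `log OS = baseline + volume_coeff·V + rim_coeff·r +
enh_coeff·E + N(0, noise_sd)`, with V the core volume (mL), r the
equivalent-sphere enhancing-rim width (mm) and E the white-matter-relative
T1c enhancement (gain-invariant, so the *information* survives centre shift
even when raw intensities do not). `enh_coeff` defaults to 0, reducing to a
purely geometric model. The default baselines and noise are set so the
single-centre marginal has mean OS near 22.8 months and the multi-centre
marginal near 14.8 months, reproducing the cohort-shift asymmetry such
studies report (ages are drawn from N(62.75, 9.96²) truncated to [18, 95]).
The cohort tumour-size distribution is a stated configuration default, not
a fitted quantity.

**What passing phantom tests does not show.** No skull/CSF, no Rician
noise, no motion or registration error, ellipsoidal (not infiltrative)
margins, and noise-independent segmentations. Results on phantoms bound the
pipeline's correctness, not clinical performance.

## Regions and centroids

The eight analysis labels are derived set-theoretically from the four base
compartments; identities (`wt = cet∪net∪nec∪ed`, `core = wt\ed`,
`net_ncr = net∪nec`, `net_ed = net∪ed`) are enforced by construction and
property-tested. Dice of two empty masks is defined as 1.0 (with a warning):
perturbing an absent label is not disagreement. Tumour location is
scalarized to one value per region — the distance of the region centroid
from the brain bounding-box centre, normalized by the box half-diagonal —
a deterministic "normalized brain frame" standing in for atlas
registration, giving exactly 8 location features per case.

## Feature bank

Definitions follow the standard (IBSI-aligned) radiomics reference set;
every formula is in the code next to its name. Conventions worth stating:

- **Discretization**: fixed bin count (default 80, admissible 30–130) over
  the masked intensity range, or fixed bin width anchored at zero.
- **Shape (26)**: 16 3-D descriptors (mesh volume by divergence theorem and
  surface area from a marching-cubes mesh, surface/volume ratio,
  sphericity, compactness 1/2, maximum 3-D and per-plane 2-D diameters,
  PCA axis lengths, elongation, flatness) plus the 10 standard 2-D
  descriptors computed on the largest-area axial slice (marching-squares
  perimeter, polygon area, circularity, 2-D diameters and axes). The mesh
  chamfers voxel edges, so e.g. a 10³-voxel cube reports a surface slightly
  below the 600 mm² voxel-face count.
- **First order (19)**: population moments (Pearson kurtosis, 3 for a
  normal); entropy/uniformity on the discretized histogram; energy on raw
  intensities.
- **Texture**: matrices built in 3-D; GLCM and GLRLM average the 13
  per-direction (distance-1) matrices — each GLCM symmetrized and
  normalized before averaging — while GLSZM/NGTDM/GLDM use the
  26-connected neighbourhood. Degenerate cases are defined, not errors:
  single-level regions give zero contrast and an undefined (NaN, flagged)
  correlation, NGTDM coarseness caps at 10⁶, single-voxel masks warn and
  return NaN for pairwise families.
- **Enhancement geometry (7)**: CE, inner (necrotic) and total volumes, the
  equivalent-sphere rim width (difference of equivalent radii of total and
  inner volumes), maximum 3-D diameter, mesh surface area, and surface
  regularity (equal-volume-sphere area / actual area).
- **Deep stand-in (8192)**: a seeded random-weight conv + two-FC network on
  the mask bounding box resized to 12³. It is deliberately untrained; it
  exists so the sparse high-dimensional plumbing (robustness screening,
  sparsity filter) is exercised without pretrained weights, and it is off
  by default. ReLU activations make roughly half the outputs exactly zero,
  which is what the sparsity filter is designed to catch.

Family cardinalities (26/19/24/16/16/5/14 = 120 per sequence–region, plus
7 geometry, 8 centroid, 1 age) are asserted against the registry in tests.

## Perturbations and calibration

All perturbations are one-factor-at-a-time and deterministic given their
spec (family, value, seed). Image-level perturbations re-extract only the
affected sequence's intensity features and splice them into the original
table, which both saves work and guarantees label-only features are
bit-identical across image perturbations. Resampling perturbations simulate
the coarse acquisition and return to the analysis grid, so extraction
geometry never changes.

- **Noise**: σ levels are calibrated per sequence by bisection so the
  cohort-mean post-noise white-matter SNR stays at or above
  (mean SNR − 1 SD) of the unperturbed cohort; levels are then evenly
  spaced up to that σ_max.
- **Inter-rater**: one smooth random displacement field (white noise,
  6 mm Gaussian scale) warps all labels; its amplitude is bisected until
  the target region's Dice against the original lands within ±0.02 of the
  target. Default targets span 0.85–0.94, the range reported for
  whole-tumour inter-rater agreement in public GBM segmentation data.
- **k-space**: Bernoulli mask over all frequency bins with DC always kept,
  no Hermitian symmetrization, magnitude afterwards (phase is treated as
  already lost). Fraction 1.0 reproduces the input to ~1e−7.
- **Binning** is bookkept like the others but exempt from robustness
  exclusion, since consistent binning is controllable in practice.
- Default level counts per sequence (or per region for inter-rater):
  noise 10, binning 54, inter-rater 10, voxel size 10, slice spacing 10,
  k-space 21 (fractions 0.80…1.00 in steps of 0.01). Level values are
  evenly spaced across each family's admissible range; the spacing of the
  noise and binning levels is a documented default, not a measured one.

## Robustness decision and filter cascade

For each feature and family, the ratings matrix is cases × (original +
that family's pooled variants); pooling all of a family's parameter levels
into one rater set is the default reading of "agreement across
perturbations". ICC(2,1) uses absolute agreement because a perturbation
that shifts a feature systematically must count against it — a model
transferred to another centre sees the shifted value, not a re-centred one.
A degenerate variance decomposition (feature constant everywhere) is
undefined and treated as non-robust: a constant feature carries no
information. The F-based CI matches `pingouin.intraclass_corr` to machine
precision (cross-checked in the tests; the implementation is independent).

The cascade then applies, in order: restriction to the robust set, zero-MAD
removal, removal of features non-zero in ≤ 1 case, and retention of
features with direction-folded C-index > 0.55 (an anti-concordant feature
is still predictive, hence the fold `max(c, 1−c)`). The cascade is
idempotent and its stage counts are non-increasing by construction.

## Selection and benchmarking

Mutual information is the plug-in estimate on equal-frequency discretized
features (default 5 bins) in bits; all eight greedy criteria keep running
accumulators so each step costs one pairwise-MI scan against the newly
selected feature, and each is verified against an exhaustive per-step
re-scoring oracle. MIFS uses β = 1 by default. ReliefF uses 10 neighbours,
all instances, prior-weighted misses, features scaled to [0, 1]. The number
of features kept per fold (k, default 10) is a configuration knob — the
benchmark contract does not fix it.

The CV harness fits imputation (training medians), standardization and
selection inside each of 10 stratified folds (folds reduce with a warning
when the minority class is smaller). Models come from scikit-learn with
library defaults and fixed seeds; "gradient-boosted trees" is
`GradientBoostingClassifier`. AUC uses the rank (Mann–Whitney) formulation
with tie correction; confusion-table metrics threshold the predicted
probability at 0.5 (an undocumented operating point in the benchmark
contract — 0.5 is the standard choice). A case exactly at an OS boundary is
a long survivor. Ties in the best-combo pick break by balanced accuracy,
then lexicographic (selector, model) order, so the grid is deterministic
given its seed.

Transfer refits the whole pipeline on the full training cohort and
evaluates once on the second cohort; the drop is the training-CV mean minus
the transfer value, per metric. Training features missing from the test
table are imputed with training medians (logged).

## Problem sizes used in tests and the acceptance script

Phantom-based checks run on 36³ grids with proportionally small tumours;
the two-centre experiment uses 30 cases per centre with two sequences and
three regions (658 features), a robustness screen on 8 cases with 1–2
levels per family, a 2-selector × 2-model grid at the 425.8-day boundary,
and a survival model with strong geometry and enhancement coefficients
(volume −0.8/mL, enhancement −0.6/unit, noise 0.2 log-days) so the planted
signal dominates sampling noise at that cohort size. The null-band check
uses 60 cases × 500 pure-noise features with all 13 selectors over a
logistic model; the test suite averages three repeated CVs per selector
because a single 10-fold AUC at n = 60 has a Monte-Carlo sd of ≈ 0.08.
These sizes are the package's desk-scale defaults; all of them are
configuration, not constants.

## Known limitations

- The deep extractor is a stand-in; findings about deep-feature robustness
  on phantoms say nothing about pretrained-CNN features on patients.
- The binning perturbation re-extracts with a changed global discretization
  for the targeted sequence; first-order entropy/uniformity share that
  discretization and therefore move with it.
- The slice-profile model is a boxcar average, not a true excitation
  profile; the voxel-size round trip uses linear/nearest interpolation
  without anti-alias filtering beyond the profile average.
- No censoring: all survival times are observed, matching cohorts
  restricted to known OS; the C-index is the uncensored all-pairs form.
- Three-class OS experiments are out of scope; the 144-combination count
  for them is still derivable from the registry (t-score is binary-only).
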