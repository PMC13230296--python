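# ctca-audit

A segmentation-quality audit pipeline for coronary CT angiography (CTCA).

Deep-learning coronary-artery segmenters that look excellent on their training
cohort routinely degrade on new scanners, new patients and more diseased
anatomy. This package quantifies *why*, case by case: it measures the image
and anatomy factors that drive segmentation accuracy — contrast-to-noise
ratio, artery contrast enhancement, edge sharpness, calcium burden, vessel
calibre and curvature — and relates them statistically to Dice overlap at both
the whole-tree and individual-branch level (LM, LAD, LCx, D1, OM1, RCA).
A synthetic phantom generator provides contrast-enhanced coronary trees with
controllable quality factors and known ground truth, so the entire analysis
runs end-to-end without any clinical data; the same interfaces accept real
NIfTI volumes, masks and model outputs unchanged.

## What it computes

For a CT volume \(V\) (Hounsfield units) with arterial mask \(A\) and
peri-arterial ring \(R\) (voxels within a fixed number of face-connected
dilation steps of \(A\), excluding \(A\)):

- **Artery contrast enhancement (HU):** `ACE = mean(V[A]) − mean(V[R])`
- **Contrast-to-noise ratio:** `CNR = ACE / sd(V[R])` (population SD)
- **Edge sharpness (HU/mm):** mean spacing-aware gradient magnitude
  `|∇V|` (central differences) over the arterial boundary voxels
- **Dice similarity coefficient:** `DSC = 2|A∩B| / (|A|+|B|)` per tree and,
  via nearest-centreline-point attribution, per branch
- **Ensembling:** soft averaging of probability maps (threshold 0.5,
  inclusive) and strict-majority voting of binary masks
- **Vessel morphometrics:** centreline from 3D thinning + longest geodesic
  path; local diameter = 2 × maximal inscribed sphere radius; mean absolute
  curvature `κ = |x′×x″| / |x′|³` on an arc-length-resampled, smoothed path
- **Calcium stratification:** Agatston-style bins 0 / 1–99 / 100–399 / ≥400
- **Cohort statistics:** Pearson correlations of tree DSC against the three
  quality metrics; Welch's t-tests of DSC between cohorts within each calcium
  stratum; sex-stratified per-branch correlations of branch DSC against mean
  diameter and curvature. Significance at p < 0.05, no multiplicity
  correction (deliberately exploratory); cells with n < 3 are reported as
  not-estimable.

## Worked example

```python
from ctca_audit import pipeline

rep, table = pipeline.run_pipeline(
    {"simulate": {"n": 12, "seed": 3, "shape": (96, 96, 96),
                  "spacing": (0.5, 0.5, 0.5)}})
print(table[["id", "sex", "calcium_stratum", "tree_dsc", "cnr",
             "contrast_enhancement", "edge_sharpness"]].head(5).round(3))
for c in rep.quality_correlations:
    print(f"{c['x']:>22s}: r = {c['r']:+.3f}, p = {c['p']:.4f}, n = {c['n']}")
```

prints

```
     id    sex calcium_stratum  tree_dsc    cnr  contrast_enhancement  edge_sharpness
case000   male             low     0.984  9.063               357.789         472.935
case001   male             low     0.959  4.698               230.809         253.447
case002 female        moderate     0.980  5.130               242.998         290.138
case003 female        moderate     0.901  2.734               192.480         250.218
case004   male            none     1.000 13.179               341.915         447.208

                   cnr: r = +0.617, p = 0.0327, n = 12
  contrast_enhancement: r = +0.757, p = 0.0044, n = 12
        edge_sharpness: r = +0.678, p = 0.0154, n = 12
```

Each row is one synthetic case: its Dice score against ground truth (from an
HU-window pseudo-segmenter whose quality degrades with poor contrast, noise,
blur and calcium blooming), the three image-quality metrics, and its calcium
stratum. The correlation block is the cohort-level finding: cases with
stronger contrast enhancement and sharper edges are segmented more
accurately.

## Command line

```bash
audit simulate --n 12 --seed 3 --out cohort/       # write NIfTI cohort + meta.csv
audit metrics  --image img.nii.gz --mask ref.nii.gz
audit evaluate --pred p1.nii.gz --pred p2.nii.gz --ref ref.nii.gz --ensemble vote
audit geometry --ref-labels labels.nii.gz
audit run      --config config.json --out results/  # end-to-end cohort audit
```

`audit run` takes a JSON config with either a `simulate` block or a `cases`
list of NIfTI paths plus a metadata CSV (`id,sex,calcium_score,cohort`), and
writes `cases.csv`, `report.json` and one CSV per report table. Runs are
byte-reproducible given the config and seed.

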