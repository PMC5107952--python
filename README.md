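# msigrade

Automated pathological-response grading of colorectal-cancer liver
metastases (CRCLM) from MALDI mass-spectrometry-imaging (MSI) lipid data.

Assessing how a metastasis responded to preoperative chemotherapy is
normally a subjective, semi-quantitative histopathology call.  `msigrade`
implements a computational alternative for pathologists and MSI
researchers: per-pixel lipid spectra acquired on a 100 µm grid (m/z
460–1200, positive and/or negative ionization) are turned into a
histology map, a discriminant-lipid marker table, and a modified Tumor
Regression Grade (mTRG) that stratifies lesions into response groups for
survival analysis.

## The pipeline

1. **Preprocess** — Savitzky–Golay smoothing, total-ion-current (TIC)
   normalization, peak picking at signal-to-noise ≥ 3, and single-linkage
   m/z alignment of per-pixel peak lists into a pixels × features matrix.
2. **Segment** — spatially-aware k-means (k = 7, pixel radius r = 1):
   each pixel's log-intensity vector is augmented with Gaussian-weighted
   neighbour vectors (weight `exp(−(di²+dj²)/(2σ²))`, σ = r/2) before
   clustering, which yields spatially coherent segments.  The seven
   segments are correlated with annotated histology: adjacent liver,
   tumor, usual necrosis (UN), infarct-like necrosis (ILN), fibrosis,
   inflammation, and mucin/MALDI-matrix.
3. **Classify** — the correlated segments form a labelled spectral
   library; a PLS-DA model (PLS2 regression of one-hot class labels on
   centered intensities, argmax class score) classifies the pixels of new
   lesions.  UN-vs-ILN subtyping matters because ILN indicates response
   to treatment while UN accompanies tumor progression.
4. **Markers** — per feature × histology, the Mann–Whitney ROC a.u.c.
   against a stratified random subset of all other histologies, plus the
   fold change (mean target / mean rest intensity, mean ± sd across
   samples), ranked into a top-N marker table.
5. **Grade** — with `T` = % viable tumor + UN and `F` = % fibrosis +
   inflammation over the lesion (liver, mucin/matrix excluded; fibrosis
   and inflammation merged):

   | mTRG | T (%) | F (%) |
   |------|----------------|-------|
   | 1 | 0 | any |
   | 2 | < 7 | any |
   | 3 | ≥ 7 and < 50 | any |
   | 4 | ≥ 50 | ≥ 5 |
   | 5 | ≥ 50 | < 5 |

   Higher grade = worse response.  Grades 1–2 are a *major* response,
   grade 3 *partial*, grades 4–5 *minor*.
6. **Survival** — Kaplan–Meier curves per response group compared by the
   log-rank (Mantel–Cox) test; grader agreement as Pearson r.

Because no public MSI cohort accompanies this analysis, the
`msigrade.synthetic` module generates seeded lesion phantoms whose
per-class marker intensities follow the published lipid fold changes
(e.g. SM(d18:1/16:0) ×5.62 in ILN) under multiplicative log-normal noise
calibrated so the headline ILN marker's binormal a.u.c. equals the
published 0.902.  Every stage of the pipeline is testable end to end
without downloads.

## Worked example

```python
from msigrade.synthetic import generate_phantom, generate_peak_matrix
from msigrade.segment import spatially_aware_segment, map_segments_to_histology
from msigrade.classify import PixelClassifier
from msigrade.grading import grade_lesion

# one synthetic lesion with known histology
truth = generate_phantom(width=128, height=128, seed=1)
matrix = generate_peak_matrix(truth, seed=1)

# spatially-aware segmentation (k = 7, pixel radius r = 1)
seg = spatially_aware_segment(matrix, k=7, r=1, seed=1)
mapping = map_segments_to_histology(seg, truth.labels)
for cluster, label in sorted(mapping.mapping.items()):
    print(f"cluster {cluster} -> {label.value:24s} "
          f"agreement {mapping.agreement[cluster]:.2f}")

# PLS-DA pixel classification and automated mTRG
clf = PixelClassifier(spatial_r=1, n_components=16, include_mucin=False)
clf.fit([(matrix, truth.labels)])
pred, _ = clf.classify(matrix)
comp, grade, group = grade_lesion(pred)
print(f"T = {grade.t_percent:.1f}%  F = {grade.f_percent:.1f}%")
print(f"mTRG {grade.grade} -> {group.value} response")
```

prints

```
cluster 0 -> tumor                    agreement 0.89
cluster 1 -> usual_necrosis           agreement 0.91
cluster 2 -> adjacent_liver           agreement 0.81
cluster 3 -> mucin_matrix             agreement 1.00
cluster 4 -> inflammation             agreement 0.75
cluster 5 -> fibrosis                 agreement 0.78
cluster 6 -> infarct_like_necrosis    agreement 0.75
T = 30.8%  F = 57.3%
mTRG 3 -> partial response
```

The seven clusters recover all six tissue histologies plus one
off-tissue matrix cluster; the classified pixel map then gives the
lesion 30.8% tumor + usual necrosis against 57.3% fibrosis +
inflammation — mTRG 3, a partial response.

A whole synthetic study (training lesions → spectral library → held-out
classification → grading → survival) runs from one config:

```sh
msigrade run-all config.yaml       # see PipelineConfig for the keys
```

Per-stage subcommands (`preprocess`, `segment`, `train`, `classify`,
`markers`, `grade`, `survival`, `simulate`) operate on imzML and
`x,y,...` CSV files.

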