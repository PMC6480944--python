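# gicasel

Group ICA, regional statistics and discriminant-guided feature selection
for two-group task-fMRI studies.

`gicasel` is for neuroimaging researchers who want to know *which brain
regions* distinguish a patient group from controls during a task — the
canonical example being working-memory (Sternberg item recognition) fMRI in
schizophrenia versus healthy subjects. Rather than voxel-wise contrasts, the
pipeline decomposes the data into functionally connected networks, reduces
each network to interpretable regional statistics, and lets a classifier
decide which of them matter:

1. **Group ICA.** Subject-run volumes (timepoints × voxels, voxel series
   mean-centred) are PCA-reduced per run, concatenated, group-PCA-reduced to
   the model order *k*, and unmixed with Infomax (natural-gradient ascent,
   logistic nonlinearity). *k* is estimated by a modified
   minimum-description-length criterion,
   `MDL(k) = −N′(p−k)·log(g_k/a_k) + ½k(2p−k+1)·log N′`, whose effective
   sample size N′ subsamples voxels to respect spatial smoothness.
   Per-subject spatial maps come from GICA back-projection, averaged over
   runs.
2. **Regional features.** Each subject's component map is segmented by a
   116-region AAL-style parcellation and each region's voxel set
   `V_r = [v_1..v_N]` summarized by mean, standard deviation (÷N), skewness,
   kurtosis (raw) and histogram entropy `−Σ P_i log₂ P_i` — 580 = 116 × 5
   features per subject per component.
3. **Selection + classification.** Under leave-one-out cross-validation,
   each fold ranks features by the Fisher discriminant ratio
   `FDR(x) = |mean_h − mean_s|² / (var_h + var_s)` on its training rows,
   then adds them in rank order while an inner LOOCV scores each subset with
   a linear SVM (C = 1.09) or 1-NN (Euclidean); the smallest subset with
   maximal inner accuracy predicts the held-out subject. The held-out
   subject never influences ranking, scaling or subset choice.
4. **Report.** Selected feature columns are backtracked to named regions,
   coalesced across components, and written as TSV tables plus a NIfTI mask
   of the frequently occurring regions.

Because the clinical multi-site dataset this kind of study uses is
access-controlled, the package ships a seeded synthetic-cohort generator
(34 + 34 subjects, 3 runs, TR 2 s, 180-volume runs, block design with
memory loads of 1/3/5 digits) that plants spatially independent
region-supported sources, task-locked time courses, and a group amplitude
effect of known size — so every stage, end to end, is testable and its
parameter recovery measurable.

## Worked example

A complete synthetic study — simulate, decompose, featurize, classify,
backtrack:

```python
import gicasel as g

grid = g.GridSpec(nx=16, ny=18, nz=14, n_timepoints=180)
atlas = g.make_atlas(grid, n_regions=24, seed=11)
supports = g.plan_source_supports(atlas, n_sources=4, seed=11)
cohort = g.CohortSpec(n_healthy=34, n_patient=34, n_runs=3, n_sources=4,
                      effect_regions=supports[0], seed=11)
scans, manifest = g.simulate_cohort(cohort, atlas, grid)

gica = g.run_group_ica(scans, n_components=4, config=g.GicaConfig(seed=0))

# component 3 carries the planted effect here; a real analysis loops over all
maps = {sid: gica.map_volume(gica.subject_maps[sid][3])
        for sid in manifest.subject_id}
features = g.build_feature_matrix(maps, atlas, manifest)

svm = g.loocv_pipeline(features, g.ClassifierSpec(kind="linear_svm", C=1.09),
                       max_subset=10)
knn = g.loocv_pipeline(features, g.ClassifierSpec(kind="knn"), max_subset=10)
regions = g.backtrack_features(svm.chosen_subsets(), features.column_descriptors)
```

Output:

```
cohort: 68 subjects, 204 runs
group ICA: 4 components, converged=True
feature matrix: 68 subjects x 120 features
LOOCV accuracy: SVM 97.1%, 1-NN 97.1%
most frequently selected regions:
  Region_006: 68/68 folds, stats=['mean', 'std']
  Region_012: 68/68 folds, stats=['mean', 'std']
  Region_013: 68/68 folds, stats=['mean', 'std']
  Region_019: 68/68 folds, stats=['mean', 'std']
  Region_016: 54/68 folds, stats=['std']
planted effect regions: ['Region_006', 'Region_009', 'Region_012',
                         'Region_013', 'Region_016', 'Region_019']
```

The planted amplitude effect (patients' source amplitude × 1.22 in six
designated regions, regional Cohen's d ≈ 2) is recovered: both classifiers
separate the groups at ~97%, and every frequently selected region is one of
the planted six. With a 116-region atlas the same calls produce 580-column
feature matrices and reports in AAL nomenclature (`Amygdala_L`, `Heschl_R`,
`Vermis_6`, ...).

The same pipeline runs from the shell on NIfTI + TSV artifacts:

```bash
gicasel simulate --config cohort.yaml --out data/ --seed 1
gicasel gica     --manifest data/manifest.tsv --components auto --out gica/
gicasel features --gica gica/ --manifest data/manifest.tsv --atlas data/atlas.nii --out feat/
gicasel select   --features feat/ --classifier svm --c 1.09 --repeats 10 --out sel/
gicasel report   --selection sel/ --features feat/ --atlas data/atlas.nii --out report/
```

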