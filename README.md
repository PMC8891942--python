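# pasym

Voxel-wise hemispheric functional-connectivity asymmetry analysis for
resting-state BOLD data.

For every brain voxel, the asymmetry score is the difference between its
mean Fisher-z functional connectivity with supra-threshold voxels of the
opposite hemisphere and the corresponding mean within its own hemisphere
(threshold r > 0.2; negative correlations excluded). The package covers
the full analysis chain on spatially normalized data:

- **`pasym.io_core`** — NIfTI volumes/masks, TSV subject/motion tables,
  YAML run configuration, shared domain types.
- **`pasym.preprocess`** — framewise displacement, motion-based subject
  exclusion, Friston-24 + CSF/WM nuisance regression, linear detrending,
  0.01–0.08 Hz band-pass filtering, FD-based scrubbing (0.2 mm).
- **`pasym.pas`** — hemisphere labeling by world-space x sign, blocked
  voxel-wise asymmetry computation, a naive reference oracle, and
  group stacking.
- **`pasym.inference`** — covariate-adjusted ANCOVA partial-F maps,
  post-hoc two-group t maps, Benjamini–Hochberg FDR, connected-cluster
  extraction (6/18/26 connectivity), and summary-statistics tests
  (ANOVA / pooled t / chi-square) for demographics tables.
- **`pasym.association`** — Spearman correlation of cluster-mean scores
  with clinical variables, BH-corrected over the tested grid.
- **`pasym.classify`** — leave-one-out SVM discrimination from
  cluster-mean features with per-fold standardization and feature-subset
  sweeps.
- **`pasym.simulate`** — synthetic two-hemisphere BOLD cohorts with a
  latent-factor covariance model (closed-form homotopic / within-side
  correlations), realistic motion traces, and group-structured clinical
  tables, so everything runs without real data.
- **`pasym.cli`** — the `pasym` command-line tool and pipeline
  orchestration.

## Command line

```sh
pasym demo --out-dir demo --seed 0          # end-to-end synthetic run
pasym simulate --out-dir data --seed 0 --region-size 8 --delta 1.2
pasym run --data-dir data --out-dir results
pasym preprocess --bold sub-001_bold.nii.gz --mask mask.nii.gz \
    --motion sub-001_motion.tsv --nuisance sub-001_nuisance.tsv \
    --out sub-001_clean.nii.gz
pasym compute --bold sub-001_clean.nii.gz --mask mask.nii.gz \
    --out-pas sub-001_pas.nii.gz
pasym table1 --subjects subjects.tsv
pasym correlate --cluster-means means.tsv --subjects subjects.tsv \
    --variables gi_item,sleep_disturbance --out correlations.tsv
pasym classify --features means.tsv --subjects subjects.tsv \
    --subsets "cluster_1;cluster_2;cluster_1+cluster_2" --out svm.tsv
```

`pasym run` executes preprocess → asymmetry maps → group inference
(three-group ANCOVA plus the three pairwise contrasts) → correlation →
classification, writes a `manifest.json`, and resumes from existing
intermediates on re-run. All thresholds live in a YAML config
(`--config`); defaults match the analysis settings above.

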