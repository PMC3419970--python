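# adhdml

A tested re-implementation of a multi-site, multimodal machine-learning
pipeline for diagnostic classification of ADHD (attention deficit
hyperactivity disorder) versus typical development from resting-state
functional MRI, structural morphometry and demographic features — the kind
of pipeline used in the ADHD-200 global competition. It is aimed at
researchers who want to study the pipeline's statistical machinery
(feature ranking, unbiased subset selection, cross-site harmonization,
ensemble voting) end to end without access to the original imaging
release: a synthetic multi-site cohort generator reproduces the
statistical structure the analysis assumes, so every stage is testable on
a laptop.

## What it computes

**Features.** From per-subject ROI time series: Fisher-z Pearson
connectivity matrices (z = atanh r), whose lower triangle supplies
R(R−1)/2 edge features (79,800 for a 400-ROI atlas); nodal amplitude
spectra |F(x)| per frequency bin; and graph-theoretical metrics of the
proportionally thresholded brain graph — clustering coefficient CC, local
efficiency E_loc, characteristic path length CPL, global efficiency
E_glob, normalized CC and CPL (γ, λ) against 100 degree-preserving random
rewirings, small-worldness σ = γ/λ, and Louvain modularity Q, plus five
nodal metrics (strength, CC_i, E_loc_i, regional efficiency E_reg_i,
betweenness centrality BC_i), averaged across sparsity levels
{10, 15, 20, 25, 30}%. From voxel data: global connectivity (mean Fisher-z
correlation of each voxel with all other in-mask voxels) and regional
homogeneity (Kendall's W over each voxel's 26-neighborhood,
W = 12S / (m²(n³−n))).

**Learning.** Features are ranked by multiple-subsample linear SVM-RFE:
per elimination pass, linear soft-margin SVMs are fitted to stratified
subsamples and each feature's criterion is mean(w²)/sd(w²); half of the
features are dropped per pass down to 5,000 survivors, then one by one.
The number of top features k\* is chosen by 10-fold cross-validation held
*external* to the ranking (features are re-ranked inside every training
fold), which makes the accuracy-vs-k curve an unbiased estimate of
generalization accuracy. RBF-SVM hyperparameters (C, kernel width) are
grid-searched on a log2 grid with internal stratified CV. Site-specific
classifiers are retrained on all of a site's labeled subjects; sites
without labeled (or any) training data are served by an across-site
classifier after per-feature mean alignment on the typically-developing
subgroup (or on all subjects when labels are unknown). Modality votes are
combined by majority (ties → TD), ADHD subtypes assigned from site-level
training priors, and predictions scored by 3-class accuracy, 2-class
sensitivity/specificity, subtype accuracy, and competition-style points
(1 for correct TD, 1 for correct ADHD with correct subtype, 0.5 with wrong
subtype).

## Worked example

```python
from adhdml import demo_config, run_pipeline

report, artifacts = run_pipeline(demo_config(seed=1))
print(report.as_dict())
```

prints (three synthetic sites, one of them TD-only and handled by
cross-site alignment; demographics + connectivity + graph modalities; a
planted connectivity effect):

```
{'accuracy_3class': 0.826, 'sensitivity': 1.0, 'specificity': 1.0,
 'subtype_accuracy': 0.556, 'points': 21.0, 'max_points': 23.0}
```

All 23 held-out subjects are classified correctly as ADHD vs TD
(sensitivity and specificity 1.0 — the planted edge effect is strong and
the voting ensemble recovers it), while 3-class accuracy is lower because
ADHD subtypes are assigned from site priors alone, which is exactly the
design's behavior when subtype structure carries no imaging signature.

The same stages are available as CLI subcommands:

```bash
adhdml simulate --out data/ --seed 1
adhdml features --pheno data/phenotypes.csv --timeseries-dir data/timeseries \
    --modality connectivity --out conn.csv
adhdml rank --features conn.csv --pheno data/phenotypes.csv --out ranked.csv
# ... select / train / predict / vote / score
```

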