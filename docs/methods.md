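# Methods

## The synthetic cohort generator

The generator emulates the statistical structure of a multi-site pediatric
ADHD study, so the downstream machinery can be exercised and validated
without the original imaging release.

**Phenotypes.** Subject counts per site, diagnosis (TD, ADHD-C, ADHD-H,
ADHD-I) and gender are taken from the configuration and reproduced
exactly. The bundled `adhd200_template()` carries the published
training-set composition of the eight-site ADHD-200 release (e.g. NI:
23 TD / 18 C / 6 H / 1 I; Peking: 116 TD / 29 C / 49 I), including the
per-site, per-diagnosis female counts for the five sites with ADHD
subjects; the two TD-only sites' gender split is not published and is
generated even. Ages are uniform within a per-site range (years);
full-scale IQ is normal with a per-site mean, sd 15 points, and an
additive shift of −9 points in ADHD, the population-level deficit reported
in large family studies. IQ missingness is site-wise only (the entire NI
site), never subject-wise. Default fMRI dimensions are T = 176 time points
at TR = 2 s — typical acquisition lengths; neither is asserted by any
test — and frequencies outside 0.009–0.08 Hz are removed, the standard
resting-state band.

**ROI time series.** Gaussian white noise is masked in the frequency
domain (exact removal of out-of-band spectral mass, rescaled by the
analytic variance factor) and then colored by the Cholesky factor of the
class covariance. Frequency-domain masking was chosen over IIR filtering
because it is exactly controllable and leaves no filter transients. The
class covariance is the identity except on *planted edges*: ROI pairs
whose Fisher-z correlation is `planted_base_z` (default 0.2) in TD and
`planted_base_z + d` in ADHD, so the population z-difference between
classes is exactly the configured effect size d.

**Voxel blocks.** Each voxel carries independent band-limited noise; voxels
inside a planted block share a fraction of their variance with a common
block signal (default 0.2, plus a configurable increment in ADHD). Raising
the shared fraction raises within-neighborhood concordance, i.e. the
class effect acts on Kendall's W directly.

**Morphometry.** 747 named columns — 9 surface measures × 34 cortical
regions × 2 hemispheres plus 3 volume/intensity measures × 45
non-cortical segmentation entities — as standardized surrogate features
(population sd 1), with additive class shifts on configured columns.

What the generator does *not* emulate: hemodynamics, motion and scanner
noise spectra, spatial autocorrelation beyond the planted block,
age/gender effects on imaging features, and site effects on imaging
features unless planted explicitly. Passing tests therefore demonstrate
the correctness and statistical soundness of the pipeline machinery on
data satisfying its assumptions — not classifier performance on real
imaging data.

## Functional features

Correlations are capped at |r| ≤ 1 − 1e−7 before atanh, so perfectly
correlated series map to a large finite z. Connectivity matrices are
computed from the series as given (the band-limited preprocessing is
assumed upstream); constant columns cannot be correlated and their
rows/columns are zeroed with a warning. Power spectra are one-sided
amplitude spectra (modulus of the Fourier coefficients) without detrending
or windowing — upstream preprocessing already detrends; squared power is
available via an exponent parameter since the amplitude/power convention
is ambiguous in parts of the literature. Kendall's W uses average ranks
for ties and no tie correction by default (the data are continuous); the
tie-corrected denominator is behind a flag. Edge-of-mask voxels use only
their in-mask neighbors (m < 27) rather than being dropped, which keeps
maps defined on small synthetic grids; voxels with no in-mask neighbor are
undefined (NaN).

## Brain graphs

Proportional thresholding retains round(p·R(R−1)/2) of the strongest
positive Fisher-z connections; negative connections are always discarded;
ties break deterministically by (weight desc, row asc, column asc).
Weighted path distances are d_ij = 1/w_ij, the standard choice for
connectivity weights. Weighted clustering follows the Onnela
geometric-mean formulation. Local efficiency of a node is the global
efficiency of its neighborhood subgraph. CPL averages over connected pairs
only (an edgeless graph reports +inf and a flag); global and regional
efficiency count unreachable pairs as zero efficiency. Betweenness is
normalized by (R−1)(R−2)/2 so it is the fraction of shortest paths through
a node. Modularity Q is the best of five seeded Louvain restarts; the
partition itself is run-dependent, so only Q is exposed as a feature.
γ and λ normalize CC and CPL by the mean over 100 seeded
degree-preserving double-edge-swap rewirings (10 swaps per edge), the
field-standard null; an Erdős–Rényi ensemble with the same node and edge
counts is available by flag. Both "strength" (weight sum) and "degree"
(connection count) are emitted as nodal features, since either reading of
nodal strength appears in the literature. Metrics are averaged across
sparsity levels {0.10, 0.15, 0.20, 0.25, 0.30}; levels where a metric is
undefined are excluded from its average with a warning.

## Feature ranking (mSVM-RFE)

Ranking fits use a soft-margin linear SVM with C = 1 (exposed in the
config); features are standardized to mean 0 / sd 1 on exactly the rows
of each fit, never on held-out rows, so weight magnitudes are
commensurate and no information leaks by construction. The elimination
schedule drops half of the surviving features per pass while more than
5,000 survive, then one feature per pass. The multiple-subsample criterion
fits 10 linear SVMs per pass on stratified 90% subsamples without
replacement and scores each feature by mean(w²)/sd(w²) across subsamples
(with a tiny epsilon guard when the sd is zero); with a single subsample
at fraction 1 the criterion reduces to w², i.e. plain SVM-RFE. Criterion
ties break by original column order, which makes rankings deterministic
given the seed. Note that at very small subsample counts (2–3) the
sd-normalized criterion can favor a feature whose tiny weight happens to
be stable; the default of 10 subsamples makes this rare.

## Subset selection and hyperparameters

The accuracy-vs-k curve comes from stratified 10-fold CV that is external
to the ranking: each fold re-ranks features on its own training rows, and
for every candidate k tunes and trains an RBF-SVM on the training rows
only before scoring the held-out rows. k\* is the argmax of mean hold-out
accuracy, ties to the smallest k. The candidate grid defaults to an
approximately geometric ladder 1, 2, 5, 10, 25, … capped at the feature
count. Accuracy is the objective (the competition metric);
balanced accuracy is available by flag for skewed sites. Hyperparameters
are re-tuned per (fold, k) — the stricter reading that keeps every stage
inside the fold — on a coarse log2 subgrid (step 4) of the full grid
C ∈ 2^−5…2^15, width ∈ 2^−15…2^3; the standalone tuner uses the full
21 × 19 grid with internal stratified 10-fold CV. Grid ties resolve to the
smaller C, then the smaller width.

## Site models, alignment, voting

Site models are retrained on all of a site's labeled training rows using
the top-k\* features, standardized by site training statistics; they
predict only from their selected features and refuse input missing any of
them unless median imputation is explicitly enabled. A site missing a
feature entirely (e.g. no IQ) simply trains without it — never imputed
across sites. ADHD-H subjects are excluded from training by default.
TD-based alignment replaces each site's per-feature TD mean by the pooled
TD mean — exact to machine precision and a pure shift, so within-site
class contrasts are untouched; label-free alignment does the same with
grand means. Mean-only alignment is deliberate: no variance rescaling
(a flag exists but defaults off) and no distribution-level harmonization.
Votes are combined by majority; ties go to TD, reflecting the emphasis on
correct TD calls in a majority-TD cohort (configurable). Subtypes come
from the modal subtype among the site's ADHD training subjects, pooled
across sites when a site has none, ties to ADHD-C (the overall more
common subtype). The point scheme (1 / 1 / 0.5 / 0) reproduces the
half-point granularity of the competition scoring and is configurable.
Prevalence percentages round half away from zero.

## Problem sizes and determinism

The bundled demonstration study uses three sites (~85 subjects), 8 ROIs,
T = 96, three modalities, a k-grid of (1, 2, 5, 10, 25), a 5 × 5 log2
tuning grid with 5 inner folds, and 20 random graphs for γ/λ — sizes
chosen so a full run completes in a few minutes while still exercising
every code path (labeled sites, a TD-only site served by alignment, and
modality voting). All randomness flows from named per-stage seeds derived
from one master seed via numpy `SeedSequence`, so identical configurations
give bit-identical outputs and single stages can be rerun in isolation.

## Known limitations

Louvain modularity is partition-unstable by nature; only Q is used.
γ is undefined (flagged) when the random ensemble has zero clustering, as
happens on very sparse graphs. The external-CV accuracy estimate is
unbiased but high-variance at site-sized n; its argmax over the k-grid
carries the usual mild selection optimism, which the null-permutation
tests bound. The generator's independence assumptions make planted
effects easier to detect than real effects of equal nominal size.
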