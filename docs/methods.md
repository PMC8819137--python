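# Methods

This note documents the models, algorithms, parameter choices, and known
limits of `emtpath`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The stratification problem

Clear cell renal cell carcinoma (ccRCC) splits into an epithelial (Epi) and
a mesenchymal (Mes) molecular subtype with different survival. The package
derives that stratification from expression data and then learns to
reproduce it directly from H&E histology, so the molecular label can be
predicted where only slides exist.

## Molecular arm

### Signature selection

Candidate genes (typically a published EMT gene set) are scored by Pearson
correlation against four canonical markers: CDH1 (epithelial side) and
VIM, CDH2, FN1 (mesenchymal side). A gene is selected when, for at least
one marker, |r| ≥ `r_min` and the Benjamini–Hochberg adjusted p-value of
that correlation (adjusted across all candidate × marker pairs) is ≤
`alpha`. Defaults: `r_min = 0.4`, `alpha = 0.05`, both config-exposed —
the selection rule is a correlation screen by design, and the exact
threshold is a tunable of the analysis, not a constant of nature. A
selected gene joins the mesenchymal set when its strongest association is
positive with a mesenchymal marker or negative with an epithelial marker;
otherwise the epithelial set. Marker genes themselves pass the screen
trivially (self-correlation) and are kept in the signature.

### Subtype clustering and orientation

Samples are clustered on their signature-gene profiles with agglomerative
clustering using the centered-correlation distance, d(x, y) = 1 − Pearson
r(x, y), cut at two clusters. Linkage defaults to *average*; Ward is
reserved for the methylation analysis where it is part of the procedure.
Centering makes the distance invariant to affine rescaling of a sample's
profile (an uncentered cosine distance is not), which the tests verify in
both directions. Cluster names are then fixed by marker contrast: the
cluster with the larger mean(z of mesenchymal markers) − mean(z of
epithelial markers) is Mes; an exact tie raises rather than guessing.

### EMT score

Per sample, the genes of the signature (epithelial ∪ mesenchymal sets) are
ranked by expression, descending, with average ranks on ties; gene order
is fixed (sorted ids) so ECDF step order is deterministic. With F_mes and
F_epi the empirical CDFs of the two sets' rank positions evaluated at every
occupied rank,

    D+ = max_t (F_mes − F_epi) floored at 0
    D− = max_t (F_epi − F_mes) floored at 0
    score = D+ − D−  ∈ [−1, +1].

This signed two-sample Kolmogorov–Smirnov construction attains +1 exactly
when every mesenchymal gene outranks every epithelial gene, −1 in the
mirror case, and is invariant under any strictly monotone transform of the
sample's expression vector (rank-based). A brute-force oracle (exhaustive
ECDF evaluation at every rank) backs the implementation in tests for small
gene sets.

### Methylation clustering

Beta values are dichotomized at 0.3 — a probe with beta ≥ 0.3 counts as
hypermethylated (the boundary value is inclusive) — and samples are
clustered by Ward agglomeration of pairwise Jaccard distances between
binary probe vectors, cut at two clusters.

### Survival and frequency statistics

Kaplan–Meier estimation and the two-group log-rank test delegate to
`lifelines`; Benjamini–Hochberg to `statsmodels`. Conventions: censored
subjects at time t remain at risk for events at t; the log-rank statistic
is chi-square on 1 df. The mutation-frequency permutation test is written
here: statistic = |freq difference| between groups, null built by label
shuffling, p = (1 + #{null ≥ observed}) / (1 + n_perm). The add-one
estimator never returns p < 1/(n_perm + 1) and is conservative
(super-uniform under the null) — exact uniformity is unattainable with a
discrete statistic, and the tests check super-uniformity rather than a KS
fit. Multivariate Cox regression is intentionally not reimplemented;
`lifelines.CoxPHFitter` is the supported route where needed.

## Imaging arm

### Tiling and background filtering

Images are cut into non-overlapping 256×256 windows, row-major, partial
edge windows dropped. Coordinates are 0-based with origin top-left; a tile
origin (x, y) means column x, row y, with half-open extent
[x, x+256) × [y, y+256). A pixel is background when **all three channels
are ≥ 220** (near-white glass); a tile is dropped when its background
fraction exceeds 0.5 (exactly 0.5 is kept). The inequality direction is
flippable via `BackgroundFilterConfig(background_is_bright=False)` for
non-standard imagery, but near-white background is the default because
H&E glass is bright.

### Macenko stain normalization

Optical density is OD = −log10((I + 1)/255) per channel. Pixels with any
channel below β = 0.15 OD are discarded as non-tissue; the surviving cloud
is projected onto its top-2 covariance eigenvectors; the robust extreme
directions at the (α, 100−α) = (1, 99) angle percentiles, back-projected
and unit-normalized, are the stain vectors. The column with the larger
blue-channel component is hematoxylin. Concentrations come from
nonnegative least squares (closed form for the 2-stain case: clamp a
negative coefficient to zero and project on the remaining stain);
per-stain 99th-percentile concentrations define the dynamic range. A tile
is normalized by scaling its concentrations by reference/source maxima and
re-rendering through the reference stain matrix, clipped to 0–255. One
profile per slide (pooled pixel sample from up to 50 retained tiles) is
the intended use; per-tile estimates are supported and are what the
forward-model tests exercise. Degenerate inputs raise: grayscale (rank-1
OD) → "degenerate stain geometry"; fewer than 1000 tissue pixels →
"insufficient tissue".

### Synthetic slides as the stain oracle

Tiles are rendered through the exact inverse of the OD map:
I = 255·10^(−S·c) − 1 for concentration fields c, so Macenko estimation
has a ground-truth stain matrix to recover; the acceptance suite requires
both vectors within 2° on ≥ 95 % of tiles. The default synthetic stain
matrix keeps both stains' red/blue absorbances high enough that moderate
concentrations clear the per-channel β filter — with literature eosin
vectors (blue OD component ≈ 0.11) the any-channel filter would discard
pure-eosin pixels and the extreme-angle construction would lose one pole.
Tissue textures: background is uniform near-white (≥ 240 everywhere);
necrosis is low-contrast mottled debris with both stains; stroma is wavy
eosin-rich fibres; tumor is an eosin cytoplasm field with elliptical
hematoxylin nuclei placed uniformly (overlap allowed — density is the only
controlled signal), at 25 nuclei/tile for Epi vs 70 for Mes, radii 4–9 px.
Slide grids default to 14×14 (196 tiles), inside the realistic 170–9500
per-slide tile range seen on real whole-slide images; smaller grids are
allowed for compact tests with a warning rather than an error, since the
range is an empirical regularity, not a validity condition. All randomness
descends from a single integer seed through hashed stream splits
(seed + context tags), making every artifact byte-reproducible.

What the generator does **not** emulate: real nuclear chromatin texture,
pen marks, blur, folds, pyramidal multi-resolution structure, or the
continuum of mixed morphologies in real tumors. Passing tests therefore
demonstrate that the pipeline's mechanics are correct and that it learns a
planted, separable morphological signal — not that it reaches any
particular accuracy on real slides.

### Classifiers and training

Two classifiers share one frozen backbone: a 3-class tumor detector
(necrosis / stroma / tumor) trained on a stratified 7 : 1.5 : 1.5 split
(largest-remainder apportionment within each class), and a 2-class Epi/Mes
detector trained with slide-wise k-fold cross-validation — a slide's tiles
never straddle folds, and per class the fold sizes differ by at most one
slide. Epi/Mes training pools are balanced by keeping every Epi slide,
downsampling Mes slides without replacement to twice the Epi count, then
sampling at most 600 tumor tiles per Epi slide and 300 per Mes slide.

The transfer-learning contract is: backbone frozen, only the final softmax
layer trained, by minibatch SGD at learning rate 0.01 (defaults: 10
epochs, batch 32; the scaled experiments use 5 epochs). The `small-cnn`
backbone is a fixed, seeded 3-block convolutional extractor (8/16/32
filters, 3×3, ReLU, 2×2 max-pool) over tiles area-averaged to 64×64,
ending in 8×8 feature maps whose global average pooling (GAP) feeds the
head. Head training standardizes features internally and folds the
standardization back into the returned weights, so the head is exactly
linear over raw GAP features — the precondition for class activation maps.
An `inception-v3-pretrained` backbone name is registered for environments
with a torch runtime.

### Aggregation, heatmaps, CAM

The slide AI score is the plain (unweighted) mean of its tumor tiles' Mes
probabilities; > 0.5 calls Mes, < 0.5 Epi, and exactly 0.5 is called Mes
with a `boundary` flag since the defining inequalities are strict.
Heatmaps place each tile's score at its grid cell, masking cells without a
tumor tile. CAM for class c is Σ_k w_k^c f_k(u, v) over the final conv
feature maps, bilinearly upsampled to tile size; min-max scaling is for
display only and the raw map (and its pre-upsampling version, on which the
GAP algebra — spatial mean of CAM = logit − bias — holds exactly) is
retained.

## Scaled experiment sizes

The end-to-end experiment used by the acceptance suite runs 60 synthetic
slides (20 Epi / 40 Mes) of 196 tiles each with 3-fold slide-wise
cross-validation and 1000 detector tiles per class — sizes chosen so the
whole experiment is a single-CPU job while every mechanism (tiling,
filtering, detection, balancing, grouped folds, aggregation) runs exactly
as at full scale. Stain normalization inside the experiment is off by
default: synthetic slides share one rendering stain matrix, so
normalization is an identity-cost step there; it is exercised directly by
the stain-oracle tests and available via `normalize_stains=True`.

## Known limitations

* The headline numbers of the motivating study (tile AUC ≈ 0.99, slide AUC
  ≈ 0.84 on TCGA) require controlled-access whole-slide images and
  GPU-scale training; they are out of scope here, and synthetic results do
  not estimate them.
* The two-subtype model is fixed; an intermediate stratum can be formed as
  an EMT-score tertile split downstream, but no three-group definition is
  built in.
* The optional pyramidal-WSI adapter (reading a level near 10×) is not
  included; inputs are expected at working resolution.
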