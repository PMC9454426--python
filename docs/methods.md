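# Methods

## Problem setting

Salivary gland carcinomas (SGC) comprise several rare subtypes whose
histological differentiation is difficult; adenoid cystic carcinoma (AdCy)
in particular is prone to late metastasis, so subtype calls matter
clinically. MALDI mass-spectrometry imaging (MSI) of a tissue microarray
(TMA) yields a full mass spectrum per 50 µm pixel, and each TMA core carries
one class label (six SGC subtypes, healthy control tissue, and matrix-only
control spots — eight classes in all). `msidl` implements the corresponding
analysis workflow as a reusable package: spectral preprocessing, per-pixel
1-D CNN classification under stratified 5-fold cross-validation, DeepLift
discriminative-mass discovery, supervised density-preserving 2-D embedding,
and spatial/core-level reporting. Because no public dataset accompanies this
setting, the package ships a first-class synthetic TMA generator that
defines the test conditions and the ground truth against which feature
recovery is scored.

## Data model

All stages share one equidistant m/z axis (`BinningScheme`): bins are
half-open and lower-inclusive, bin *i* covering
`[lo + i·w, lo + (i+1)·w)` with center `lo + (i+0.5)·w`. Pixels live on a
0-based integer grid; imzML's 1-based coordinates are shifted at the I/O
boundary. Interchange is continuous-mode imzML 1.1 (via pyimzml) with
annotations as TSV sidecars; a single-file HDF5 container exists because
XML-adjacent formats are slow for spectra with thousands of bins.

## Synthetic TMA generator

Every pixel spectrum is a non-negative sum of Gaussian peaks of constant
width `peak_sigma` (default 2.5 mDa) rendered on the binned axis by
integrating the Gaussian over each bin interval, plus additive half-normal
noise of scale `noise_sigma` (default 0.02). Peak roles:

* **Class markers** (5 per class): peaks unique to one class, snapped to bin
  centers, mean height 0.5 with per-pixel lognormal jitter
  (`marker_jitter`, default sigma 0.3). These stand in for the
  discriminative masses the attribution stage must recover. The matrix-only
  class also receives 5 characteristic peaks, rendered only in matrix
  spots; physically these play the role of matrix cluster peaks, which are
  strongest where no tissue suppresses them.
* **Background peaks** (30): shared by all tissue classes, heights 0.2–0.7.
* **Matrix peaks** (500 incl. the reference): present in every pixel. The
  reference peak has base height 3.0 — the globally most intense peak by
  construction — with per-pixel lognormal amplitude A. Each satellite's
  height mixes A with an independent lognormal term so that its population
  Pearson correlation with the reference equals `matrix_corr` (default
  0.9) exactly; the mixing weight is `delta = sqrt(1/c² − 1)`.

All planted m/z values sit on a jittered regular grid with spacing above
`2·0.02 Da + 2 bins`, so matrix-filter windows can never clip a marker and
the planted structure is unambiguous. Cores are disks on a regular grid of
non-overlapping slots; a fraction `off_tissue_fraction` (default 0.1,
per-pixel Bernoulli) of tissue-core pixels carries matrix-only signal and is
flagged tissue=0. The generator is fully driven by one seed; identical
configurations produce byte-identical datasets.

**Desk-scale defaults.** The reference axis is 590–631 Da at 10 mDa bins
(4100 bins) and cores have radius 1 (5 pixels), with the study-patterned
core counts (Acin 20, AdCy 24, Anos 8, Control 6, MuEp 16, SaDu 4, Sec 3,
plus 6 matrix spots — 87 cores, ~435 pixels). These sizes were chosen so a
full 5-fold cross-validation of the default CNN completes in a few minutes
on one CPU core while every stage (binning, windowed filtering, pooling
arithmetic) is still exercised at realistic resolution; axis, radius and
counts are all configurable. The acquisition-scale axis (590–2000 Da at
sub-mDa bins) is supported by the data model but is not a sensible default
for a numpy training loop.

**What the generator does not emulate** — and hence what passing tests do
not show about real tissue: peptide mass distributions and isotope
envelopes, adducts, resolution varying with m/z, spatial gradients within
cores, biological heterogeneity within a class, and batch effects. Class
separability is planted by construction, so classifier accuracies here
validate the pipeline mechanics, not clinical performance.

## Preprocessing

Order: rebin → off-tissue masking → matrix filter → per-pixel min-max
normalization. Normalizing last guarantees the CNN's [0, 1] input contract;
correlations for the matrix filter are computed on pre-normalization
intensities, where co-variation is meaningful. No baseline removal or
global normalization is performed.

* **Re-binning** adds each raw point to the bin containing its m/z
  (half-open intervals); in-range total intensity is conserved exactly
  (float64, relative 1e-9).
* **Off-tissue masking** drops in-core pixels outside the tissue mask,
  except pixels of the dedicated matrix class, which are tissue-free by
  definition and retained.
* **Matrix filter**: peaks are strict local maxima of the dataset-mean
  spectrum above `median + 3·MAD` of that spectrum (deterministic and
  scale-free); the reference is the detected peak of highest mean intensity
  over matrix-class pixels (global fallback when no matrix class exists);
  each peak's apex-bin intensity is Pearson-correlated with the reference's
  across pixels; the top 500 peaks (reference always included) are zeroed
  within ±0.02 Da in every pixel.
* **Min-max normalization** maps each pixel to [0, 1]; constant spectra map
  to all-zeros (not NaN) so tensors stay finite. Idempotent.

## Classifier

Architecture: six blocks of [same-padding conv (kernel 9) → leaky ReLU
(slope 0.01) → max-pool 4], channels (8, 16, 32, 64, 128, 128), then one
fully connected layer to raw class scores. Depth and layer types are the
study design; channel/kernel/pool sizes are free hyperparameters exposed in
`ArchConfig`. Training minimizes softmax cross-entropy with Adam at
learning rate 0.001, 30 epochs, batch 64, no early stopping — a fixed,
deterministic budget. The net is implemented directly in numpy (im2col +
BLAS matmuls, float32), which also gives the attribution stage direct
access to every layer.

Cross-validation is pixel-stratified: within each class, pixels are
shuffled (seeded) and dealt round-robin into k = 5 folds, so per-class fold
sizes differ by at most one and every pixel is predicted exactly once by a
model that never trained on it. Pixels of one core may span training and
test folds under this protocol; `split_by="core"` provides the leakage-safe
variant (whole cores dealt per class) for users who want it. Per-class
accuracy is computed per fold and averaged over folds; a class absent from
the predictions is reported as undefined rather than 0. Class imbalance
(280 AdCy pixels vs 15 Sec at the defaults) is left unweighted.

Determinism: all seeds fixed → run-to-run reproducibility on one platform
(BLAS reduction order may differ across platforms).

## DeepLift

Contributions are propagated backward as multipliers against a reference
spectrum (default: all zeros — the natural "no ion signal" state after
min-max normalization):

* conv/dense layers: multipliers propagate through the weights (biases
  cancel in differences-from-reference);
* leaky ReLU: rescale rule `m·Δy/Δx`, falling back to the pointwise
  derivative where `|Δx| < 1e-7`;
* max pooling: the multiplier is routed to the argmax position of the
  actual input, scaled by `Δy/Δx` at that position; if that Δx is
  degenerate (< 1e-7) the multiplier is rerouted to the window position of
  largest |Δx|. This keeps summation-to-delta — contributions sum to
  `score(x) − score(reference)` — exact up to epsilon for any reference,
  not just a constant one.

Attribution runs in float64. For class-level masses, contributions are
averaged over the correctly classified held-out pixels of each class, each
pixel attributed through the model of its own fold (restricting to correct
pixels avoids contaminating the average with confused spectra; per-pixel
averaging rather than attributing a class-mean spectrum keeps the
computation aligned with what the model actually classified). The top 10
positive-contribution bins per class, reported as bin-center m/z, form the
per-class mass lists; ties break toward lower m/z.

## Mass dedup and embedding

Pooled top-10 lists (80 entries for 8 classes) are chained into groups of
masses equal within one bin width; groups touched by more than one class
are flagged as artifacts (shared signal cannot be subtype-specific) and
excluded, mirroring the duplicate-filtering step of the underlying study
design. The remaining class-unique masses are the feature set for a
supervised densMAP embedding (umap-learn, `densmap=True`, categorical
label supervision with `target_weight` default 0.5, seeded via
`random_state`). The embedding contract is checked with silhouette-based
tests rather than exact coordinates, since the projection is delegated to
umap-learn. Exports: TSV and a self-contained interactive HTML scatter
(hover shows the core).

## Reporting

* Classification maps: green = correct, red = misclassified, black =
  unimaged, on the pixel grid.
* Core majority vote: modal predicted label per core; ties break by higher
  mean raw score, then lexicographic class order (deterministic); a core's
  vote is correct when it matches the annotation. When every core's own
  pixel accuracy exceeds 50%, majority voting classifies 100% of cores
  correctly (majority amplification).
* Ion images: per pixel, the sum over bins intersecting `mz ± window`
  (default ±3 mDa), rendered with per-image max scaling; raw window sums
  are exported alongside so quantitative checks never depend on rendering.

## Numerical choices and degenerate inputs

* Constant spectra normalize to zeros; constant peak columns get
  correlation −inf (never selected); a constant reference bin raises a
  degenerate-correlation error.
* Peak apexes are kept ≥ 0.3 bins away from bin edges in the generator so
  apex bins are strict local maxima.
* The rescale epsilon is 1e-7 on Δinput; summation-to-delta holds to
  < 1e-4 relative on random networks (tested).
* Max-pool truncates a trailing remainder (length % pool); multipliers and
  gradients for truncated positions are zero.
* Empty datasets, empty masks, unannotated cores, duplicate coordinates and
  conflicting labels are rejected with named validation errors.

## Known limitations

* Training is CPU-bound numpy; acquisition-scale axes (hundreds of
  thousands of bins) are impractical to train on, though I/O and
  preprocessing handle them.
* The generator's class separability is planted; accuracy numbers on
  synthetic data are mechanics checks, not performance claims.
* Protein identification from discriminative masses, negative-predictive
  masses, and architecture search are out of scope.
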