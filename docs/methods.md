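# Methods

`overprint` implements an unsupervised workflow for hyperspectral ToF-SIMS
images acquired in the extreme low-dose regime, where a macroraster of tens of
millions of pixels carries so few secondary-ion counts that a single pixel's
spectrum is a near-binary "barcode" (per-peak counts of 0 or 1, per-pixel
total ion counts well under 100). The motivating application is chemical
imaging of two partially overlapping latent fingermarks on a substrate:
separating the two marks, the substrate, and the zone where the marks cross,
and — because ToF-SIMS probes only the top monolayers — inferring which mark
was deposited last.

## The bin–train–backfit model

Per-pixel spectra are too sparse to cluster directly, and summing counts over
B × B pixel blocks ("binning") buys signal at the price of an B-fold loss of
lateral resolution. The workflow keeps both:

1. **Bin**: sum the K-channel count cube over B × B neighborhoods
   (default B = 14). Sums, not means — counting statistics are preserved.
2. **Train**: fit a *parametric* UMAP on the binned pixel-by-peak matrix.
   A k-nearest-neighbor fuzzy graph is built on the binned rows
   (k = 15, Euclidean metric on raw counts): directed weights
   w(i→j) = exp(−max(0, d_ij − ρ_i)/σ_i) with ρ_i the distance to the nearest
   neighbor and σ_i solved by bisection so the weights sum to log2(k)
   (residual < 1e−5), then symmetrized by the probabilistic union
   w_ij + w_ji − w_ij·w_ji. The low-dimensional layout is produced by a
   multilayer perceptron (two hidden ReLU layers of 128 units, linear head)
   trained with Adam (learning rate 1e−3, 50 epochs) to minimize the fuzzy
   cross-entropy between graph weights and embedded similarities
   1/(1 + a·d^{2b}), with 5 uniform negative samples per positive edge and
   per-coordinate gradient clipping at ±4. (a, b) come from the standard
   least-squares fit of the similarity curve to the min_dist = 0.1 kernel.
3. **Backfit**: because the layout is a trained function, it is applied
   row-wise to the *unbinned* matrix — no re-optimization — restoring
   full lateral resolution. The encoder is pure: identical rows map to
   identical coordinates across calls, processes, and serialization
   round-trips.

Pixels are embedded in 3-D (so the axes can be percentile-scaled to RGB for
similarity maps); the transposed matrix (peaks as rows) is embedded in 2-D
for the mass domain.

### Dose augmentation (why plain backfitting is not enough)

A binned row has roughly B²-fold larger norm than the unbinned rows the
encoder must later embed. An MLP trained only at the binned scale is
essentially unconstrained near the origin, and in our experiments the
backfitted full-resolution embedding collapsed most of the class structure
(nearest-centroid accuracy against ground truth fell from 0.99 achievable on
raw counts to 0.89 in the backfit space, and pipeline ARI to 0.24). Per-pixel
TIC normalization did not repair this — normalized single-pixel barcodes are
extremely noisy directions.

The package therefore trains the encoder with *Binomial count-thinning
("dose") augmentation*: every count vector fed to the network during
optimization is first thinned, each ion kept independently with probability
u drawn log-uniformly from [u_min, 1], with u_min = 1/B² in the pipeline.
Thinning a Poisson/Bernoulli count spectrum is statistically exactly a
lower-fluence acquisition of the same surface chemistry, so the augmentation
teaches the encoder the invariance the backfit step *assumes*: that a pixel
and the binned block containing it express the same chemistry at different
doses. The fuzzy graph itself is still built on the raw binned rows. With
augmentation the phantom pipeline reaches ARI ≈ 0.985 at full resolution.
`dose_augment` is exposed on the estimator (`None` disables it; it then
behaves as a plain parametric UMAP).

## Clustering

* **Pixel domain**: Ward agglomerative clustering on a seeded uniform
  subsample (default 8 000 pixels; full pairwise Ward on tens of millions of
  pixels is infeasible), followed by nearest-centroid assignment of every
  pixel — the label map always has full coverage. The cluster number is
  either fixed or selected in [2, 8] by the maximum mean silhouette over the
  subsample. The choice of Ward + silhouette is a reproducibility decision:
  the visual identification of clusters in an RGB map is replaced by an
  explicit, testable rule.
* **Mass domain**: HDBSCAN (scikit-learn implementation) on the 2-D embedded
  peaks, `min_cluster_size` = 5. Channels in no dense region keep the noise
  label −1 and render gray; a fixed-k hierarchical cut could not produce such
  unclustered points, which are part of the intended output semantics. On the
  default phantom the transposed pipeline separates the channel groups that
  share a rate profile (substrate, each print's exclusive channels, shared
  print channels, overlap-mix, background) essentially perfectly (ARI > 0.9
  against the signature-column grouping, computed in the test suite).

**Known limitation — the overlap cluster and automatic k.** On the default
phantom the full pipeline separates substrate and the two prints essentially
perfectly (ARI ≈ 0.985), but the silhouette rule selects k = 3, merging the
overlap class (≈ 1.8 % of pixels whose signature is 80 % that of the top
print) into the top print's cluster: even an ideal four-way partition of the
embedded subsample scores a lower mean silhouette (≈ 0.73) than the Ward
three-way cut (≈ 0.78). Mean silhouette is known to under-reward carving a
small adjacent cluster out of a dominant one. Forcing `k_clusters=4`
reproduces the four-class structure; the automatic rule is deliberately left
as specified rather than special-cased. The deposition-sequence verdict is
unaffected (see below).

## Cluster spectra and the deposition sequence

A cluster's characteristic spectrum is the membership-weighted sum of the
*unbinned* counts. Hard {0,1} memberships (the default; the clustering is
hard) make the per-cluster spectra an exact integer partition of the total
spectrum — an identity the tests assert. Soft memberships via a softmax over
negative squared centroid distances (temperature 1.0) are available.

The deposition order of two overlapping marks is decided from surface
chemistry: in the overlap zone the detected signal is dominated by the mark
deposited last. `sequence_verdict` reports the print whose cluster covers
the larger fraction of the overlap zone, with an explicit margin
(default 0.1) below which the verdict is *indeterminate* — "unequivocal" is
replaced by a falsifiable statistic. On phantoms the overlap zone comes from
ground truth; on real data it is approximated by intersecting the two print
clusters' masks after morphological dilation (radius 2 px), since interleaved
ridges barely intersect pixel-wise. Whether an overlap-specific cluster
should count toward either print is ambiguous; only the two print clusters
are counted and the residual fraction is reported implicitly as
1 − coverage_A − coverage_B.

## The synthetic phantom

No public raw data exist for this kind of acquisition, so every quantitative
test runs on a synthetic scene with analytic ground truth:

* **Geometry**: two axis-aligned ellipses (the marks) on a 504 × 504 raster
  (divisible by 4, 14, and 56), each filled with a sinusoidal ridge grating
  (period 16 px, duty cycle 0.5, different orientations). Labels: substrate,
  print A, print B, overlap (= both gratings on). Ridges are deliberately
  *not* biometrically realistic — ground truth must be analytic, and
  minutiae are irrelevant to the statistics being tested.
* **Counts**: K = 64 channels; per-pixel, per-channel counts drawn
  Bernoulli(rate) (Poisson mode available). Rates per class: 10 substrate
  channels at 0.35; 14 exclusive channels per print at 0.45 plus 6 channels
  shared by both prints at 0.45 (prints of different people share common
  sebum/eccrine chemistry); substrate show-through under the prints at 0.05;
  a 0.02 background everywhere. Expected per-pixel TIC ≈ 5–10, maximum
  observed ≈ 22 — comfortably inside the ≤ 100 regime, with the binary
  "barcode" property holding exactly in Bernoulli mode.
* **Occlusion**: the overlap signature is
  α·signature(top) + (1−α)·signature(bottom) + mixing component, α = 0.8
  (surface sensitivity: the top mark dominates but does not fully mask the
  bottom one; no quantitative occlusion depth is available in the literature,
  so α is a modeling choice, exposed as a parameter). The mixing component
  (4 channels at 0.30) models chemistry specific to the doubly-deposited
  zone. Clipping to [0, 1] is applied after combination.
* **Determinism**: identical (config, seed) produce byte-identical cube
  files; all sampling uses one PCG64 generator.

What the phantom does *not* emulate: detector dead time and saturation, mass
calibration drift, macroraster stitching seams, topography/matrix effects,
and realistic ridge patterns. Passing tests therefore demonstrate the
statistical machinery — graph construction, dose-invariant encoding,
backfit resolution recovery, conservation identities, order inference under
occlusion — not instrument-specific artifacts.

## Problem sizes and numerical choices

Tests and the worked examples run the full pipeline on the 504 × 504, K = 64
phantom (254 016 pixels; 1 296 training rows after 14 × 14 binning), a
desk-scale stand-in preserving the count statistics of the published
49-Mpixel regime; the code paths themselves stream row-blocks and subsample
where the full-scale data would not fit in memory (dense-matrix budget,
centroid assignment in 2^18-row blocks, Ward on a subsample). Exact k-NN is
used throughout — after binning, training sets are at most a few tens of
thousands of rows. Other numerical details: bandwidth bisection runs 64
iterations with a small floor (1e−3 of the mean neighbor distance) for
degenerate neighborhoods of coincident points; embedding distances are
floored at 1e−12 and the repulsive gradient denominator offset by 0.001;
training aborts on a non-finite epoch loss. Binning level is sample-dependent
and left to the user; the `sweep` command scores a factor list against
phantom truth (class recovery degrades at both extremes: too little binning
starves the graph of statistics, too much destroys the discriminative
information — on the default phantom ARI falls from ≈ 0.985 at B = 14 to
≈ 0.2–0.9 at B = 56, while B = 4 sits just below B = 14).
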