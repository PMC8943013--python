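# Methods

This note documents the models, transforms, and metrics implemented in
`mevae`, the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Nuisance model and canonicalization

Three uninformative transformations are controlled: in-plane **rotation**,
**polar orientation** (the direction from the cell's geometric centroid to
its intensity center of mass), and **size/shape**. Each has a
canonicalizer and a randomizer that are mutually inverse up to
interpolation error.

* *Rotation.* The mask's second central moment matrix is diagonalized and
  the image is rotated about the mask centroid until the leading
  eigenvector (major axis) is horizontal. The major axis only defines an
  orientation mod 180°, so the reported correction lives in [0°, 180°).
  The residual two-fold ambiguity is resolved — when the intensity center
  of mass is informative — by a further 180° rotation that places the
  center of mass in the +x half-plane; this makes
  randomize-then-canonicalize an identity for polarized cells and leaves a
  flagged ambiguity for radially symmetric ones. Masks with a moment
  eigenvalue ratio below 1.05 are flagged unstable.
* *Polarity.* The image is rotated so the centroid-to-center-of-mass angle
  becomes the fixed canonical direction 0° (+x). The canonical direction
  is an arbitrary but fixed convention; any other angle would be
  equivalent. If the center of mass lies within 0.5 px of the centroid the
  polarity is undefined and the image is returned unchanged with a
  degeneracy flag.
* *Size/shape (circle registration).* Assuming star-convexity from the
  centroid, the boundary radius R(θ) is estimated on a 720-point angular
  grid by ray marching at 0.25-px steps with sub-pixel refinement of the
  0.5-crossing of the bilinearly interpolated mask; non-star-convex masks
  use the outermost crossing per ray. The output pixel at polar coordinate
  (θ, r) samples the input at radius r·R(θ)/R_target. Intensities are
  sampled with mask-renormalized bilinear interpolation (weights of
  out-of-mask neighbors are dropped), which prevents the zero background
  from diluting boundary pixels. Ray resampling does not preserve total
  intensity, and no mass renormalization is applied.

Canonicalization order is fixed: rotation → polarity → circle
registration, and the order is recorded with each paired sample. When
polarity is corrected together with rotation, the polarity rotation is
applied after axis alignment; the axis is then generally no longer
horizontal, which is immaterial whenever circle registration follows (the
shape is mapped to a disc regardless) and is the price of treating the two
corrections as independent encoders.

Coordinate convention throughout: row-major images with the origin at the
top-left; geometry in a y-up mathematical frame (+x right, +y up, angles
counter-clockwise from +x). Interpolation is bilinear for intensities and
nearest-neighbor for masks; background fill is exactly 0. Percentile
normalization (histogram stretch to the 1st/99th percentiles over masked
pixels, per cell or dataset-wide) uses linear-interpolation quantiles.

## Model variants and losses

All encoders and decoders are three fully-connected ReLU layers (default
widths 256/128/64 toward the code), with affine μ and log σ² heads on the
encoder and a sigmoid output layer on the decoder. Dense blocks were
chosen over convolutions because the implementation is pure numpy with
hand-written gradients and runs on one CPU; the block internals are not
otherwise constrained by the method, and the loss arithmetic — the part
that defines each variant — is independent of this choice.

Losses are implemented in minimized form, reconstruction **plus** weighted
KL (the ELBO-maximization sign convention would drive posterior variances
to infinity if minimized literally). Binary cross-entropy is summed over
pixels and averaged over the batch; KL divergences are summed over latent
dimensions and averaged over the batch; the global KL weight defaults
to 1.

* standard VAE: `BCE(x, x̂) + KL(q(z|x) ‖ N(0,I))` on matched raw pairs;
* output-corrected VAE: same arithmetic with a randomly transformed input
  and the canonical target (the pairing is asserted via sample
  provenance);
* ME-VAE: `BCE(x′, p(z_all)) + (1/n) Σᵢ KLᵢ`, with z_all the element-wise
  product of the per-encoder codes;
* β-VAE: `BCE + β·KL`, β default 4 (exposed; the parameter is known to be
  hard to tune and comparisons are qualitative);
* invariant conditional VAE: `(1+λ)·BCE + KL(q‖prior) + λ·M`, where the
  intractable marginal term KL(q(z|x) ‖ q(z)) is approximated by the mean
  pairwise closed-form Gaussian KL between the sample's posterior and
  every other posterior in the batch, and the nuisance vector c (sin/cos
  of rotation and polarity plus z-scored area) is concatenated onto the
  decoder input; λ defaults to 1;
* denoising AE / ME-DAE: reconstruction term only, deterministic latent
  (z = μ).

During training the multiplicative fusion acts on sampled codes (each
encoder keeps its own reparameterization so each KL term stays
meaningful); at encode time the embedding is deterministic — posterior
means, fused by product for the multi-encoder variants. Because the
trained encoders are (approximately) invariant to their nuisance, the
choice of input view at encode time should not matter; each encoder
receives a cell-id-seeded random transform of the canonical image, which
keeps encoding deterministic, and the decorrelation benchmark verifies the
premise.

Numerical safety: reconstructions are clamped to [1e-7, 1−1e-7] before the
log, log-variances to [−10, 10] (gradient masked outside), and the KL uses
`expm1(logvar) − logvar` to avoid cancellation near the prior. Optimizer:
Adam, learning rate 1e-3, batch 64 (exposed in the model spec). A
non-finite loss aborts training naming the offending term.

## Synthetic benchmarks

The generator renders elliptical cells (well-defined major axis for
rotation ground truth) with sampled rotation, polarity, and axes; a
polarized Gaussian hotspot carrying a configurable fraction of total
intensity; and one of four staining patterns: uniform, linear radial
gradient, a 2.5-px membrane ring, or a perinuclear pattern (dim central
nucleus disc, diffuse cloud, bright blob just outside the nucleus toward
the polarity direction). After rendering, intensities are rescaled —
iteratively under the [0, 1] clip — so every cell's whole-cell mean hits
the target (0.45 by default); the radial-linear pattern is shifted
additively instead so its planted slope survives exactly. Optional
Gaussian pixel noise (sd 0.02 by default) is added inside the mask.

Two standard study sets are built in:

* the **two-population benchmark** (membrane-ring vs. perinuclear-diffuse,
  matched on whole-cell mean intensity and on the size distribution) —
  population means differ by well under 0.25 pooled sd on both statistics
  and a linear classifier on (mean intensity, area) stays near chance;
* the **rotation benchmark**, a single population whose hotspot is locked
  to the cell frame so that each image is, up to small size jitter and
  noise, a pure rotation of one base cell: rotation is the single
  governing feature and is fully identifiable from the image (with a free
  hotspot the mask only identifies the angle mod 180°, making
  angle-leakage measurements ill-posed for every model).

The recorded polarity ground truth is the planted hotspot direction; for
hotspots clipped by the mask boundary the realized center-of-mass
direction can deviate by a few degrees, so polarity truth is treated as
approximate while the center-of-mass angle itself is exact.

What the benchmarks do **not** emulate: real stain texture, imaging noise
statistics, segmentation errors, multi-channel marker panels at scale, or
non-star-convex cell shapes. Passing these tests shows the architecture
removes controlled geometric nuisances and recovers planted subcellular
localization differences; it does not by itself establish performance on
real multiplexed imaging data.

## Metrics and aggregation

* **Cluster purity**: per k-means cluster, the modal-label fraction;
  reported as unweighted mean ± sd over clusters (the sd is over clusters,
  consistent with the per-cluster definition; empty clusters are excluded
  with a warning). k-means uses k-means++ with 10 restarts and a fixed
  seed; k = 2 for the two-population analysis (k is a flag).
* **NMI**: I(L;C)/√(H(L)·H(C)) with natural-log entropies; defined as 0
  for single-class partitions.
* **Nuisance leakage**: max over latent columns of |Spearman ρ| against
  the nuisance series. Circular nuisances are correlated through their
  sin and cos components (rank correlation against a raw angle is
  discontinuous at the wrap-around); constant columns contribute 0.
* **Radial slope**: rings r = floor(distance) restricted to the disc of a
  circularized cell; OLS of ring means vs. ring index; the slope is the
  metric, the intercept is stored but ignored. Empty rings (possible on
  even-sized canvases whose center falls between pixels) are interpolated
  from neighbors with a warning. Compartment means use equal radial
  thirds (boundaries at R/3 and 2R/3 — the equal-thirds choice is a
  convention, exposed as such).
* **Separability**: one-way ANOVA F/p plus pairwise Tukey HSD p-values;
  effect size is the pairwise standardized mean difference with pooled sd.
* **Feature aggregation**: latent dimensions are standardized
  (population sd), hierarchically clustered (Euclidean distance, average
  linkage; method exposed) and cut at a user-chosen number of clusters
  (no automatic selection); a cell's aggregated score is the mean of the
  member features. The explanatory **feature score** is
  Var_all − mean over cell clusters of Var_within (population variances;
  cell clusters, i.e. groups of cells, not feature clusters — the
  variance decomposition reads most naturally across cell groups);
  singleton clusters contribute zero variance with a warning.
* **Pathway activity**: relative protein level = (x − column
  median)/column sd; the score sums sign·weight·relative level over a
  pathway's members. Cross-modal correlation pairs condition-mean
  aggregated features with pathway scores by condition and reports
  Spearman ρ; with ≤ 6 conditions the matrix is flagged descriptive.

## Problem sizes and reproducibility

The bundled benchmarks run at desk scale: 32×32 single-channel crops,
latent dimension 16, 5 epochs, 2 000 cells for the decorrelation study and
400 cells per population for the separability study, three seeds each —
sizes at which the qualitative contrasts are already decisive on one CPU.
Larger latent spaces (64 per the single-channel convention) and cell
counts are plain parameters. Every stochastic component draws from a
generator seeded by the single run seed, so the full pipeline, including
k-means and training, reproduces bit-for-bit; reports carry a hash of
their configuration.

## Known limitations

* Dense (not convolutional) blocks cap reconstruction fidelity on larger
  images; reconstruction-quality comparisons between variants are
  qualitative only.
* Circle registration assumes star-convexity from the centroid; strongly
  concave cells are resampled by their outermost boundary crossing.
* The membrane-ring pattern degenerates toward uniform in very small
  cells (minor axis ≲ band width), where a radial-slope sign is not
  meaningful.
* Whether multiplicative fusion should act on sampled codes or means
  during training is not externally fixed; product-of-samples is the
  default and product-of-means is what `encode` uses deterministically.
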