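# mevae

Transform-invariant feature extraction for single-cell microscopy images
with a **multi-encoder variational autoencoder (ME-VAE)**.

## The problem

Variational autoencoders are attractive for single-cell image phenotyping
because they learn representations without hand-crafted features. On
cropped single-cell images, however, a plain VAE spends its capacity on the
dominant *uninformative* transformations — in-plane rotation, polar
orientation (which side of the cell the stain points to), and cell
size/shape — and the latent space ends up encoding little else. Two
biologically distinct populations that differ only in subcellular staining
pattern then look identical to the embedding.

## The method

Each nuisance is a known, invertible image transformation, so it can be
turned into a self-supervision signal. For every cell we build a fully
canonicalized target image x′ (major axis rotated to horizontal, intensity
center of mass rotated to a fixed direction, mask warped onto a fixed disc
by per-angle ray remapping). Each of n parallel encoders receives its own
randomly re-transformed copy Tᵢ⁻¹(x′) of that target; their latent codes
zᵢ are fused by element-wise multiplication into z_all, and a single
decoder must reconstruct x′:

    L_ME-VAE = BCE(x′, p(z_all)) + (1/n) Σᵢ KL( qᵢ(zᵢ | Tᵢ⁻¹(x′)) ‖ N(0, I) )

Only information shared across all randomized views survives the product
fusion, so the embedding becomes invariant to the controlled nuisances.
The package also implements the comparison architectures — standard VAE,
output-corrected VAE, β-VAE (BCE + β·KL), invariant conditional VAE (with
nuisance values injected into the decoder and a marginal-posterior KL
penalty), and denoising autoencoders (single- and multi-encoder, BCE only)
— plus evaluation metrics (k-means cluster purity, normalized mutual
information, max |Spearman| nuisance leakage, radial slope and compartment
means of circularized cells, ANOVA/Tukey separability), hierarchical
feature aggregation, signed pathway activity scoring, and cross-modality
Spearman correlation.

Everything is exercisable end-to-end on a built-in synthetic generator:
elliptical cells with known rotation/polarity/size, and two populations
(membrane-ring vs. perinuclear-diffuse staining) deliberately matched on
cell size and whole-cell mean intensity so that naive features cannot
separate them. All networks are implemented in numpy (dense three-layer
ReLU blocks with hand-written gradients and Adam), so the package runs on a
plain CPU with no deep-learning framework.

## Worked example

Train the ME-VAE (rotation + polarity + size/shape corrections) on the
matched two-population benchmark and evaluate the embedding:

```python
from mevae import (ModelSpec, generate_two_population_benchmark, make_paired_dataset,
                   train, encode, kmeans_embed, cluster_purity,
                   normalized_mutual_information, max_nuisance_correlation)
from mevae import normalize_records

corrections = ("rotation", "polarity", "size_shape")
cells = normalize_records(generate_two_population_benchmark(400, seed=0))
labels = [c.label for c in cells]

spec = ModelSpec(variant="me_vae", latent_dim=16,
                 input_shape=cells[0].image.shape, corrections=corrections)
model = train(spec, make_paired_dataset(cells, corrections, seed=1), epochs=5, seed=2)
embedding = encode(model, cells)

clusters = kmeans_embed(embedding, k=2, seed=0)
purity, sd, _ = cluster_purity(labels, clusters, k=2)
print(f"mean cluster purity: {purity:.3f} (sd {sd:.3f})")
print(f"NMI:                 {normalized_mutual_information(labels, clusters):.3f}")
rot = embedding.nuisance["rotation_deg"]
print(f"max |Spearman| with rotation: {max_nuisance_correlation(embedding, rot, circular=True):.3f}")
```

Output (about half a minute on one CPU):

```
mean cluster purity: 0.989 (sd 0.006)
NMI:                 0.914
max |Spearman| with rotation: 0.076
```

The two populations — indistinguishable by mean intensity and area by
construction — are separated almost perfectly (purity 0.99), and the
embedding has essentially no rotation leakage (max |Spearman| 0.08; a
standard VAE trained on the same raw images typically leaks rotation at
0.9+ and reaches purity around 0.86). A command-line surface wraps the same
pipeline: `mevae simulate`, `preprocess`, `train`, `encode`, `evaluate`,
`aggregate`, `pathways`, `crossmodal`, and `mevae run` for the end-to-end
benchmark.

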