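# Methods

## Model

`deepclust` implements the two-phase deep embedded clustering procedure.

**Phase 1 — representation learning.** A backbone autoencoder learns
f<sub>θ</sub>: X → Z by minimizing a reconstruction objective. The five
families share one convention set:

- *dense*: symmetric MLP; ReLU in hidden layers, linear bottleneck and
  linear output layer (the convention greedy layer-wise pretraining
  assumes: in each encoder/decoder pair both activations are ReLU except
  the first pair's decoder and the last pair's encoder).
- *stacked_denoising*: the same architecture initialized by greedy
  layer-wise training. Each pair is trained as a two-layer denoising
  autoencoder on the clean output of the previously trained stack: the
  pair input and the hidden code are corrupted by dropout masking and
  the pair is scored by least squares against the clean input. After all
  pairs, the concatenated deep autoencoder (encoder order, then reversed
  decoder order) is fine-tuned end-to-end on clean inputs.
- *convolutional*: per stage Conv(ReLU) + 2×2 max-pooling, a linear
  dense map to the latent code, and a mirrored decoder with
  nearest-neighbour upsampling ending in a sigmoid convolution so image
  reconstructions stay in [0, 1]. Stride-1 same-padding convolutions
  with odd kernels; input sizes must be divisible by the pooling
  schedule.
- *variational*: a dense trunk with linear mean and log-variance heads
  defining a diagonal-Gaussian posterior; training minimizes the
  negative ELBO = squared-error reconstruction of a reparameterized
  sample + KL(q(z|x) ‖ N(0, I)) in closed form. `encode` returns the
  posterior mean so clustering sees a deterministic embedding; sampling
  happens only during training.
- *recurrent*: an encoder LSTM consumes a variable-length sequence of
  real vectors; its final hidden state, linearly projected, is the
  fixed-length representation. The decoder LSTM is seeded from that code
  and, with teacher forcing, predicts the sequence in reverse input
  order; the loss sums squared errors over sequences and time steps.

Loss reductions: squared-error objectives sum over features and average
over the batch; the sequence objective is a plain sum (recorded in each
`ReconstructionReport`). The denoising objective encodes the *corrupted*
input and scores against the *clean* target — the standard denoising
convention. Dropout corruption is pure masking: surviving coordinates
are not rescaled, since corruption (not inverted-dropout inference) is
what the formulation describes.

**Phase 2 — cluster-assignment hardening.** Centroids are initialized on
the encoded training samples by k-means (default; `n_init=10`),
Ward-linkage agglomerative clustering (group means) or a
full-covariance Gaussian mixture (component means). Soft assignments use
the Student's-t kernel with α = 1 (fixed; cross-validating α is not
viable unsupervised, and learning it adds nothing — it remains
configurable). The auxiliary target squares the assignments and
normalizes by soft cluster frequency, emphasizing confident points. The
hardening loss KL(P‖Q) uses natural logarithms with 0·log(0/q) = 0.

Each optimizer step is full batch: the analytic gradients

∂L/∂z<sub>i</sub> = ((α+1)/α) Σ<sub>j</sub> (1 + ‖z<sub>i</sub>−μ<sub>j</sub>‖²/α)⁻¹ (p<sub>ij</sub>−q<sub>ij</sub>)(z<sub>i</sub>−μ<sub>j</sub>),
∂L/∂μ<sub>j</sub> = −((α+1)/α) Σ<sub>i</sub> (same factor)

are injected into the encoder's backward pass (scaled by 1/n so the
clustering and reconstruction terms share the mean-over-batch scale) and
the centroids move under the same Adam optimizer. The target P is
refreshed every `update_interval` steps; the run stops once fewer than
`tol` percent of training samples change hard assignment between
refreshes, or at `max_iters`. If a centroid loses all its hard
assignments it is re-seeded at the least confidently assigned sample, so
K stays fixed. The loss history records L_AE, L_KLD (per-sample mean so
the two are comparable), the combined loss and the percentage of changed
assignments at every refresh.

**σ schedule.** The default is the hard schedule: σ = 0 during
pretraining (reconstruction only), σ = 1 afterwards (pure clustering
loss). A constant 0 < σ < 1 keeps joint training; both are selectable
via `TrainConfig.sigma`. The combined loss is the plain convex
combination σ·L_KLD + (1−σ)·L_AE. With σ = 0 the centroids receive no
gradient at all (verified by test).

**Pipeline mode.** DBSCAN and OPTICS define no centroids and hence no
joint update; they cluster the extracted latent features directly
(`pipeline_cluster`), with noise labelled −1. OPTICS defaults to xi
extraction; agglomerative defaults to Ward on Euclidean distances; GMM
to full covariance. All are configurable — the choices are unstated in
the source formulation and follow the scikit-learn defaults a
practitioner would use.

## Metrics

All label metrics are computed from the contingency table with natural
logarithms. NMI normalizes mutual information by the arithmetic mean of
the two label entropies; ACC maximizes the match fraction over
one-to-one cluster/class mappings via the Hungarian algorithm on the
square-padded negated contingency table; RI counts correct pairwise
decisions over all n(n−1)/2 pairs; ARI applies the fixed-marginal
permutation-model correction. Homogeneity = 1 − H(y|c)/H(y) and
completeness = 1 − H(c|y)/H(c). Conventions for degenerate inputs: NMI
and ARI are 1.0 when both partitions are trivial (zero denominators);
homogeneity/completeness are 1.0 when their reference entropy is zero.
Noise labels (−1) from density-based algorithms are treated as singleton
clusters by default, or excluded with `noise="exclude"` — the choice is
exposed because no single treatment is canonical.

Elbow selection takes the K maximizing the discrete second difference of
WCSS over a contiguous K range, ties toward smaller K. G is the ratio of
train to validation per-sample combined loss on a seeded 90/10 split;
values well below 1 indicate overfitting.

In `sweep_k`, the WCSS column is computed on the *shared* pretrained
embedding with per-run label means as centroids, so the curve is
comparable across K (each joint run re-shapes its own latent space, so
per-run WCSS values would not share a scale); NMI and G come from the
per-K fitted runs.

## Preprocessing

Expression matrices are transformed entry-wise by log2(FPKM + 1)
(proportional rather than additive changes), then genes with low
information burden are removed: post-log mean < 0.4 **or** sample
standard deviation (ddof = 1) < 0.75 across samples, both configurable.
The filter runs *after* the log transform; the ordering is an
interpretation (the source is silent) and is exposed by the API
boundary. Star ratings collapse to polarity: ≤ 4 negative, 5–7 neutral,
≥ 8 positive. Images are resized with anti-aliased interpolation,
channels last, top-left origin, clipped to [0, 1]. Token sequences are
embedded with a randomly initialized trainable table (id 0 reserved for
padding); a hook loads user-supplied vectors in word2vec text format —
no external corpus is downloaded. The per-sample statistic
(1/d)‖z‖² is provided as a diagnostic for the ≈ 1 normalization that
embedded-clustering initialization expects; it measures and does not
transform.

## Synthetic data

The generators plant class structure in disjoint feature blocks so
ground truth is unambiguous:

- *blobs*: K isotropic Gaussian components in a latent space with
  pairwise centroid distance ≥ separation·noise_sd, lifted to the
  ambient dimension by a fixed random linear map plus a leaky-ReLU
  nonlinearity (injective, so separability is preserved). The latent
  coordinates and map are recorded for oracle checks. The standard
  recovery fixture is 3 × 200 samples, 2-D latent, 50-D ambient,
  separation 8, unit noise.
- *expression*: log-normal baseline (post-log mean 2, SD 1.2 — passes
  the filter comfortably); each subtype up-regulates its own disjoint
  signature block by 5 doublings; exactly `n_low_info` genes are
  constructed to fail the filter (half by low post-log mean, half by
  near-zero SD), with indices recorded.
- *images*: class-specific base intensity plus oriented sinusoidal
  stripes and mild pixel noise; the realized between-class mean
  intensity margin is recorded. Default 64×64 rather than full
  microscopy resolution — the clustering mechanics are identical at
  desk scale.
- *text*: three polarity classes drawing 90% of tokens from disjoint
  vocabulary blocks (the rest from a shared block); ratings are sampled
  inside each class's range so the polarity thresholds reproduce the
  labels exactly; lengths vary uniformly in [max_length/2, max_length].

What these fixtures do **not** emulate: negative-binomial count noise
and library-size effects in RNA-seq, stain/appearance variation in
histology, and natural-language statistics. Passing recovery tests shows
the machinery finds planted separable structure; it does not certify
performance on real data, where separability itself is the open
question.

## Numerical choices

- All computation is float64 on a package-local reverse-mode autodiff
  engine; every primitive and layer is gradient-checked against central
  finite differences (tolerance 1e−5 relative or better), as are the
  analytic hardening gradients.
- Adam with lr 1e−3, β = (0.9, 0.999), batch 32 for reconstruction
  training; full-batch steps in the hardening phase. Glorot-uniform
  initialization from a per-model seeded generator; bit-reproducible per
  seed.
- Defaults: α = 1, tol = 0.1% (the usual convention for the stopping
  rule), update_interval = 140 steps, σ hard schedule.
- Max-pooling routes gradients to the first maximum in each block
  (deterministic tie-break). Padded sequence positions use reserved id
  0 with zeroed embedding.
- Checkpoints are a single `.npz` with parameters plus embedded JSON
  spec.

## Problem sizes

The test suite and the acceptance script run the recovery experiments at
n = 600 samples (3 × 200), 50 ambient dimensions, a [50, 32, 5] dense
encoder, 30 pretraining epochs and ≤ 1400 hardening steps; the metric
oracles are exhaustive over all partition pairs of up to 6 items in ≤ 3
blocks plus 200 random larger instances; gradient checks use 50 random
instances with n ≤ 8, K ≤ 3, d ≤ 4. These sizes make the whole suite
run in well under a minute while leaving the conclusions unchanged at
larger n (the procedures are n-independent).

## Known limitations

- The hardening loop is full-batch; mini-batch hardening (as used on
  very large corpora) would need per-batch row alignment of P and is not
  implemented.
- The convolutional and recurrent backbones are desk-scale: pure-numpy
  convolutions and per-sequence LSTM loops are not competitive with GPU
  frameworks on large images or corpora, though they are numerically
  exact and fully tested.
- Batch normalization uses running statistics at encode time; training
  very deep stacks may still need per-layer tuning beyond the presets.
- K is fixed during a run (empty clusters are re-seeded); selecting K is
  delegated to the Elbow/NMI sweep.
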