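# Methods

## The model

Each single-cell frame is a square patch `x ∈ [0,1]^{p×p}` from one
fluorescence channel. The encoder maps it to a diagonal-Gaussian posterior
`q(z|x) = N(mu, diag(exp(logvar)))` in a `d`-dimensional latent space
(default `d = 16`); the generator decodes a latent point back to a patch
through a sigmoid, so the [0,1] pixel contract holds by construction; the
discriminator scores realness and exposes its fourth-layer feature maps
`F(x)`. The per-image objective combines

* pixel reconstruction `‖x − G(z)‖²` (mean over pixels),
* learned similarity `λ_feat · ‖F(x) − F(G(z))‖²` (mean over features),
* `w_kl · KL(q(z|x) ‖ N(0, I)) / d` — the closed form
  `0.5 Σ_d (mu_d² + e^{logvar_d} − logvar_d − 1)`, normalised per latent
  dimension so that the annealing weights are scale-free,
* non-saturating adversarial terms
  (`−log D(G(z))` for the generator, `−log D(x) − log(1 − D(G(z)))` for the
  discriminator), weighted by `adv_weight`.

Architecture: stride-2 4×4 convolutions with batch normalisation and
leaky-ReLU, channel widths (32, 64, 128) for the encoder (mirrored in the
generator), (32, 64, 128, 256) plus a final k×k realness convolution for
the discriminator — standard DCGAN-scale choices for 64×64 patches. Patch
sizes must be multiples of 16 (four stride-2 halvings in the
discriminator).

Everything runs on a small reverse-mode autodiff tape over NumPy arrays
(`cyclemap._autodiff`), written for exactly this workload: the dependency
footprint stays scientific-Python-only, checkpoints are plain `.npz`
arrays, and every forward pass is bit-reproducible. Convolutions use
einsum over strided window views; the transposed convolution is implemented
directly as the adjoint scatter (verified against the inner-product adjoint
identity and finite differences in the test suite).

## Temporal cycle consistency

For two embedded trajectories `U = (u_1..u_T)`, `V = (v_1..v_S)` the soft
nearest neighbour of a reference frame is
`v~_i = Σ_j α_j v_j, α = softmax_j(−‖u_i − v_j‖²/τ)`, and the cycle-back
distribution `β = softmax_k(−‖v~_i − u_k‖²/τ)` is scored with cross-entropy
against class `i`; the loss is the mean over reference frames and both
orderings are exercised during training by sampling ordered pairs. Only the
classification variant is implemented; the temperature `τ` defaults to 1 on
squared Euclidean distances. During training TCC is computed between two
distinct trajectories sampled per batch, on contiguous windows of at most
`tcc_window` frames (64 by default) to bound memory.

## Training schedule

Three stages, each with its own epoch budget and early stopping
(validation total loss checked every `checkpoint_every` epochs, patience
counted in checkpoints, best checkpoint restored at stage end):

1. warm-up at a small constant KL weight (`1e-3`) so reconstruction and the
   learned similarity dominate;
2. linear KL annealing from `kl_weight_initial` to `kl_weight_final` over
   the first half of the stage (guards against posterior collapse);
3. stage-2 objective plus `tcc_weight ·` TCC.

Three Adam optimisers (encoder+generator for the VAE terms, generator for
its adversarial term, discriminator) share the learning rate `1e-4` by
default; `disc_lr_factor` can slow the discriminator. Trajectories are
split 60/40 into train/test and 10% of training trajectories are held out
for early stopping. Stage labels never enter training.

## Synthetic data

The generator emulates the statistics of PCNA-marked HeLa nuclei imaged at
5.9-min intervals: a centred nucleus whose radius grows from ~0.18·p at
birth to ~0.28·p in late G2; punctate replication foci in S phase (≈20
small foci in early S, ≈35 in mid S, ≈8 larger peripheral ones in late S);
a small condensed bright object in mitosis (its mean patch intensity
exceeds interphase, as condensation concentrates signal); additive Gaussian
noise (σ = 0.03) and slow photobleaching (5·10⁻⁴ per frame). Phase advances
by `1/period_frames` per frame with 2% multiplicative jitter; crossing 1 is
a division. Trajectories start at phase ≈ 0.85 ± 0.03 (late G2, the rough
G2–M synchronisation typical of such datasets). Stage occupancies default
to typical HeLa proportions (G1 0.35, early/mid/late S 0.12 each, G2 0.21,
M 0.08) — configurable, not asserted as fact about any real dataset.

What it does **not** emulate: photorealistic texture, foci that persist
across frames (they are redrawn per frame), illumination gradients,
neighbouring cells, segmentation or tracking errors. Passing tests
therefore demonstrate that the pipeline recovers structure that is present
in idealised single-cell movies; they do not certify performance on real
microscopy.

## Downstream analysis

**Staging.** An 8-component full-covariance Gaussian mixture (k-means
initialised, fixed seed) is fitted to pooled training latents; components
are named by the majority stage of their members (ties: the globally more
frequent stage, then canonical stage order), early-S/mid-S are renamed to
one "S" stage, and same-stage components merge into predictive clusters —
with six labels and eight components this typically reduces to five
stages. Held-out frames take the stage of their argmax-responsibility
component.

**Projection and orientation.** UMAP (n_neighbors 30, min_dist 0.1,
Euclidean, fixed seed) is fitted on training latents only. Because the
returned plane is arbitrary up to a rigid transform, conventions are
anchored on an observable landmark — the division frames: UMAP1's sign is
flipped so divisions sit at its minimum (`orient_projection`), and
`canonical_rotation` can place the division centroid in the lower-left
diagonal when a full pose normalisation is wanted.

**Key stages and the G1–G2 constraint.** On the B-spline-smoothed,
orientation-normalised UMAP1 curve the two lowest troughs are the mitoses
bounding one cycle; between them the first peak is G1, the highest peak
late S, the trough between those two peaks early S; inflection frames of
the smoothed curve annotate transitions. The late-S peak then disambiguates
the one confusion morphology cannot resolve: within the delimited cycle, a
G1 call at or after the late-S frame becomes G2, a G2 call before it
becomes G1 (a call exactly at the late-S frame counts as "after"). With the
*true* late-S time this rule provably never reduces accuracy (G1 precedes
and G2 follows late S within a cycle); with an *inferred* late-S time it
can occasionally overcorrect — on clean synthetic data, where raw staging
is already strong, the constrained accuracy is sometimes slightly below
the unconstrained one, and both are reported.

**Cycle duration.** `estimate_cycle_duration` smooths a scalar curve with a
centered running average (10 frames by default; truncated windows at the
edges) and returns the spacing of two troughs in hours. Two selection
rules are provided: `"prominent"` (the two most prominent troughs — the
oscillation reading of a UMAP2-style curve) and `"deepest"` (the two
lowest troughs — the landscape reading, matching the mitosis-trough
delimitation above). The pipeline measures duration on the per-cell
*distance to the division landmark* (Euclidean distance of each frame's
2-D coordinates to the training-set division centroid) with the deepest
rule: troughs of that curve are closest approaches to mitosis, the reading
is invariant to the arbitrary plane pose, and trough depth — unlike
prominence — is not truncated when a mitosis falls near the trajectory
boundary. On repeated desk-scale studies this reading recovered the
simulated period for essentially all held-out cells, where the raw
single-axis readings succeeded only for some training runs.

**Ordering diagnostic.** For each held-out cell, the Spearman correlation
between oriented UMAP1 and `|phase − phase_at_M|` (phase_at_M = mid-M) is
computed within one full cycle; the median absolute correlation over cells
is reported. It measures whether the manifold orders the cycle
monotonically away from mitosis.

## Desk-scale study

`RunConfig.desk_scale(seed)` defines the study used by the examples, the
acceptance script and the end-to-end tests: 16 cells, 32×32 patches, 64
frames, period 48 frames (4.72 h at 5.9 min/frame), latent dimension 8,
channels (8, 16, 32)/(8, 16, 32, 64), dense width 128, epochs (40, 30, 30)
with checkpoints every 5 and patience 3, batch 32, learning rate 1e-3,
`tcc_weight` 1.0, `kl_weight_final` 0.1, running-average window 5. Sixteen
cells split 10/6 into train/held-out; one study trains in a few minutes on
one CPU.

Two desk-scale choices deviate from the full-scale defaults and deserve
justification. The learning rate is raised to 1e-3 because ten trajectories
yield only ~20 optimiser steps per epoch; at 1e-4 the compressed epoch
budget stops far short of convergence. And the adversarial and
feature-metric weights are set to zero: with ~600 training frames and batch
32, the discriminator wins the minimax game almost immediately, and its
gradients visibly distort the embedding geometry (the within-cycle ordering
correlation collapses when they are enabled at this scale). The study
therefore exercises the VAE+TCC path of the full objective; the GAN terms
are part of the package defaults and are intended for realistically sized
datasets.

## Numerical notes

* Softmaxes subtract the row maximum; GAN losses are computed from logits
  via stable softplus during training, and from clipped probabilities
  (`1e-7`) in the analytic API.
* Batch normalisation keeps float64 running statistics; evaluation mode is
  used for every deterministic API (encode/decode/discriminate/embed).
* B-spline smoothing defaults to a residual budget of
  `T · (0.15 · std)²`; smoothing factor 0 interpolates; constant series are
  reproduced exactly.
* All randomness flows through `numpy.random.Generator` seeded from the
  schedule/config; re-running with the same seed on the same hardware
  reproduces losses, checkpoints and artifacts bit-for-bit.
* A non-finite training loss aborts with a stage/epoch diagnostic rather
  than continuing.

## Known limitations

* The NumPy networks are single-threaded and desk-scale; wall-clock budgets
  cap realistic patch sizes around 64×64 and datasets around 10⁴ frames.
* Foci are redrawn per frame in the generator, so the synthetic texture has
  no temporal persistence; TCC benefits from persistence in real data.
* Whether a trained manifold opens the cycle loop (monotone UMAP1 ramp) or
  keeps it closed varies across training runs at desk scale; the
  landmark-distance duration reading is robust to this, but the
  single-axis ordering correlation is itself run-dependent.
* The G1–G2 constraint is applied within one delimited cycle per
  trajectory; multi-generation lineages are out of scope.
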