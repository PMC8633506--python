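# Methods

## Featurization

Trajectories enter as multi-model PDB or a flat frames×(3·M)
coordinate matrix (Å).  Frames are superposed onto frame 0 by the
Kabsch algorithm (SVD of the covariance matrix with a determinant
correction so reflections are excluded); the fit can be restricted to
a selection while the transform is applied to all atoms.  Alignment is
exact for rigid motions and preserves intra-frame geometry to
numerical precision (~1e-12 Å in practice, asserted at 1e-9 Å).

Each coordinate column is MinMax-scaled with its per-column extrema
over frames.  Scaling is per feature column, not global: two columns
with different spans get different affine maps, and the stored
(min, max) pairs invert the map exactly.  Columns with max = min are
undefined under this scaling; they are mapped to 0.0 and flagged with
a warning rather than silently producing NaN.  Inverse scaling accepts
values outside [0, 1] and extrapolates linearly, because decoder
outputs may exceed the training range.

The train/test split reserves every 4th frame (1-based: frames 4, 8,
…) for testing — exactly 25% when the frame count is a multiple of
four.

## Autoencoder and variational autoencoder

Both models are hourglass stacks of dense layers.  The five reference
geometries (input/output width 4980, latent width 2) are:

| encoder layers | sizes |
|---|---|
| 1 | 128 |
| 2 | 512, 32 |
| 3 | 1024, 128, 16 |
| 4 | 1024, 256, 64, 16 |
| 5 | 2048, 512, 128, 32, 8 |

`scaled_architecture` generates the analogous geometry for any input
width by keeping a constant compression factor between adjacent
layers, which is the rule those reference stacks follow.

The networks are implemented directly in NumPy (dense forward/backward
passes, Adam updates).  At these sizes — at most ~10M parameters, a
few thousand frames — a framework adds nothing, and a single-threaded
NumPy implementation makes training bit-reproducible for a fixed seed.
Gradient correctness is enforced by finite-difference-validated
derivations and by the training tests.

Choices the underlying method leaves open, fixed here as defaults and
exposed in `ModelSpec`:

- **Reconstruction likelihood**: Gaussian with fixed variance, i.e.
  summed squared error on the [0, 1]-scaled features (mean over the
  batch).  Inputs are scaled coordinates, not probabilities, so a
  Bernoulli likelihood would be wrong.
- **Activations**: rectifier hidden, sigmoid output (keeps decodes in
  the scaled range).
- **Optimizer**: Adam, learning rate 1e-3, batch 32, 200 epochs
  (training loss visibly converges by then on the synthetic system).
- **Prior / posterior**: standard normal prior; diagonal Gaussian
  posterior with one reparameterised sample per datum per step.
  Log-variances are clipped to ±10 for numerical safety.
- **KL weight**: 1.0 (plain ELBO), with **linear warm-up over the
  first 50 epochs** (`kl_anneal_epochs`).  Without warm-up the
  posterior collapses on inputs of this width: the KL term drives
  q(z|x) onto the prior before the decoder learns to use z, and the
  model never leaves that attractor (reconstruction stays at the
  data-mean level).  With warm-up the final objective is still the
  plain ELBO.  Set `kl_anneal_epochs=0` to disable.
- Encoding always returns the posterior mean μ(x), never a sample, so
  embeddings and all derived metrics are deterministic.

Per-epoch history records reconstruction, KL, the effective KL weight
and the total; total = reconstruction + weight·KL holds to 1e-6 by
construction.

## Assessment metrics

**Distance preservation (encoder).**  Euclidean distances for the same
frame pairs are computed in feature space and in latent space — all
pairs when there are ≤100,000, otherwise a seeded uniform subsample of
pairs (all-pairs is quadratic in frames).  Spearman's ρ uses the
6Σd²/(n(n²−1)) shortcut on average ranks; when ties are present the
shortcut is biased, so the implementation falls back to the Pearson
correlation of the ranks (the two agree exactly on tie-free data).
Degenerate inputs (a constant distance list) make the correlation
undefined; both metrics then return NaN with a warning.

**Superposition RMSD (decoder).**  Minimum RMSD over rigid transforms,
via the same Kabsch fit.  Symmetric, zero for rigid copies, and
cross-checked in the tests against a fine rotation-grid search and an
independent library implementation.

**MMD and EMD.**  Following the proxy-variable convention, the
distributions compared are scalar RMSD-to-reference values (reference:
first frame of the evaluated set, configurable) for real versus
decoded frames.  MMD uses a Gaussian kernel with median-heuristic
bandwidth on the pooled sample (both overridable) and the unbiased
squared-MMD estimator clamped at zero; EMD is the exact 1-D first
Wasserstein distance (sorted quantiles, via SciPy).  Because kernel
and estimator conventions vary, absolute MMD/EMD values are only
comparable within a fixed configuration; the benchmark harness keeps
that configuration constant across models.

**Benchmark harness.**  Each architecture trains n_replicates times
(default 3, seeds offset deterministically); all five metrics are
computed on the held-out partition; per-replicate rows plus the mean
are reported, and a failed replicate is recorded as a row with an
error note rather than dropped.  A `dope` field exists in the report
schema but is populated only if the caller supplies an external
statistical-potential scorer; no such scorer ships here.

## Latent-space exploration

Candidate seed points are placed at evenly spaced interpolation
parameters on the segment between the centroids of two labelled state
regions, with optional seeded Gaussian jitter — a deterministic
surrogate for picking points by eye in a latent-space plot.  Decoded
seeds are written as single-model PDB files on a template's atom
records.  Decoded structures are not energy-minimised; producing
plausible Cartesian coordinates is where this tool's contract ends,
minimisation belongs to the downstream MD engine.

Domain-angle collective variables are angles between two
centre-of-mass difference vectors over residue ranges.  Centroids are
unweighted by default (mass weighting available) and, by default, all
selected atoms in the range contribute.  The packaged adenylate-kinase
configuration ships the published CORE–NMP / CORE–LID residue ranges
in three crystal-structure numberings; note the LID angle's tail and
head ranges share one boundary residue in the published definition, so
overlapping (but not identical) tail/head sets warn instead of
erroring.

## Markov-state-model analysis

CV trajectories are discretised by k-means (k-means++ initialisation,
10 restarts, seeded; scikit-learn).  Transition counting uses a
sliding window by default (strided available) and never crosses
joins between concatenated trajectory segments.  The transition matrix
is the non-reversible maximum-likelihood estimate (row normalisation)
restricted to the largest strongly connected component of the count
graph; trimmed states are reported.  Reversible (detailed-balance)
estimation is out of scope.

Implied timescales are t_i(τ) = −τ/ln λ_i(τ) for the eigenvalues
below 1, sorted by descending real part after checking the spectrum is
near-real (complex parts above 1e-8 are flagged with a warning, which
can legitimately occur for non-reversible estimates at finite
sampling).  Eigenvalues ≤0 or ≥1 yield NaN entries, flagged rather
than dropped.  Confidence intervals come from a percentile bootstrap:
whole-segment (block) resampling when at least five segments exist,
otherwise transition-pair resampling with a warning.

## Synthetic data

The generator emulates the essential structure of a two-state protein
trajectory: two reference conformations of M pseudo-atoms (default: a
straight 50-atom chain versus a chain bent by 48°, ~5 Å apart in
superposition RMSD — far enough that a 2-D latent space must separate
them), a symmetric two-state Markov chain over frames, isotropic
Gaussian positional noise per coordinate (default σ = 0.5 Å, roughly
thermal-fluctuation scale), and optionally an independent uniform
SO(3) rotation plus a translation uniform in a ±5 Å cube per frame.
A single seeded RNG stream drives chain, noise and rigid motions, so
output is bit-identical across runs.

What it does **not** emulate: bonded geometry and physical energetics,
anisotropic/correlated fluctuations, more than two states, and
state-dependent noise.  Tests passing on this generator therefore
demonstrate the correctness of the pipeline's machinery (alignment,
scaling, optimisation, metrics, MSM estimation) and its behaviour
under known ground truth — not that a VAE trained on any particular
real protein will separate its states.

## Problem sizes and numerical choices

The end-to-end checks use 50 atoms × 2,000 frames with a 4-layer VAE
trained 200 epochs (~10 s single-threaded); analytic-limit checks use
a 200,000-step simulated two-state chain; the Monte-Carlo RMSD oracle
uses 1e5 draws.  Training sets much smaller than ~300 frames at these
widths can still collapse the posterior even with warm-up — the
reconstruction reward is too small relative to the KL — which is a
known limitation, not a target of the defaults.

Tie-breaks and degenerate inputs: constant feature columns are flagged
and zeroed; collinear alignment references raise; identical latent
group centroids raise (no interpolation direction); all-equal distance
lists return NaN with a warning; non-decaying eigenvalues give NaN
timescales.
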