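# Methods

## Model and procedure

`gparcel` orders tractography seed voxels along a continuum of
connectivity change. The unit of analysis is the binarised connectivity
profile: for seed *i*, a 0/1 row vector over all brain voxels recording
which voxels any streamline from that seed visited. The stages are

1. **Seed surface.** The grey/white-matter interface is obtained by
   binarising a white-matter partial-volume map at any positive value and
   extracting perimeter voxels — foreground voxels with at least one
   background or out-of-grid neighbour. The neighbourhood defaults to
   6-connectivity (18/26 available); out-of-bounds counts as background so
   voxels on the grid edge are perimeter. Seeds are ordered
   lexicographically by (x, y, z), and that order is persisted because it
   defines profile-matrix rows.
2. **Preprocessing.** Each per-seed visitation volume is thresholded at a
   fraction of its own maximum (default 5e-4, i.e. 0.05 % — a conventional
   noise floor for probabilistic tractography), downsampled by an integer
   factor (default 2) using **block maximum**, binarised (> 0) and
   flattened with x varying fastest. Block-maximum downsampling is chosen
   over striding or averaging because it preserves binarised visitation
   support: a visited voxel anywhere in a block keeps the block visited.
   All-zero columns are dropped (they contribute nothing to any dot
   product or norm, so no cosine similarity changes); the surviving
   original column indices travel with the matrix.
3. **Similarity.** Cosine similarity between profile rows, symmetrised by
   averaging with the transpose (post-check tolerance 1e-10). Rows with
   zero norm are rejected by name with the advice to lower the threshold
   fraction; silently dropping seeds would desynchronise the seed table.
4. **Spectral reordering.** With the similarity diagonal zeroed (self
   loops shift the spectrum without changing the ordering and would make
   λ₂ thresholds uninterpretable), degrees d_i = Σ_j S_ij and
   L = I − D^(−1/2) S D^(−1/2). λ₂, the second-smallest eigenvalue, is
   the gradation index; the second eigenvector mapped through D^(−1/2) is
   the Fiedler vector of the generalised problem (D − S)x = λDx, the
   coordinate that minimises Σ S_ij (x_i − x_j)² under degree weighting.
   The ordering is the stable argsort of its entries.
5. **Projection.** The seed at matrix position p receives normalised rank
   p/(n−1) in its voxel; background voxels carry NaN (0 is a valid rank).
   An optional RGB rendering uses a blue→red map; colours are
   presentation only. Profiles of any stretch of matrix positions can be
   summed and un-flattened to a volume to inspect the tracts driving that
   part of the gradient.
6. **Group level.** Each template-surface seed pulls the profile of its
   nearest individual seed (Euclidean distance in world mm through the
   affine — voxels are often anisotropic), ties to the lowest individual
   index. This direction guarantees every template seed has exactly one
   tract per participant, while an individual seed may serve several
   template seeds. Voxelwise averaging of the k binarised tracts gives
   probabilistic profiles on the lattice {0, 1/k, …, 1}, which flow
   through the same similarity/reordering path without re-binarisation.
7. **Consistency.** (a) Leave-one-out: the group path on all-but-one
   participants predicts the held-out participant's ordering; the held-out
   data, mapped to the template and permuted to the predicted order, are
   reordered and the resulting positions Spearman-correlated against the
   prediction. (b) Deviation map: with the full-group ordering as
   reference, each participant's |position − reference position| is
   averaged over participants and divided by N−1 (the maximum possible
   displacement), giving a per-seed score in [0, 1].

## Conventions and numerical choices

* **Laplacian normalisation.** The degree-normalised form is the default:
  it makes both ordering and λ₂ invariant to global rescaling of the
  similarities, bounds λ₂ in [0, 2], and gives the "λ₂ near zero iff
  clustered" criterion a scale-free meaning. The unnormalised Laplacian is
  available (`normalised=False`) for sensitivity analysis.
* **Eigensolver.** Dense `eigh` below n = 300 (faster and exact at that
  scale); above, shift-inverted Lanczos (`eigsh`, k = 2, σ just below 0)
  with a fixed all-ones starting vector so repeated runs are bit
  identical, falling back to dense on non-convergence. The solver path is
  recorded in every output.
* **Sign and ties.** Eigenvector sign is fixed by requiring non-negative
  Spearman correlation with a reference ordering (default: input index
  order; in validation: the predicted ordering). A global reversal of an
  ordering is therefore an equivalence, never an error. Ties in Fiedler
  entries break by original seed index via stable sort.
* **Spearman p-values** use the large-sample approximation; at the sizes
  analysed (n ≥ 40) this is accurate far beyond the decision threshold.
* **Degenerate inputs.** All-zero volumes threshold to themselves with a
  warning; an all-zero profile matrix drops to width 0 with a warning;
  empty profile rows and isolated seeds (zero total similarity) are
  rejected by seed id.

## Synthetic cohorts

The generator emulates exactly the statistical object the analysis
consumes — binarised visitation maps — and nothing upstream (no diffusion
signal or streamline propagation; Bernoulli visitation is the minimal
faithful noise model, and per-voxel flip noise stands in for tracking
error). Defaults: a 32³ grid (a realistic post-downsampling working grid),
K = 4 tract templates echoing the handful of major bundles that dominate
real temporal-lobe profiles, visitation probability 0.9 inside a template,
200 seeds, 8 participants, flip noise 0.05. Templates are slabs with
configurable pairwise overlap; seeds lie on a serpentine curve so the
latent coordinate t increases along a spatially connected path, as on a
cortical surface strip.

In the graded regime, mixture weights are Gaussian bumps of t (width
0.5/(K−1)), so expected-profile similarity decays smoothly with |t_i −
t_j|; the decay is exactly monotone along each direction of the gradient
from any seed, though not as a two-sided function of |Δt| alone (seeds near
the gradient ends have asymmetric neighbourhoods). In the clustered
regime, weights are one-hot in floor(tK), giving block similarity with
λ₂ → 0 as template overlap → 0.

What passing on synthetic cohorts does *not* show: robustness to
registration error, to spatially correlated tracking artefacts (flip noise
is i.i.d. per voxel), to seed surfaces that differ across participants
(clones share geometry), or to anatomically realistic bundle shapes.
Recovery numbers on these cohorts are best-case references, not forecasts
for real diffusion data.

## Problem sizes

The test suite and the acceptance script run planted-gradient recovery and
the graded-vs-clustered contrast at 200 seeds × 8 participants × 10
replicates, consistency validation at 100 seeds × 6 participants across
noise {0.02, 0.05, 0.1}, and solver-equivalence checks on 100 random
matrices up to n = 200 — sizes at which every documented property is
exercised while a full run stays in the minutes range on one CPU. Real
cohorts (≈3000 seeds per individual, ≈5000 template seeds) are within the
dense-matrix design envelope; the sparse eigensolver path engages
automatically above n = 300.

## Known limitations

* Registration/normalisation to template space is out of scope: group
  inputs are assumed already resampled to the template grid.
* Only cosine similarity is contracted; correlation/Jaccard kernels are
  not offered.
* Single-eigenvector embedding only: no diffusion maps or multi-dimensional
  spectral embeddings, and no hard clustering.
* λ₂ values depend on the normalisation convention; compare them only
  across analyses using the same convention.
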