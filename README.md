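# gparcel

Graded connectivity-based parcellation of a cortical seed surface by
spectral reordering of tractography connectivity profiles.

## The problem

Hard parcellation schemes (k-means, hierarchical clustering) carve a brain
region into parcels with sharp borders. But the connectivity of many
cortical territories changes *gradually*: neighbouring seed voxels reach
largely overlapping sets of brain voxels, and similarity decays smoothly
with distance along the cortex. `gparcel` implements the alternative:
instead of imposing clusters, it orders seed voxels along a continuum of
connectivity change and quantifies *how graded* that continuum is. It is
aimed at researchers analysing diffusion-MRI tractography "connectivity
fingerprints" — one whole-brain streamline-visitation volume per seed voxel
on the grey/white-matter interface (GWI).

## The method

For `n` seed voxels with binarised, flattened connectivity profiles stacked
into an `n × m` matrix, the pipeline computes the pairwise cosine similarity

    S_ij = ⟨x_i, x_j⟩ / (‖x_i‖ ‖x_j‖)

and treats `S` (diagonal removed) as a weighted graph with degrees
`d_i = Σ_j S_ij`. The symmetric normalised graph Laplacian

    L = I − D^(−1/2) S D^(−1/2)

has a trivial eigenvalue 0; its second-smallest eigenvalue **λ₂**
(algebraic connectivity, in [0, 2]) is the *gradation index*: near zero
when the seeds split into weakly coupled clusters, larger when similarity
varies smoothly across the region. The corresponding eigenvector, mapped
through `D^(−1/2)` (the **Fiedler vector** of the generalised problem
`(D − S) x = λ D x`), embeds the seeds on a line; sorting by its entries is
the **spectral reordering**. Each seed's normalised rank `p/(n−1)` in the
reordered matrix is projected back into its voxel, producing a graded
(blue→red) parcellation map rather than hard parcels.

Group analysis maps every participant's seeds onto a shared template GWI by
nearest-neighbour distance in world (mm) coordinates, averages the
binarised tracts into probabilistic profiles on the lattice `{j/k}` for `k`
participants, and reorders those exactly like individual data. Consistency
is validated by leave-one-out prediction (Spearman rho between each
held-out participant's ordering and the ordering predicted by the rest of
the cohort) and by a per-seed normalised mean absolute rank-deviation map.

Because real tractography cohorts are rarely shareable, the package ships a
first-class synthetic generator: seeds along a 1-D curve mix K canonical
"tract templates" with smooth bump weights of a latent coordinate
`t ∈ [0, 1]` (graded regime) or one-hot weights (clustered regime), and
participants draw Bernoulli visitation with optional flip noise.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from gparcel import make_cohort, run_group_pipeline

cohort = make_cohort(n_seeds=200, n_participants=8, K=4,
                     regime="graded", noise=0.05, rng_seed=17)
result, gpm = run_group_pipeline(cohort.participant_profiles,
                                 cohort.participant_seeds, cohort.seeds)
rho = spearmanr(result.positions(), cohort.truth.t).statistic
print(f"group lambda2 = {result.lambda2:.3f}")
print(f"gradient recovery |rho| = {abs(rho):.4f}")
```

prints

```
group lambda2 = 0.563
gradient recovery |rho| = 1.0000
```

The ordering recovers the planted gradient essentially perfectly
(|rho| = 1.0 up to rounding), and λ₂ ≈ 0.56 sits well away from zero, as
expected for a graded cohort. The same cohort generated in the clustered
regime at the same noise gives λ₂ ≈ 0.36, and a two-cluster cohort with
disjoint templates and no noise gives λ₂ = 0 — the index separates graded
from clustered organisation. Leave-one-out validation on a 6-participant
graded cohort yields rho in 0.9998–0.9999 and a mean rank deviation of
0.0027 (scale 0–1).

The same stages are available from the shell:

```bash
gparcel simulate --regime graded --n-seeds 200 --participants 8 \
        --noise 0.05 --seed 17 --out sim/
gparcel group --manifest sim/cohort.yaml --out group_out/
gparcel validate --manifest sim/cohort.yaml --out consistency/
```

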