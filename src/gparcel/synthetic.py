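"""Synthetic cohorts of binarised per-seed connectivity volumes.

The analysis pipeline consumes only binarised streamline-visitation maps,
so the generator emulates exactly that statistical object and nothing
upstream of it: no diffusion signal, no streamline propagation.

A cohort is built from K canonical "tract templates" — disjoint (or
partially overlapping) slabs of visitation probability in a small 3-D grid,
standing in for the handful of major bundles that dominate real seed
profiles.  Seeds are laid along a 1-D serpentine curve through the grid and
each carries a latent coordinate t in [0, 1]:

* graded regime — each seed's visitation probability is a smooth mixture of
  the K templates, with Gaussian bump weights in t, so cosine similarity
  decays continuously with |t_i - t_j| and the planted structure is a
  gradient;
* clustered regime — weights are one-hot in the seed's cluster label
  floor(t * K), so similarity is block-structured with sharp borders.

Each participant draws independent Bernoulli visitation from the seed's
probability map, then every voxel is flipped with probability ``noise``
(tracking error).  All randomness flows through one seeded generator, so a
cohort is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile_io import ProfileMatrix, SeedSet
from .similarity import SimilarityMatrix

__all__ = ["TractTemplate", "PlantedTruth", "SyntheticCohort", "make_cohort",
           "make_templates", "make_block_similarity", "expected_profiles"]

DEFAULT_GRID = (32, 32, 32)
DEFAULT_VISIT_PROB = 0.9


@dataclass
class TractTemplate:
    """One canonical bundle: a per-voxel visitation-probability map."""

    volume: np.ndarray  # values in [0, 1]
    id: str

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if (self.volume < 0).any() or (self.volume > 1).any():
            raise ValueError("template values must be probabilities in [0, 1]")
        if not (self.volume > 0).any():
            raise ValueError("template support must be non-empty")


@dataclass
class PlantedTruth:
    """Ground truth behind a synthetic cohort."""

    t: np.ndarray                 # (n_seeds,) latent gradient coordinate
    weights: np.ndarray           # (n_seeds, K) mixture weights, rows sum to 1
    cluster: np.ndarray | None    # (n_seeds,) labels in the clustered regime
    regime: str
    noise: float


@dataclass
class SyntheticCohort:
    """Per-participant profile matrices plus shared seeds and truth."""

    seeds: SeedSet
    participant_profiles: list[ProfileMatrix] = field(default_factory=list)
    participant_seeds: list[SeedSet] = field(default_factory=list)
    templates: list[TractTemplate] = field(default_factory=list)
    truth: PlantedTruth | None = None


def _serpentine_seeds(n_seeds: int, grid: tuple[int, int, int]) -> np.ndarray:
    """Seed voxels along a serpentine curve in the z=0 plane.

    Consecutive seeds are spatially adjacent, so the latent coordinate t
    increases along a connected 1-D path, as on a cortical surface strip.
    """
    gx, gy, _ = grid
    if n_seeds > gx * gy:
        raise ValueError(f"{n_seeds} seeds do not fit a {gx}x{gy} seed plane")
    coords = []
    for y in range(gy):
        xs = range(gx) if y % 2 == 0 else range(gx - 1, -1, -1)
        for x in xs:
            coords.append((x, y, 0))
            if len(coords) == n_seeds:
                return np.array(coords, dtype=int)
    return np.array(coords, dtype=int)


def make_templates(K: int, grid: tuple[int, int, int] = DEFAULT_GRID,
                   overlap: float = 0.0,
                   visit_prob: float = DEFAULT_VISIT_PROB) -> list[TractTemplate]:
    """K slab templates along x, occupying z >= 2 (clear of the seed plane).

    ``overlap`` in [0, 1) is the fraction of each slab's width shared with
    its neighbour; 0 gives disjoint supports.
    """
    if K < 2:
        raise ValueError("need at least K = 2 templates")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    gx, gy, gz = grid
    width = gx // K
    if width < 1:
        raise ValueError(f"grid x-extent {gx} too small for {K} templates")
    stride = max(1, int(round(width * (1 - overlap))))
    templates = []
    for k in range(K):
        start = min(k * stride, gx - width)
        vol = np.zeros(grid)
        vol[start:start + width, :, 2:] = visit_prob
        templates.append(TractTemplate(volume=vol, id=f"template_{k}"))
    return templates


def _bump_weights(t: np.ndarray, K: int, width: float | None = None) -> np.ndarray:
    """Gaussian bump mixture weights over K templates as a function of t."""
    if width is None:
        width = 0.5 / (K - 1)
    centres = np.linspace(0, 1, K)
    w = np.exp(-0.5 * ((t[:, None] - centres[None, :]) / width) ** 2)
    return w / w.sum(axis=1, keepdims=True)


def expected_profiles(truth: PlantedTruth,
                      templates: list[TractTemplate]) -> np.ndarray:
    """Noise-free per-seed visitation probabilities, flattened (x fastest)."""
    flat_templates = np.stack([t.volume.ravel(order="F") for t in templates])
    return truth.weights @ flat_templates


def make_cohort(
    n_seeds: int = 200,
    n_participants: int = 8,
    K: int = 4,
    regime: str = "graded",
    noise: float = 0.05,
    rng_seed: int = 0,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    overlap: float = 0.0,
    gradient_width: float | None = None,
) -> SyntheticCohort:
    """Generate a synthetic cohort with a planted gradient or clusters.

    Every participant shares the seed geometry (the cohort is generated
    directly in template space); visitation is drawn independently per
    participant and per voxel, then flipped with probability ``noise``.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if not (0 <= noise < 0.5):
        raise ValueError("noise must be in [0, 0.5)")
    if regime not in ("graded", "clustered"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(rng_seed)
    templates = make_templates(K, grid=grid, overlap=overlap)
    coords = _serpentine_seeds(n_seeds, grid)
    t = np.linspace(0, 1, n_seeds)
    if regime == "graded":
        weights = _bump_weights(t, K, gradient_width)
        cluster = None
    else:
        cluster = np.minimum((t * K).astype(int), K - 1)
        weights = np.zeros((n_seeds, K))
        weights[np.arange(n_seeds), cluster] = 1.0
    truth = PlantedTruth(t=t, weights=weights, cluster=cluster,
                         regime=regime, noise=noise)
    probs = expected_profiles(truth, templates)  # (n_seeds, m)
    m = probs.shape[1]
    seeds = SeedSet(coords=coords, affine=np.eye(4), label="template")
    cohort = SyntheticCohort(seeds=seeds, templates=templates, truth=truth)
    for p in range(n_participants):
        visits = (rng.random((n_seeds, m)) < probs)
        if noise > 0:
            flips = rng.random((n_seeds, m)) < noise
            visits = visits ^ flips
        pm = ProfileMatrix(
            values=visits.astype(float),
            seed_ids=[f"seed_{i}" for i in range(n_seeds)],
            column_map=np.arange(m, dtype=np.int64),
            grid_shape=grid,
            space_tag="synthetic",
        )
        cohort.participant_profiles.append(pm)
        cohort.participant_seeds.append(
            SeedSet(coords=coords.copy(), affine=np.eye(4), label=f"participant_{p}"))
    return cohort


def make_block_similarity(n: int, within: float, between: float) -> SimilarityMatrix:
    """Two equal blocks with constant within/between similarity, unit diagonal.

    A direct fixture for the gradation index: between = 0 gives a
    disconnected graph (lambda_2 = 0), between = within a complete graph
    (lambda_2 = n/(n-1)).
    """
    if n % 2 != 0:
        raise ValueError("n must be even (two equal blocks)")
    if not (0 <= between <= within <= 1):
        raise ValueError("need 0 <= between <= within <= 1")
    half = n // 2
    S = np.full((n, n), between)
    S[:half, :half] = within
    S[half:, half:] = within
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, seed_ids=[f"seed_{i}" for i in range(n)])
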