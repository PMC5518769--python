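"""Group-level aggregation of individual connectivity profiles.

Individual seed surfaces differ across participants, so before averaging,
every seed on a shared template surface is matched to its nearest seed (in
world-space Euclidean distance) in each participant.  Because individual
surfaces are typically sparser than the template, one individual seed may
serve several template seeds, and every template seed ends up with exactly
one binarised tract per participant.  Averaging those tracts voxelwise
yields probabilistic profiles on the lattice {0, 1/k, ..., 1} for k
participants, which then flow through the same similarity/reordering path
as individual data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .profile_io import ProfileMatrix, SeedSet, drop_zero_columns
from .similarity import cosine_similarity_matrix
from .spectral import SpectralResult, reorder

__all__ = ["GroupProfileMatrix", "nearest_neighbour_map", "group_average",
           "run_group_pipeline"]


@dataclass
class GroupProfileMatrix:
    """Probabilistic profiles on the template seed surface."""

    profiles: ProfileMatrix
    participant_count: int


def nearest_neighbour_map(individual: SeedSet, template: SeedSet) -> np.ndarray:
    """For each template seed, the index of the nearest individual seed.

    Distances are Euclidean in world (mm) coordinates through the shared
    affine, so anisotropic voxels are handled correctly.  Ties break to the
    lowest individual seed index.
    """
    if len(individual) == 0:
        raise ValueError("individual seed set is empty")
    if not np.allclose(individual.affine, template.affine):
        raise ValueError("individual and template seed sets are on different grids")
    tree = cKDTree(individual.world_coords())
    dist, idx = tree.query(template.world_coords(), k=1)
    # cKDTree breaks exact ties arbitrarily; enforce lowest-index winner
    world_ind = individual.world_coords()
    world_tmp = template.world_coords()
    for t in range(len(idx)):
        d2 = np.sum((world_ind - world_tmp[t]) ** 2, axis=1)
        tied = np.flatnonzero(np.isclose(d2, d2[idx[t]], rtol=0, atol=1e-9))
        if tied.size > 1:
            idx[t] = tied.min()
    return np.asarray(idx, dtype=int)


def group_average(per_participant: list[np.ndarray]) -> np.ndarray:
    """Voxelwise mean of binarised tract rows across participants.

    Returns values on the lattice {j/k}: 0 when no participant's tract
    visits the voxel, 1 when every participant's does.
    """
    k = len(per_participant)
    if k < 1:
        raise ValueError("need at least one participant")
    shapes = {np.asarray(t).shape for t in per_participant}
    if len(shapes) != 1:
        raise ValueError(f"participants are on mixed grids: shapes {sorted(shapes)}")
    stack = np.stack([np.asarray(t, dtype=float) for t in per_participant])
    if ((stack != 0) & (stack != 1)).any():
        raise ValueError("tracts must be binarised before group averaging")
    return stack.mean(axis=0)


def build_group_profiles(
    participant_profiles: list[ProfileMatrix],
    participant_seeds: list[SeedSet],
    template: SeedSet,
) -> GroupProfileMatrix:
    """Map every participant onto the template surface and average.

    Each participant's rows are re-indexed so that row t holds the profile
    of the individual seed nearest to template seed t, then the k
    re-indexed matrices are averaged voxelwise.
    """
    k = len(participant_profiles)
    if k != len(participant_seeds):
        raise ValueError("one seed set per participant profile matrix required")
    grids = {pm.grid_shape for pm in participant_profiles}
    if len(grids) != 1:
        raise ValueError(f"participant profiles on mixed grids: {sorted(grids)}")
    n_tmpl = len(template)
    mapped_rows = []
    for pm, seeds in zip(participant_profiles, participant_seeds):
        if pm.n != len(seeds):
            raise ValueError("profile rows and seed count differ for a participant")
        mapping = nearest_neighbour_map(seeds, template)
        assert len(mapping) == n_tmpl  # full template coverage by construction
        mapped_rows.append(pm.values[mapping])
    mean = group_average(mapped_rows)
    template_ids = [f"tmpl_{i}" for i in range(n_tmpl)]
    profiles = ProfileMatrix(
        values=mean,
        seed_ids=template_ids,
        column_map=participant_profiles[0].column_map.copy(),
        grid_shape=participant_profiles[0].grid_shape,
        space_tag=participant_profiles[0].space_tag,
    )
    return GroupProfileMatrix(profiles=profiles, participant_count=k)


def run_group_pipeline(
    participant_profiles: list[ProfileMatrix],
    participant_seeds: list[SeedSet],
    template: SeedSet,
    normalised: bool = True,
) -> tuple[SpectralResult, GroupProfileMatrix]:
    """Full group path: map, average, drop zero columns, similarity, reorder."""
    if len(participant_profiles) < 2:
        raise ValueError("group pipeline requires at least two participants")
    gpm = build_group_profiles(participant_profiles, participant_seeds, template)
    reduced = drop_zero_columns(gpm.profiles)
    sm = cosine_similarity_matrix(reduced)
    result = reorder(sm, normalised=normalised)
    return result, gpm
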