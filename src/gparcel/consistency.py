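"""Cross-participant consistency of spectral orderings.

Two complementary checks:

1. Leave-one-out prediction: the group pipeline is run on all participants
   except one; its permutation is the predicted ordering for the held-out
   participant.  The held-out data are permuted to that predicted order,
   spectrally reordered, and the actual ordering is Spearman-correlated
   against the prediction (one rho per participant).

2. Rank-deviation map: with the full-group ordering as reference, each
   participant's data are permuted to the reference and reordered; for
   every template seed the mean absolute difference between the
   participant's and the reference matrix positions, averaged over
   participants and divided by N-1 (the maximum possible displacement),
   gives a per-seed consistency score in [0, 1].

Spectral orderings are defined only up to global reversal, so before any
comparison the Fiedler sign is aligned to make the correlation with the
reference non-negative; reported rho values are the aligned branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .profile_io import ProfileMatrix, SeedSet, drop_zero_columns
from .group import run_group_pipeline
from .similarity import cosine_similarity_matrix
from .spectral import SpectralResult, reorder

__all__ = ["ConsistencyReport", "loo_predicted_ordering", "actual_vs_predicted",
           "rank_deviation_map", "run_validation"]


@dataclass
class ConsistencyReport:
    """Per-participant prediction accuracy and per-seed rank stability."""

    participant_ids: list
    rho: np.ndarray            # aligned Spearman rho, one per participant
    p_values: np.ndarray
    deviation: np.ndarray      # per template seed, normalised to [0, 1]
    reference_ordering: np.ndarray


def loo_predicted_ordering(
    participant_profiles: list[ProfileMatrix],
    participant_seeds: list[SeedSet],
    template: SeedSet,
    test_index: int,
    normalised: bool = True,
) -> SpectralResult:
    """Group ordering computed with one participant held out."""
    k = len(participant_profiles)
    if k < 3:
        raise ValueError("leave-one-out requires a cohort of at least 3")
    keep = [i for i in range(k) if i != test_index]
    result, _ = run_group_pipeline(
        [participant_profiles[i] for i in keep],
        [participant_seeds[i] for i in keep],
        template,
        normalised=normalised,
    )
    return result


def _reorder_on_template(
    profiles: ProfileMatrix,
    seeds: SeedSet,
    template: SeedSet,
    predicted: np.ndarray,
    normalised: bool = True,
) -> np.ndarray:
    """Permute one participant's template-mapped data to the predicted order,
    reorder spectrally, and return the actual positions in predicted-order
    coordinates (so the predicted ordering is the identity)."""
    from .group import nearest_neighbour_map

    mapping = nearest_neighbour_map(seeds, template)
    rows = profiles.values[mapping]          # template order
    rows = rows[predicted]                   # predicted order: identity reference
    pm = ProfileMatrix(
        values=rows,
        seed_ids=[f"tmpl_{i}" for i in range(len(rows))],
        column_map=profiles.column_map.copy(),
        grid_shape=profiles.grid_shape,
        space_tag=profiles.space_tag,
    )
    sm = cosine_similarity_matrix(drop_zero_columns(pm))
    # default reference = identity = the predicted ordering; this fixes the
    # Fiedler sign to the non-negative-correlation branch
    res = reorder(sm, normalised=normalised)
    return res.positions()


def actual_vs_predicted(
    profiles: ProfileMatrix,
    seeds: SeedSet,
    template: SeedSet,
    predicted: SpectralResult | np.ndarray,
    normalised: bool = True,
) -> tuple[float, float]:
    """Spearman rho (and p) between a participant's actual and predicted ordering."""
    pred = predicted.ordering if isinstance(predicted, SpectralResult) else np.asarray(predicted)
    positions = _reorder_on_template(profiles, seeds, template, pred, normalised)
    n = len(positions)
    res = spearmanr(positions, np.arange(n))
    return float(res.statistic), float(res.pvalue)


def rank_deviation_map(actual_positions: list[np.ndarray],
                       reference: SpectralResult | np.ndarray) -> np.ndarray:
    """Per-seed normalised mean absolute rank deviation.

    ``actual_positions`` holds, per participant, the matrix position of each
    template seed; the reference positions come from the full-group
    ordering.  Deviations are averaged over participants and divided by
    N-1 so 0 means every participant agrees with the reference and 1 is
    the maximum possible displacement.
    """
    if isinstance(reference, SpectralResult):
        ref_pos = reference.positions()
    else:
        reference = np.asarray(reference, dtype=int)
        ref_pos = np.empty(len(reference), dtype=int)
        ref_pos[reference] = np.arange(len(reference))
    N = len(ref_pos)
    devs = []
    for pos in actual_positions:
        pos = np.asarray(pos)
        if len(pos) != N:
            raise ValueError("participant ordering length differs from reference")
        devs.append(np.abs(pos - ref_pos))
    mean_dev = np.mean(devs, axis=0)
    return mean_dev / (N - 1) if N > 1 else mean_dev.astype(float)


def run_validation(
    participant_profiles: list[ProfileMatrix],
    participant_seeds: list[SeedSet],
    template: SeedSet,
    normalised: bool = True,
) -> ConsistencyReport:
    """Run both consistency procedures over a cohort.

    Returns per-participant leave-one-out rho/p and the per-template-seed
    deviation map computed against the full-group reference ordering.
    """
    k = len(participant_profiles)
    if k < 3:
        raise ValueError("validation requires a cohort of at least 3")
    rhos, pvals = [], []
    for t in range(k):
        predicted = loo_predicted_ordering(
            participant_profiles, participant_seeds, template, t, normalised)
        rho, p = actual_vs_predicted(
            participant_profiles[t], participant_seeds[t], template,
            predicted, normalised)
        rhos.append(rho)
        pvals.append(p)

    full_group, _ = run_group_pipeline(
        participant_profiles, participant_seeds, template, normalised=normalised)
    ref = full_group.ordering
    # participant positions in reference coordinates: permute to reference,
    # reorder, then map matrix positions back to template seed order
    actual = []
    for t in range(k):
        pos_in_ref_coords = _reorder_on_template(
            participant_profiles[t], participant_seeds[t], template, ref, normalised)
        pos_by_seed = np.empty(len(ref), dtype=int)
        pos_by_seed[ref] = pos_in_ref_coords
        actual.append(pos_by_seed)
    deviation = rank_deviation_map(actual, ref)
    assert np.all(deviation >= 0) and np.all(deviation <= 1)
    labels = [s.label or f"participant_{i}" for i, s in enumerate(participant_seeds)]
    return ConsistencyReport(
        participant_ids=labels,
        rho=np.array(rhos),
        p_values=np.array(pvals),
        deviation=deviation,
        reference_ordering=ref,
    )
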