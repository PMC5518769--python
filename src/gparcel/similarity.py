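"""Pairwise cosine similarity between seed connectivity profiles.

Each seed's connectivity profile is a non-negative row vector; the cosine
of the angle between two rows measures how much of the brain the two seeds
reach in common, independent of overall streamline count.  For non-negative
profiles the similarity lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import io as sio
from scipy import sparse

from .profile_io import ProfileMatrix

__all__ = ["SimilarityMatrix", "cosine_similarity_matrix", "region_submatrix",
           "load_similarity", "save_similarity"]

_SYMMETRY_TOL = 1e-10


@dataclass
class SimilarityMatrix:
    """Symmetric n x n matrix of cosine similarities between seed profiles."""

    values: np.ndarray
    seed_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.seed_ids) != self.values.shape[0]:
            raise ValueError("seed_ids length must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValueError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def cosine_similarity_matrix(pm: ProfileMatrix) -> SimilarityMatrix:
    """Cosine similarity between every pair of profile rows.

    Entry (i, j) is dot(row_i, row_j) / (||row_i|| * ||row_j||).  Exact
    symmetry is enforced by averaging with the transpose.  Rows with zero
    norm have no defined angle and are rejected; lowering the threshold
    fraction in preprocessing usually removes them.
    """
    X = np.asarray(pm.values, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        offenders = [pm.seed_ids[i] for i in zero[:20]]
        raise ValueError(
            f"{zero.size} seed profile(s) are all-zero (seed_ids {offenders}); "
            "cosine similarity is undefined for empty profiles — consider "
            "lowering the threshold fraction"
        )
    Xn = X / norms[:, None]
    S = Xn @ Xn.T
    S = (S + S.T) / 2.0
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, seed_ids=list(pm.seed_ids))


def region_submatrix(sm: SimilarityMatrix, ids) -> SimilarityMatrix:
    """Principal submatrix for the given seed ids, in the given order."""
    pos = {s: i for i, s in enumerate(sm.seed_ids)}
    try:
        idx = np.array([pos[s] for s in ids], dtype=int)
    except KeyError as e:
        raise KeyError(f"unknown seed id {e.args[0]!r}") from None
    return SimilarityMatrix(values=sm.values[np.ix_(idx, idx)], seed_ids=list(ids))


def save_similarity(sm: SimilarityMatrix, path: str | Path) -> None:
    path = Path(path)
    sio.mmwrite(str(path), sparse.coo_matrix(sm.values))
    with open(path.with_suffix(path.suffix + ".seeds.tsv"), "w") as fh:
        fh.write("seed_id\n")
        for s in sm.seed_ids:
            fh.write(f"{s}\n")


def load_similarity(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    values = np.asarray(sio.mmread(str(path)).todense(), dtype=float)
    values = (values + values.T) / 2.0
    with open(path.with_suffix(path.suffix + ".seeds.tsv")) as fh:
        seed_ids = [line.strip() for line in fh.readlines()[1:] if line.strip()]
    return SimilarityMatrix(values=values, seed_ids=seed_ids)
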