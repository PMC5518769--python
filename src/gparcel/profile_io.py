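"""Volumes, seed sets and connectivity-profile matrices.

This module owns the preprocessing path from per-seed connectivity volumes
to the ``n x m`` profile matrix that drives the similarity and spectral
stages: seed-surface (grey/white-matter interface) extraction, region
masking, thresholding relative to the volume maximum, block downsampling,
binarise-and-flatten, row concatenation and zero-column removal.

Conventions
-----------
* Voxel coordinates are 0-based integer triples ``(x, y, z)``.
* Flattening is lexicographic with ``x`` fastest (Fortran ravel order);
  the ``column_map`` of a :class:`ProfileMatrix` records, for every column,
  the linear (Fortran-order) voxel index in the reference grid, so matrices
  remain portable after zero columns are dropped.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import io as sio
from scipy import ndimage, sparse

__all__ = [
    "Volume",
    "SeedSet",
    "ProfileMatrix",
    "extract_perimeter",
    "mask_seeds",
    "threshold_profile",
    "downsample",
    "binarise_flatten",
    "unflatten",
    "assemble_profiles",
    "drop_zero_columns",
    "binarise_pv_map",
    "load_volume",
    "save_volume",
    "load_seedset",
    "save_seedset",
    "load_profiles",
    "save_profiles",
]


@dataclass
class Volume:
    """A 3-D scalar lattice with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_binary(self) -> bool:
        vals = np.unique(self.data)
        return np.isin(vals, (0, 1)).all()


@dataclass
class SeedSet:
    """Ordered seed voxel coordinates; order defines profile-matrix rows."""

    coords: np.ndarray  # (n, 3) int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 3)
        self.affine = np.asarray(self.affine, dtype=float)
        if len(self.coords) and len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("seed coordinates must be unique")

    def __len__(self) -> int:
        return len(self.coords)

    def world_coords(self) -> np.ndarray:
        """Seed positions in world (mm) space via the affine."""
        n = len(self.coords)
        hom = np.hstack([self.coords, np.ones((n, 1))])
        return (hom @ self.affine.T)[:, :3]


@dataclass
class ProfileMatrix:
    """Seed-by-voxel connectivity matrix with a column-to-voxel index map."""

    values: np.ndarray  # (n, m), entries in [0, 1]
    seed_ids: list
    column_map: np.ndarray  # (m,) linear voxel indices (Fortran order)
    grid_shape: tuple[int, int, int]
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("profile values must be 2-D")
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")
        self.column_map = np.asarray(self.column_map, dtype=np.int64)
        if self.values.shape[1] != len(self.column_map):
            raise ValueError("column_map length must equal number of columns")
        if self.values.shape[0] != len(self.seed_ids):
            raise ValueError("seed_ids length must equal number of rows")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# seed-surface extraction and masking


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _require_binary(vol: Volume, name: str) -> np.ndarray:
    data = np.asarray(vol.data)
    bad = np.setdiff1d(np.unique(data), [0, 1])
    if bad.size:
        raise ValueError(
            f"{name} must be binary; found values {bad[:10].tolist()}"
        )
    return data.astype(bool)


def extract_perimeter(mask: Volume, connectivity: int = 6) -> SeedSet:
    """Extract the perimeter voxels of a binary mask as a seed surface.

    A foreground voxel belongs to the perimeter when at least one of its
    neighbours (under the 6/18/26 neighbourhood) is background or lies
    outside the grid.  This is the mask minus its binary erosion with
    out-of-bounds treated as background.  Seeds are ordered
    lexicographically by ``(x, y, z)``.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    fg = _require_binary(mask, "mask")
    eroded = ndimage.binary_erosion(
        fg, structure=_CONNECTIVITY_STRUCTS[connectivity], border_value=0
    )
    perim = fg & ~eroded
    coords = np.argwhere(perim)  # lexicographic in (x, y, z)
    return SeedSet(coords=coords, affine=mask.affine)


def mask_seeds(seeds: SeedSet, region_mask: Volume) -> SeedSet:
    """Keep only seeds falling inside ``region_mask``; order preserved."""
    fg = _require_binary(region_mask, "region_mask")
    if not np.allclose(seeds.affine, region_mask.affine):
        raise ValueError("seed set and region mask are on different grids (affine mismatch)")
    if len(seeds) == 0:
        return SeedSet(coords=np.empty((0, 3), int), affine=seeds.affine, label=seeds.label)
    oob = (seeds.coords < 0).any(axis=1) | (
        seeds.coords >= np.array(region_mask.shape)
    ).any(axis=1)
    if oob.any():
        raise ValueError("seed coordinates lie outside the region mask grid")
    inside = fg[tuple(seeds.coords.T)]
    return SeedSet(coords=seeds.coords[inside], affine=seeds.affine, label=seeds.label)


def binarise_pv_map(pv: Volume) -> Volume:
    """Binarise a partial-volume map with no threshold (any positive -> 1)."""
    return Volume(data=(np.asarray(pv.data) > 0).astype(np.uint8), affine=pv.affine)


# ---------------------------------------------------------------------------
# per-seed volume preprocessing


def threshold_profile(vol: Volume, fraction: float = 0.0005) -> Volume:
    """Zero every voxel strictly below ``fraction`` of the volume maximum.

    The default fraction 5e-4 corresponds to thresholding at 0.05 percent
    of the maximum streamline count, a conventional noise floor for
    probabilistic-tractography visitation maps.  The maximum itself always
    survives, and the operation is idempotent at fixed fraction.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    data = np.asarray(vol.data, dtype=float)
    if not np.isfinite(data).any():
        raise ValueError("volume has no finite values")
    vmax = np.nanmax(data)
    if vmax == 0:
        warnings.warn("all-zero volume: threshold is 0, volume returned unchanged")
        return Volume(data=data.copy(), affine=vol.affine)
    out = data.copy()
    out[out < fraction * vmax] = 0.0
    return Volume(data=out, affine=vol.affine)


def downsample(vol: Volume, factor: int = 2) -> Volume:
    """Downsample by an integer factor using block maximum.

    Each output cell aggregates a ``factor**3`` block by maximum, so any
    visited voxel in a block keeps the block visited — binarised visitation
    support is preserved, which striding would not guarantee.  Trailing
    partial blocks are aggregated over their available voxels.  The affine
    is rescaled so the output grid covers the same world extent.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return Volume(data=vol.data.copy(), affine=vol.affine.copy())
    shape = np.array(vol.shape)
    if (factor > shape).any():
        raise ValueError(f"factor {factor} exceeds volume shape {vol.shape}")
    data = np.asarray(vol.data)
    pad = [(0, (-s) % factor) for s in shape]
    if any(p[1] for p in pad):
        data = np.pad(data, pad, mode="constant", constant_values=data.min())
    ns = np.array(data.shape) // factor
    blocks = data.reshape(ns[0], factor, ns[1], factor, ns[2], factor)
    out = blocks.max(axis=(1, 3, 5))
    new_affine = vol.affine.copy()
    scale = np.diag([factor, factor, factor, 1.0])
    new_affine = vol.affine @ scale
    # keep voxel-centre alignment: centre of output voxel 0 sits at the centre
    # of the corresponding input block
    offset = vol.affine[:3, :3] @ (np.full(3, (factor - 1) / 2.0))
    new_affine[:3, 3] = vol.affine[:3, 3] + offset
    return Volume(data=out, affine=new_affine)


def binarise_flatten(vol: Volume) -> np.ndarray:
    """Binarise (``> 0``) and flatten to a row vector, x varying fastest."""
    data = np.asarray(vol.data)
    return (data > 0).astype(np.uint8).ravel(order="F")


def unflatten(row: np.ndarray, column_map: np.ndarray, grid_shape: Sequence[int]) -> np.ndarray:
    """Place flattened values back into a 3-D grid via the column map."""
    out = np.zeros(tuple(grid_shape), dtype=float)
    idx = np.unravel_index(np.asarray(column_map, dtype=np.int64), tuple(grid_shape), order="F")
    out[idx] = row
    return out


def assemble_profiles(
    rows: Sequence[np.ndarray],
    seed_ids: Sequence,
    grid_shape: Sequence[int],
    space_tag: str = "",
) -> ProfileMatrix:
    """Concatenate per-seed row vectors into an ``n x m`` profile matrix."""
    if len(rows) == 0:
        raise ValueError("cannot assemble an empty list of profiles")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged profile rows: lengths {sorted(lengths)}")
    m = lengths.pop()
    expected = int(np.prod(grid_shape))
    if m != expected:
        raise ValueError(f"row length {m} does not match grid {tuple(grid_shape)} ({expected})")
    values = np.vstack([np.asarray(r, dtype=float) for r in rows])
    return ProfileMatrix(
        values=values,
        seed_ids=list(seed_ids),
        column_map=np.arange(m, dtype=np.int64),
        grid_shape=tuple(grid_shape),
        space_tag=space_tag,
    )


def drop_zero_columns(pm: ProfileMatrix) -> ProfileMatrix:
    """Remove all-zero columns; the column map records survivors."""
    keep = pm.values.any(axis=0)
    if not keep.any():
        warnings.warn("all columns are zero; resulting profile matrix is empty")
    return ProfileMatrix(
        values=pm.values[:, keep],
        seed_ids=list(pm.seed_ids),
        column_map=pm.column_map[keep],
        grid_shape=pm.grid_shape,
        space_tag=pm.space_tag,
    )


# ---------------------------------------------------------------------------
# persistence


def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    return Volume(data=np.asanyarray(img.dataobj), affine=img.affine)


def save_volume(vol: Volume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine), str(path))


def save_seedset(seeds: SeedSet, path: str | Path) -> None:
    """Write a seed table: commented affine header plus one voxel per line."""
    with open(path, "w") as fh:
        fh.write(f"# label: {seeds.label}\n")
        for row in seeds.affine:
            fh.write("# affine: " + " ".join(f"{v:.10g}" for v in row) + "\n")
        fh.write("x\ty\tz\n")
        for x, y, z in seeds.coords:
            fh.write(f"{x}\t{y}\t{z}\n")


def load_seedset(path: str | Path) -> SeedSet:
    label = ""
    affine_rows = []
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# label:"):
                label = line.split(":", 1)[1].strip()
            elif line.startswith("# affine:"):
                affine_rows.append([float(v) for v in line.split(":", 1)[1].split()])
            else:
                body.append(line)
    data = np.loadtxt(io.StringIO("".join(body)), skiprows=1, dtype=int, ndmin=2)
    affine = np.array(affine_rows) if len(affine_rows) == 4 else np.eye(4)
    if data.size == 0:
        data = np.empty((0, 3), int)
    return SeedSet(coords=data, affine=affine, label=label)


def save_profiles(pm: ProfileMatrix, path: str | Path) -> None:
    """Persist as MatrixMarket plus a tabular sidecar with the column map."""
    path = Path(path)
    sio.mmwrite(str(path), sparse.csr_matrix(pm.values))
    sidecar = path.with_suffix(path.suffix + ".meta.tsv")
    with open(sidecar, "w") as fh:
        fh.write(f"# grid_shape: {pm.grid_shape[0]} {pm.grid_shape[1]} {pm.grid_shape[2]}\n")
        fh.write(f"# space_tag: {pm.space_tag}\n")
        fh.write("# seed_ids: " + "\t".join(str(s) for s in pm.seed_ids) + "\n")
        fh.write("column\tvoxel_index\n")
        for c, v in enumerate(pm.column_map):
            fh.write(f"{c}\t{v}\n")


def load_profiles(path: str | Path) -> ProfileMatrix:
    path = Path(path)
    values = np.asarray(sio.mmread(str(path)).todense(), dtype=float)
    sidecar = path.with_suffix(path.suffix + ".meta.tsv")
    grid_shape = (0, 0, 0)
    space_tag = ""
    seed_ids: list = []
    col_idx = []
    with open(sidecar) as fh:
        for line in fh:
            if line.startswith("# grid_shape:"):
                grid_shape = tuple(int(v) for v in line.split(":", 1)[1].split())
            elif line.startswith("# space_tag:"):
                space_tag = line.split(":", 1)[1].strip()
            elif line.startswith("# seed_ids:"):
                seed_ids = line.split(":", 1)[1].strip().split("\t")
            elif line.startswith("column"):
                continue
            else:
                col_idx.append(int(line.split("\t")[1]))
    return ProfileMatrix(
        values=values,
        seed_ids=seed_ids,
        column_map=np.array(col_idx, dtype=np.int64),
        grid_shape=grid_shape,  # type: ignore[arg-type]
        space_tag=space_tag,
    )
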