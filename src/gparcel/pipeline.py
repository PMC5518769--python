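"""End-to-end orchestration of the parcellation stages.

A single :class:`RunConfig` drives every stage; all parameters are
serialised into each output directory (``run_config.yaml``) together with a
config hash, so two runs with equal hashes produce equal artifacts and any
result can be traced back to the exact settings that made it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .consistency import ConsistencyReport, run_validation
from .group import run_group_pipeline
from .profile_io import (ProfileMatrix, SeedSet, Volume, assemble_profiles,
                         binarise_flatten, downsample, drop_zero_columns,
                         load_profiles, load_seedset, load_volume,
                         save_profiles, save_seedset, save_volume,
                         threshold_profile)
from .projection import project_ordering
from .similarity import cosine_similarity_matrix, save_similarity
from .spectral import SpectralResult, reorder
from .synthetic import SyntheticCohort, make_cohort

__all__ = ["RunConfig", "run_individual", "run_group", "run_cohort_validation",
           "write_ordering", "read_ordering", "simulate_to_dir",
           "load_cohort_manifest"]

logger = logging.getLogger("gparcel")


@dataclass
class RunConfig:
    """Parameters for one analysis run.

    Defaults follow common practice for binarised tractography profiles:
    threshold at 0.05 percent of the per-volume maximum, downsample by a
    factor of 2, degree-normalised Laplacian, 6-neighbourhood perimeter.
    """

    threshold_fraction: float = 0.0005
    downsample_factor: int = 2
    normalised_laplacian: bool = True
    perimeter_connectivity: int = 6
    colour_map: str = "coolwarm"
    rng_seed: int = 0
    out_dir: str = "gparcel_out"
    extra: dict = field(default_factory=dict)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def dump(self, out_dir: Path) -> None:
        payload = asdict(self)
        payload["config_hash"] = self.hash()
        payload["package_version"] = __version__
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh)


def write_ordering(result: SpectralResult, path: str | Path) -> None:
    """Ordering table: seed id, matrix position, Fiedler value."""
    positions = result.positions()
    with open(path, "w") as fh:
        fh.write(f"# lambda2: {result.lambda2:.12g}\n")
        fh.write(f"# solver: {result.solver}\n")
        fh.write("seed_id\tposition\tfiedler\n")
        for i, sid in enumerate(result.seed_ids):
            fh.write(f"{sid}\t{positions[i]}\t{result.fiedler[i]:.12g}\n")


def read_ordering(path: str | Path) -> SpectralResult:
    lambda2 = float("nan")
    solver = ""
    seed_ids, positions, fiedler = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# lambda2:"):
                lambda2 = float(line.split(":", 1)[1])
            elif line.startswith("# solver:"):
                solver = line.split(":", 1)[1].strip()
            elif line.startswith("seed_id"):
                continue
            else:
                sid, pos, fv = line.rstrip("\n").split("\t")
                seed_ids.append(sid)
                positions.append(int(pos))
                fiedler.append(float(fv))
    positions = np.array(positions)
    ordering = np.empty(len(positions), dtype=int)
    ordering[positions] = np.arange(len(positions))
    return SpectralResult(ordering=ordering, lambda2=lambda2,
                          fiedler=np.array(fiedler),
                          degrees=np.full(len(positions), np.nan),
                          seed_ids=seed_ids, solver=solver)


def preprocess_volumes(volumes: list[Volume], seed_ids: list,
                       config: RunConfig) -> ProfileMatrix:
    """Per-seed volumes -> thresholded, downsampled, binarised profile rows."""
    rows = []
    grid_shape = None
    for vol in volumes:
        v = threshold_profile(vol, config.threshold_fraction)
        v = downsample(v, config.downsample_factor)
        if grid_shape is None:
            grid_shape = v.shape
        elif v.shape != grid_shape:
            raise ValueError("per-seed volumes are on mixed grids after downsampling")
        rows.append(binarise_flatten(v))
    pm = assemble_profiles(rows, seed_ids, grid_shape)
    logger.info("assembled profile matrix n=%d m=%d", pm.n, pm.m)
    return pm


def run_individual(pm: ProfileMatrix, seeds: SeedSet, reference: Volume,
                   config: RunConfig, out_dir: str | Path | None = None):
    """Individual path: drop zero columns -> similarity -> reorder -> project."""
    reduced = drop_zero_columns(pm)
    logger.info("zero-column removal: m=%d -> m'=%d", pm.m, reduced.m)
    sm = cosine_similarity_matrix(reduced)
    result = reorder(sm, normalised=config.normalised_laplacian)
    logger.info("reordered n=%d seeds, lambda2=%.6f (%s solver)",
                result.n, result.lambda2, result.solver)
    pmap = project_ordering(seeds, result, reference)
    if out_dir is not None:
        out = Path(out_dir)
        config.dump(out)
        save_profiles(reduced, out / "profiles.mtx")
        save_similarity(sm, out / "similarity.mtx")
        write_ordering(result, out / "ordering.tsv")
        with open(out / "lambda2.json", "w") as fh:
            json.dump({"lambda2": result.lambda2, "solver": result.solver,
                       "normalised": config.normalised_laplacian,
                       "n": result.n, "m": pm.m, "m_prime": reduced.m}, fh, indent=2)
        save_volume(pmap.volume, out / "parcellation.nii.gz")
    return reduced, sm, result, pmap


def run_group(cohort: SyntheticCohort | tuple, config: RunConfig,
              out_dir: str | Path | None = None):
    """Group path: template mapping -> averaging -> individual path."""
    if isinstance(cohort, SyntheticCohort):
        profiles = cohort.participant_profiles
        seeds = cohort.participant_seeds
        template = cohort.seeds
    else:
        profiles, seeds, template = cohort
    result, gpm = run_group_pipeline(profiles, seeds, template,
                                     normalised=config.normalised_laplacian)
    logger.info("group reorder: N=%d template seeds, k=%d participants, "
                "lambda2=%.6f", result.n, gpm.participant_count, result.lambda2)
    if out_dir is not None:
        out = Path(out_dir)
        config.dump(out)
        save_profiles(gpm.profiles, out / "group_profiles.mtx")
        write_ordering(result, out / "group_ordering.tsv")
        with open(out / "group_lambda2.json", "w") as fh:
            json.dump({"lambda2": result.lambda2, "solver": result.solver,
                       "participants": gpm.participant_count,
                       "n": result.n}, fh, indent=2)
    return result, gpm


def run_cohort_validation(cohort: SyntheticCohort | tuple, config: RunConfig,
                          out_dir: str | Path | None = None) -> ConsistencyReport:
    """Both consistency procedures; optionally write the report tables."""
    if isinstance(cohort, SyntheticCohort):
        profiles = cohort.participant_profiles
        seeds = cohort.participant_seeds
        template = cohort.seeds
    else:
        profiles, seeds, template = cohort
    report = run_validation(profiles, seeds, template,
                            normalised=config.normalised_laplacian)
    if out_dir is not None:
        out = Path(out_dir)
        config.dump(out)
        with open(out / "loo_rho.tsv", "w") as fh:
            fh.write("participant\trho\tp_value\n")
            for pid, rho, p in zip(report.participant_ids, report.rho,
                                   report.p_values):
                fh.write(f"{pid}\t{rho:.6f}\t{p:.3e}\n")
        with open(out / "rank_deviation.tsv", "w") as fh:
            fh.write("# normalisation: divided by (N-1), maximum displacement\n")
            fh.write("template_seed\tdeviation\n")
            for i, d in enumerate(report.deviation):
                fh.write(f"tmpl_{i}\t{d:.6f}\n")
    return report


def simulate_to_dir(out_dir: str | Path, **kwargs) -> SyntheticCohort:
    """Generate a cohort and persist it (seed tables, profiles, truth, manifest)."""
    cohort = make_cohort(**kwargs)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_seedset(cohort.seeds, out / "template_gwi.tsv")
    manifest = {"template": "template_gwi.tsv", "participants": []}
    for i, (pm, ss) in enumerate(zip(cohort.participant_profiles,
                                     cohort.participant_seeds)):
        pdir = out / f"participant_{i:02d}"
        pdir.mkdir(exist_ok=True)
        save_profiles(pm, pdir / "profiles.mtx")
        save_seedset(ss, pdir / "seeds.tsv")
        manifest["participants"].append(
            {"id": ss.label, "profiles": f"participant_{i:02d}/profiles.mtx",
             "seeds": f"participant_{i:02d}/seeds.tsv"})
    truth = cohort.truth
    with open(out / "planted_truth.tsv", "w") as fh:
        fh.write(f"# regime: {truth.regime}\n# noise: {truth.noise}\n")
        fh.write("seed\tt\tcluster\t" +
                 "\t".join(f"w{k}" for k in range(truth.weights.shape[1])) + "\n")
        for i in range(len(truth.t)):
            cl = truth.cluster[i] if truth.cluster is not None else ""
            ws = "\t".join(f"{w:.6f}" for w in truth.weights[i])
            fh.write(f"seed_{i}\t{truth.t[i]:.6f}\t{cl}\t{ws}\n")
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return cohort


def load_cohort_manifest(manifest_path: str | Path):
    """Read a cohort manifest back into (profiles, seeds, template)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    template = load_seedset(base / manifest["template"])
    profiles, seeds = [], []
    for entry in manifest["participants"]:
        profiles.append(load_profiles(base / entry["profiles"]))
        seeds.append(load_seedset(base / entry["seeds"]))
    return profiles, seeds, template
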