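"""Synthetic study generator: volumes and cohorts with the structure the
analysis assumes, so every stage is testable without any imaging data.

What it emulates
----------------
* Per-subject binary *tract* maps: tubes of fixed radius around a
  per-subject jittered centerline (stand-ins for binarised
  tractography output on the common grid).
* Per-subject *activation* maps: unions of spherical blobs around
  jittered node centres, restricted to a gray-matter mask.
* Left-hemisphere *lesion masks*: 6-connected regions grown from a seed
  voxel by random-priority flood fill, giving irregular non-convex
  shapes of a requested volume.
* A *cohort* whose behavioral outcomes decrease monotonically in lesion
  load with bimodal severity structure:

      outcome = max(0, beta0 + beta1 * LL^(1/3) + eps),  eps ~ N(0, sigma)

  with beta1 < 0. CIUs/min is additionally capped at Words/min (a CIU
  is a counted word) and BNT is rounded and clipped to 0..15.

One integer seed drives a spawned stream hierarchy (maps, lesions,
outcomes, demographics), so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import heapq
import json

import numpy as np
import pandas as pd

from .canonical import ProbabilisticMap, aggregate_subject_maps, combine_maps, mask_gray_matter
from .cohort import CohortTable
from .errors import GeometryError
from .loads import LesionMask, compute_lesion_load
from .volumetric import BinaryVolume, VoxelGrid, default_grid, write_volume

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_subject_tract_maps",
    "generate_subject_activation_maps",
    "gray_matter_mask",
    "generate_canonical_maps",
    "generate_lesion_mask",
    "generate_cohort",
    "simulate_cohort_table",
    "write_study",
]

#: default outcome-model coefficients (beta0, beta1, noise SD) per measure,
#: calibrated to the scale of the reference cohort: intercepts near the
#: unlesioned means, slopes steep enough that loads beyond ~4 cc push
#: fluency toward the floor.
DEFAULT_OUTCOME_MODEL = {
    "words_per_min": (60.0, -22.0, 10.0),
    "cius_per_min": (35.0, -16.0, 6.0),
    "bnt": (14.0, -5.5, 2.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_mm: float = 2.0
    n_map_subjects: int = 12
    n_patients: int = 50
    #: dorsal tract centerline in voxel coordinates (left hemisphere)
    tract_centerline: tuple[tuple[float, float, float], ...] = (
        (14.0, 12.0, 30.0),
        (13.0, 22.0, 34.0),
        (14.0, 34.0, 33.0),
        (16.0, 44.0, 26.0),
    )
    tract_radius_mm: float = 7.0
    subject_jitter_mm: float = 2.0
    #: activation blobs: ((centre voxel), radius mm)
    activation_nodes: tuple[tuple[tuple[float, float, float], float], ...] = (
        ((15.0, 12.0, 26.0), 7.0),
        ((15.0, 44.0, 22.0), 7.0),
        ((12.0, 28.0, 38.0), 6.0),
    )
    lesion_size_range_cc: tuple[float, float] = (15.0, 250.0)
    #: fraction of patients whose lesion is large and placed on the tract
    severity_mixture: float = 0.7
    #: load ranges (cc) of the two mixture components in the table-level
    #: simulator; the defaults straddle the ~4 cc decision region the way
    #: the reference cohort does
    severe_load_range_cc: tuple[float, float] = (4.0, 12.0)
    mild_load_range_cc: tuple[float, float] = (0.0, 3.5)
    outcome_model: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MODEL))
    seed: int = 0

    def grid(self) -> VoxelGrid:
        return default_grid(self.grid_shape, self.voxel_mm)


@dataclass(frozen=True)
class SyntheticCohort:
    cohort: CohortTable
    lesion_masks: dict
    maps: dict
    truth: dict


def _streams(seed: int) -> dict:
    kids = np.random.SeedSequence(seed).spawn(4)
    names = ("maps", "lesions", "outcomes", "demographics")
    return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


def _polyline_points(ctrl: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Densely sample a piecewise-linear curve through control points."""
    pts = []
    for a, b in zip(ctrl[:-1], ctrl[1:]):
        seg = np.linalg.norm(b - a)
        n = max(2, int(np.ceil(seg / step)))
        t = np.linspace(0, 1, n, endpoint=False)[:, None]
        pts.append(a + t * (b - a))
    pts.append(ctrl[-1][None])
    return np.concatenate(pts)


def _tube(grid: VoxelGrid, ctrl_vox: np.ndarray, radius_mm: float, voxel_mm: float) -> BinaryVolume:
    from scipy.spatial import cKDTree

    radius_vox = radius_mm / voxel_mm
    lo, hi = ctrl_vox.min(axis=0), ctrl_vox.max(axis=0)
    if (lo < radius_vox - 0.5).any() or (hi > np.asarray(grid.shape) - 1 - radius_vox + 0.5).any():
        raise GeometryError(
            f"tube of radius {radius_mm} mm around {ctrl_vox.tolist()} exits the grid {grid.shape}"
        )
    tree = cKDTree(_polyline_points(ctrl_vox))
    # only query voxels inside the bounding box of the tube
    lo_i = np.maximum(0, np.floor(lo - radius_vox).astype(int))
    hi_i = np.minimum(np.asarray(grid.shape) - 1, np.ceil(hi + radius_vox).astype(int))
    xs, ys, zs = [np.arange(a, b + 1) for a, b in zip(lo_i, hi_i)]
    box = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = tree.query(box)
    vals = np.zeros(grid.shape, dtype=np.uint8)
    inside = box[d <= radius_vox]
    vals[inside[:, 0], inside[:, 1], inside[:, 2]] = 1
    return BinaryVolume(grid, vals)


def generate_subject_tract_maps(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[BinaryVolume]:
    """Binary tubes around per-subject jittered centerlines (deterministic
    under a fixed config seed)."""
    rng = rng if rng is not None else _streams(config.seed)["maps"]
    grid = config.grid()
    ctrl = np.asarray(config.tract_centerline, dtype=float)
    jitter_vox = config.subject_jitter_mm / config.voxel_mm
    out = []
    for _ in range(config.n_map_subjects):
        disp = rng.normal(0.0, jitter_vox, size=ctrl.shape) if jitter_vox > 0 else 0.0
        out.append(_tube(grid, ctrl + disp, config.tract_radius_mm, config.voxel_mm))
    return out


def generate_subject_activation_maps(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[BinaryVolume]:
    """Unions of spherical blobs around jittered activation nodes."""
    rng = rng if rng is not None else _streams(config.seed)["maps"]
    grid = config.grid()
    jitter_vox = config.subject_jitter_mm / config.voxel_mm
    idx = np.indices(grid.shape).reshape(3, -1).T
    out = []
    for _ in range(config.n_map_subjects):
        vals = np.zeros(grid.shape, dtype=np.uint8)
        for centre, radius_mm in config.activation_nodes:
            c = np.asarray(centre, float) + (
                rng.normal(0.0, jitter_vox, size=3) if jitter_vox > 0 else 0.0
            )
            r = radius_mm / config.voxel_mm
            d2 = ((idx - c) ** 2).sum(axis=1)
            hit = idx[d2 <= r * r]
            vals[hit[:, 0], hit[:, 1], hit[:, 2]] = 1
        out.append(BinaryVolume(grid, vals))
    return out


def gray_matter_mask(config: SyntheticConfig) -> BinaryVolume:
    """A crude cortical-ribbon stand-in: everything within the outer third
    of the volume along x plus the activation-node neighbourhoods."""
    grid = config.grid()
    vals = np.zeros(grid.shape, dtype=np.uint8)
    third = max(1, grid.shape[0] // 3)
    vals[:third] = 1
    vals[-third:] = 1
    idx = np.indices(grid.shape).reshape(3, -1).T
    for centre, radius_mm in config.activation_nodes:
        r = (radius_mm + 2.0) / config.voxel_mm
        d2 = ((idx - np.asarray(centre, float)) ** 2).sum(axis=1)
        hit = idx[d2 <= r * r]
        vals[hit[:, 0], hit[:, 1], hit[:, 2]] = 1
    return BinaryVolume(grid, vals)


#: ventral comparison tracts, offset from the dorsal centerline
_VENTRAL_OFFSETS = {"EMC": np.array([2.0, 0.0, -12.0]), "UF": np.array([4.0, -4.0, -16.0])}


def generate_canonical_maps(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> dict[str, ProbabilisticMap]:
    """The full canonical map set: AF, fGM (gray-matter-masked), AF+fGM,
    EMC and UF."""
    rng = rng if rng is not None else _streams(config.seed)["maps"]
    maps: dict[str, ProbabilisticMap] = {}
    maps["AF"] = aggregate_subject_maps(generate_subject_tract_maps(config, rng), "AF")
    fgm = aggregate_subject_maps(generate_subject_activation_maps(config, rng), "fGM")
    maps["fGM"] = mask_gray_matter(fgm, gray_matter_mask(config))
    maps["AF+fGM"] = combine_maps(maps["AF"], maps["fGM"])
    ctrl = np.asarray(config.tract_centerline, dtype=float)
    jitter_vox = config.subject_jitter_mm / config.voxel_mm
    for label, off in _VENTRAL_OFFSETS.items():
        subs = []
        for _ in range(config.n_map_subjects):
            disp = rng.normal(0.0, jitter_vox, size=ctrl.shape) if jitter_vox > 0 else 0.0
            subs.append(
                _tube(config.grid(), ctrl + off + disp, config.tract_radius_mm * 0.75, config.voxel_mm)
            )
        maps[label] = aggregate_subject_maps(subs, label)
    return maps


def generate_lesion_mask(
    config: SyntheticConfig,
    target_cc: float,
    center: tuple[int, int, int],
    seed: int | np.random.Generator,
) -> LesionMask:
    """Grow a 6-connected lesion from ``center`` by random-priority flood
    fill until its volume reaches ``target_cc`` (within one voxel)."""
    grid = config.grid()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # relative slack absorbs float error in the cc -> voxel conversion
    target_vox = int(np.ceil(target_cc / grid.voxel_volume_cc * (1 - 1e-9)))
    shape = grid.shape
    center = tuple(int(c) for c in center)
    if not all(0 <= c < s for c, s in zip(center, shape)):
        raise GeometryError(f"lesion centre {center} outside grid {shape}")
    if target_vox > int(np.prod(shape)):
        raise GeometryError(f"target volume {target_cc} cc exceeds the grid")
    # Priorities are distance-from-seed times a random factor: pure random
    # priorities degenerate to invasion percolation (fractal, ~30% fill),
    # while the distance bias keeps the region compact with an irregular,
    # non-convex boundary.
    roughness = 0.6
    c = np.asarray(center, float)

    def _priority(vox) -> float:
        d = float(np.linalg.norm(np.asarray(vox, float) - c))
        return d * (1.0 + roughness * rng.random())

    vals = np.zeros(shape, dtype=np.uint8)
    heap = [(0.0, center)]
    seen = {center}
    grown = 0
    while heap and grown < target_vox:
        _, (i, j, k) = heapq.heappop(heap)
        vals[i, j, k] = 1
        grown += 1
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = (i + di, j + dj, k + dk)
            if (
                0 <= nb[0] < shape[0]
                and 0 <= nb[1] < shape[1]
                and 0 <= nb[2] < shape[2]
                and nb not in seen
            ):
                seen.add(nb)
                heapq.heappush(heap, (_priority(nb), nb))
    if grown < target_vox:
        raise GeometryError(f"grid exhausted at {grown} voxels before reaching {target_cc} cc")
    return LesionMask(grid, vals)


def _draw_outcomes(af_ll: np.ndarray, model: dict, rng: np.random.Generator) -> pd.DataFrame:
    x = np.cbrt(af_ll)
    out = {}
    censored = {}
    for name, (b0, b1, sigma) in model.items():
        raw = b0 + b1 * x + rng.normal(0.0, sigma, size=af_ll.size)
        clipped = np.maximum(0.0, raw)
        censored[name] = float((raw < 0).mean())
        out[name] = clipped
    df = pd.DataFrame(out)
    if {"cius_per_min", "words_per_min"} <= set(df.columns):
        df["cius_per_min"] = np.minimum(df["cius_per_min"], df["words_per_min"])
    if "bnt" in df.columns:
        df["bnt"] = np.clip(np.rint(df["bnt"]), 0, 15).astype(int)
    df.attrs["censored_fraction"] = censored
    return df


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Full volumetric synthetic study: maps, per-patient lesions, loads
    computed through the lesion-load module, and outcomes drawn from the
    generative model. The cohort's load columns are exactly the
    recomputed loads of the stored masks and maps."""
    streams = _streams(config.seed)
    maps = generate_canonical_maps(config, streams["maps"])
    grid = config.grid()
    rng_l = streams["lesions"]
    lo_cc, hi_cc = config.lesion_size_range_cc
    ctrl = np.asarray(config.tract_centerline, dtype=float)
    masks: dict[str, LesionMask] = {}
    rows = []
    for i in range(config.n_patients):
        pid = str(i + 1)
        severe = rng_l.random() < config.severity_mixture
        if severe:
            target = rng_l.uniform((lo_cc + hi_cc) / 2, hi_cc)
            centre = ctrl[rng_l.integers(len(ctrl))] + rng_l.normal(0, 1.5, 3)
        else:
            target = rng_l.uniform(lo_cc, (lo_cc + hi_cc) / 3)
            centre = ctrl.mean(axis=0) + np.array([10.0, 0.0, -8.0]) + rng_l.normal(0, 2.0, 3)
        centre = np.clip(np.rint(centre), 1, np.asarray(grid.shape) - 2).astype(int)
        mask = generate_lesion_mask(config, target, tuple(centre), rng_l)
        mask = LesionMask(mask.grid, mask.values, patient_id=pid)
        masks[pid] = mask
        row = {"patient_id": pid, "true_severe": severe}
        for label, col in (
            ("AF", "af_ll_cc"),
            ("fGM", "fgm_ll_cc"),
            ("AF+fGM", "af_fgm_ll_cc"),
            ("EMC", "emc_ll_cc"),
            ("UF", "uf_ll_cc"),
        ):
            row[col] = compute_lesion_load(mask, maps[label]).load_cc
        row["lesion_volume_cc"] = mask.n_voxels * grid.voxel_volume_cc
        rows.append(row)
    df = pd.DataFrame(rows)
    rng_d = streams["demographics"]
    df["gender"] = np.where(rng_d.random(config.n_patients) < 0.2, "F", "M")
    df["age_years"] = np.clip(np.rint(rng_d.normal(55, 11, config.n_patients)), 25, 85).astype(int)
    df["months_post_stroke"] = np.rint(6 + rng_d.exponential(18, config.n_patients)).astype(int)
    outcomes = _draw_outcomes(df["af_ll_cc"].to_numpy(), config.outcome_model, streams["outcomes"])
    df = pd.concat([df, outcomes], axis=1)
    truth = {
        "config_seed": config.seed,
        "outcome_model": {k: list(v) for k, v in config.outcome_model.items()},
        "severity_mixture": config.severity_mixture,
        "true_severe": df["true_severe"].tolist(),
        "censored_fraction": outcomes.attrs["censored_fraction"],
    }
    cohort_df = df.drop(columns=["true_severe"])
    return SyntheticCohort(
        cohort=CohortTable(cohort_df), lesion_masks=masks, maps=maps, truth=truth
    )


def simulate_cohort_table(
    config: SyntheticConfig, n: int | None = None, seed: int | None = None
) -> tuple[CohortTable, dict]:
    """Table-level simulator: loads drawn directly from the bimodal
    severity mixture and outcomes from the generative model, skipping
    volumetric generation. Used for large parameter-recovery runs where
    only the statistical structure matters."""
    n = n or config.n_patients
    rng = np.random.default_rng(config.seed if seed is None else seed)
    severe = rng.random(n) < config.severity_mixture
    af = np.where(
        severe,
        rng.uniform(*config.severe_load_range_cc, n),
        rng.uniform(*config.mild_load_range_cc, n),
    )
    lesion_vol = af * rng.uniform(15.0, 25.0, n) + rng.uniform(10.0, 30.0, n)
    df = pd.DataFrame(
        {
            "patient_id": [str(i + 1) for i in range(n)],
            "gender": np.where(rng.random(n) < 0.2, "F", "M"),
            "age_years": np.clip(np.rint(rng.normal(55, 11, n)), 25, 85).astype(int),
            "months_post_stroke": np.rint(6 + rng.exponential(18, n)).astype(int),
            "lesion_volume_cc": lesion_vol,
            "af_ll_cc": af,
            "fgm_ll_cc": np.minimum(lesion_vol, af * rng.uniform(1.5, 3.0, n)),
            "emc_ll_cc": np.minimum(lesion_vol, af * rng.uniform(0.2, 0.6, n)),
            "uf_ll_cc": np.minimum(lesion_vol, af * rng.uniform(0.2, 0.6, n)),
        }
    )
    df["af_fgm_ll_cc"] = np.minimum(lesion_vol, df["af_ll_cc"] + df["fgm_ll_cc"])
    outcomes = _draw_outcomes(af, config.outcome_model, rng)
    df = pd.concat([df, outcomes], axis=1)
    truth = {
        "outcome_model": {k: list(v) for k, v in config.outcome_model.items()},
        "true_severe": severe.tolist(),
        "censored_fraction": outcomes.attrs["censored_fraction"],
    }
    return CohortTable(df), truth


def write_study(study: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a complete synthetic study: NIfTI maps and lesions, a cohort
    CSV in the reference-table schema, and the generating truth as JSON."""
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    (out / "lesions").mkdir(parents=True, exist_ok=True)
    from .canonical import write_map

    for label, pmap in study.maps.items():
        write_map(pmap, out / "maps" / f"{label.replace('+', '_')}.nii.gz")
    for pid, mask in study.lesion_masks.items():
        write_volume(BinaryVolume(mask.grid, mask.values), out / "lesions" / f"patient_{pid}.nii.gz")
    study.cohort.df.to_csv(out / "cohort.csv", index=False)
    (out / "truth.json").write_text(json.dumps(study.truth, indent=2))
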