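"""Canonical probabilistic maps built from per-subject binary maps.

A canonical map records, per voxel, how many of N healthy control
subjects' binarised tract (or activation) maps contain that voxel; the
voxel's probability of belonging to the structure is count/N. The paper
workflow this mirrors: per-subject tractography output is trimmed at
the 50th percentile of its within-tract value distribution, binarised,
and summed across the 12 subjects; functional activation maps are
restricted to a gray-matter mask before summation; the combined
structural+functional map is the (capped) sum of two canonical maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyMapError, GridMismatchError
from .volumetric import (
    BinaryVolume,
    IntensityVolume,
    VoxelGrid,
    assert_same_grid,
    read_volume,
    write_volume,
)

__all__ = [
    "ProbabilisticMap",
    "threshold_percentile",
    "aggregate_subject_maps",
    "mask_gray_matter",
    "combine_maps",
    "write_map",
    "read_map",
]


@dataclass(frozen=True)
class ProbabilisticMap:
    """Voxelwise overlap counts 0..n_subjects over a grid."""

    grid: VoxelGrid
    counts: np.ndarray = field(repr=False)
    n_subjects: int
    label: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != self.grid.shape:
            raise GridMismatchError(
                f"counts shape {counts.shape} != grid shape {self.grid.shape}"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if counts.min() < 0 or counts.max() > self.n_subjects:
            raise ValueError(
                f"counts must lie in 0..{self.n_subjects}, "
                f"got range [{counts.min()}, {counts.max()}]"
            )
        object.__setattr__(self, "counts", counts.astype(np.int32))

    @property
    def probability(self) -> np.ndarray:
        """Per-voxel probability counts / n_subjects, in [0, 1]."""
        return self.counts / float(self.n_subjects)

    def probability_weighted_volume_cc(self) -> float:
        """Sum of per-voxel probability times voxel volume — the map's 'expected' volume."""
        return float(self.probability.sum()) * self.grid.voxel_volume_cc


def threshold_percentile(vol: IntensityVolume, percentile: float) -> BinaryVolume:
    """Keep voxels at or above the given percentile of the *nonzero* values.

    Tract-probability volumes are mostly zero, so the percentile is
    taken over the nonzero value distribution only (linear-interpolation
    convention); the comparison is ``>=`` so the result is never empty.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    nonzero = vol.values[vol.values > 0]
    if nonzero.size == 0:
        raise EmptyMapError("cannot threshold an all-zero volume")
    cut = float(np.percentile(nonzero, percentile))
    # tiny relative slack so limiting percentiles (q -> 0) keep boundary voxels
    slack = 1e-9 * max(1.0, float(np.abs(nonzero).max()))
    return BinaryVolume(vol.grid, (vol.values >= cut - slack).astype(np.uint8))


def aggregate_subject_maps(maps: Sequence[BinaryVolume], label: str) -> ProbabilisticMap:
    """Voxelwise sum of per-subject binary maps into a canonical map."""
    if len(maps) == 0:
        raise ValueError("need at least one subject map")
    first = maps[0]
    counts = np.zeros(first.grid.shape, dtype=np.int32)
    for m in maps:
        assert_same_grid(first, m)
        counts += m.values
    return ProbabilisticMap(first.grid, counts, n_subjects=len(maps), label=label)


def mask_gray_matter(pmap: ProbabilisticMap, gm: BinaryVolume) -> ProbabilisticMap:
    """Zero counts outside a gray-matter mask; n_subjects unchanged."""
    assert_same_grid(pmap, gm)
    return ProbabilisticMap(
        pmap.grid, pmap.counts * gm.values, n_subjects=pmap.n_subjects, label=pmap.label
    )


def combine_maps(a: ProbabilisticMap, b: ProbabilisticMap) -> ProbabilisticMap:
    """Sum two canonical maps on the probability scale, capped at 1.

    Per-voxel probability p = min(1, a/N + b/N), stored back as counts
    round(p*N). Requires equal N. The cap keeps the combined map
    interpretable as a probability while preserving plain summation
    wherever the components do not saturate.
    """
    assert_same_grid(a, b)
    if a.n_subjects != b.n_subjects:
        raise ValueError(
            f"cannot combine maps with different n_subjects ({a.n_subjects} vs {b.n_subjects})"
        )
    n = a.n_subjects
    p = np.minimum(1.0, a.probability + b.probability)
    counts = np.rint(p * n).astype(np.int32)
    return ProbabilisticMap(a.grid, counts, n_subjects=n, label=f"{a.label}+{b.label}")


def write_map(pmap: ProbabilisticMap, path: str | Path) -> None:
    """Write counts as an integer NIfTI plus a JSON sidecar with label and N."""
    path = Path(path)
    write_volume(IntensityVolume(pmap.grid, pmap.counts.astype(float)), path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = sidecar.with_name(sidecar.name + ".json")
    sidecar.write_text(json.dumps({"label": pmap.label, "n_subjects": pmap.n_subjects}))


def read_map(path: str | Path, n_subjects: int | None = None, label: str | None = None) -> ProbabilisticMap:
    """Read a canonical map written by :func:`write_map`.

    ``n_subjects``/``label`` override the sidecar; if no sidecar exists
    they are required.
    """
    path = Path(path)
    vol = read_volume(path)
    sidecar = path.with_suffix("").with_suffix("")
    sidecar = sidecar.with_name(sidecar.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        n_subjects = n_subjects or meta["n_subjects"]
        label = label or meta["label"]
    if n_subjects is None:
        raise ValueError(f"no sidecar for {path}; n_subjects must be given")
    counts = np.rint(vol.values).astype(np.int32)
    return ProbabilisticMap(vol.grid, counts, n_subjects=n_subjects, label=label or path.stem)
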