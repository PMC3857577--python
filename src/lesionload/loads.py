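"""Lesion load: probability-weighted overlap between a lesion and a canonical map.

The central statistic of the package. For a binary lesion mask L and a
canonical map with per-voxel counts I over N subjects,

    LL (cc) = sum over voxels v with L(v)=1 of (I(v)/N) * voxel_volume_cc

i.e. each intersecting voxel contributes its probability of belonging
to the structure, scaled to cc. A lesion load is therefore bounded by
both the lesion volume and the map's probability-weighted volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .canonical import ProbabilisticMap
from .errors import GridMismatchError
from .volumetric import BinaryVolume, VoxelGrid, assert_same_grid

__all__ = [
    "LesionMask",
    "LesionLoadValue",
    "compute_lesion_load",
    "compute_lesion_volume",
    "batch_lesion_loads",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LesionMask:
    """A patient's binary lesion mask on the common grid."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)
    patient_id: str = ""

    def __post_init__(self) -> None:
        bv = BinaryVolume(self.grid, self.values)  # validates shape and {0,1}
        object.__setattr__(self, "values", bv.values)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class LesionLoadValue:
    patient_id: str
    map_label: str
    load_cc: float
    lesion_volume_cc: float
    #: probability-weighted voxel count (load_cc / voxel_volume_cc), kept for transparency
    weighted_voxels: float


def compute_lesion_load(lesion: LesionMask, pmap: ProbabilisticMap) -> LesionLoadValue:
    """Probability-weighted lesion-overlap load in cc.

    An empty lesion yields 0 with a logged warning (keeps batch runs
    alive); a grid mismatch raises.
    """
    assert_same_grid(lesion, pmap)
    if lesion.n_voxels == 0:
        log.warning("empty lesion mask for patient %r: load is 0", lesion.patient_id)
    inter = pmap.counts[lesion.values == 1]
    weighted = float(inter.sum()) / pmap.n_subjects
    vv = lesion.grid.voxel_volume_cc
    return LesionLoadValue(
        patient_id=lesion.patient_id,
        map_label=pmap.label,
        load_cc=weighted * vv,
        lesion_volume_cc=lesion.n_voxels * vv,
        weighted_voxels=weighted,
    )


def compute_lesion_volume(lesion: LesionMask) -> float:
    """Total lesion volume in cc (voxel count times voxel volume)."""
    return lesion.n_voxels * lesion.grid.voxel_volume_cc


def batch_lesion_loads(
    lesions: Sequence[LesionMask], maps: Sequence[ProbabilisticMap]
) -> pd.DataFrame:
    """One row per (patient, map), ordered by patient then map label.

    Errors from individual pairs are re-raised with the pair identified.
    """
    rows = []
    for lesion in sorted(lesions, key=lambda l: l.patient_id):
        for pmap in sorted(maps, key=lambda m: m.label):
            try:
                ll = compute_lesion_load(lesion, pmap)
            except GridMismatchError as exc:
                raise GridMismatchError(
                    f"patient {lesion.patient_id!r} vs map {pmap.label!r}: {exc}"
                ) from exc
            rows.append(
                {
                    "patient_id": ll.patient_id,
                    "map_label": ll.map_label,
                    "load_cc": ll.load_cc,
                    "lesion_volume_cc": ll.lesion_volume_cc,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "map_label", "load_cc", "lesion_volume_cc"])
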