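"""Voxel morphometry: volumes, bone volume fraction and median attenuation.

Per anatomical region (and whole-sample) the pipeline reports

* ``TV`` (mm^3) — total volume of the region of interest: the filled
  periosteal envelope, marrow included;
* ``BV`` (mm^3) — bone volume, cortical and trabecular together;
* ``Ct.BV`` / ``Tb.BV`` (mm^3) — cortical / trabecular bone volume;
* ``BV/TV`` (%) — bone volume fraction, 100 * BV / TV;
* ``mu.B`` / ``mu.Ct`` / ``mu.Tb`` (mm^-1) — **median** linear attenuation
  coefficient over the voxels of each bone class (median, not mean: robust to
  partial-volume tails at class boundaries).

Volumes are voxel counts times the voxel volume; whole-sample values are
computed from the full grids, never by summing rounded regional values.
Regions whose trabecular content is a negligible fraction of the total
trabecular bone (diaphyses of long bones, typically 1-2 %) have their
trabecular fields reported as absent rather than as unstable small numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .compartments import LabelMap, RegionPartition
from .io import Volume

__all__ = [
    "MorphometryRecord",
    "WHOLE_SAMPLE",
    "PARAMETER_ATTRS",
    "compute_morphometry",
    "bone_volume_fraction",
    "apply_trabecular_exclusion",
]

WHOLE_SAMPLE = "whole sample"

#: Default exclusion threshold: regions holding less than this fraction of the
#: total trabecular volume get absent (not zero) trabecular fields.
DEFAULT_EXCLUSION_FRACTION = 0.02

#: Map from conventional parameter names to record attributes.
PARAMETER_ATTRS = {
    "TV": "TV",
    "BV": "BV",
    "Ct.BV": "Ct_BV",
    "Tb.BV": "Tb_BV",
    "BV/TV": "BV_TV",
    "mu.B": "mu_B",
    "mu.Ct": "mu_Ct",
    "mu.Tb": "mu_Tb",
}


@dataclass
class MorphometryRecord:
    """Morphometric parameters of one region of one scan.

    ``None`` fields mean *absent* (excluded or empty class), never zero.
    """

    sample_id: str
    day: int
    region: str
    TV: float  # mm^3
    BV: float  # mm^3
    Ct_BV: float  # mm^3
    Tb_BV: float | None  # mm^3, absent where trabecular content is excluded
    BV_TV: float | None  # percent
    mu_B: float | None  # mm^-1
    mu_Ct: float | None  # mm^-1
    mu_Tb: float | None  # mm^-1

    def __post_init__(self) -> None:
        if not (0 <= self.BV <= self.TV + 1e-9):
            raise ValueError(f"need 0 <= BV <= TV, got BV={self.BV}, TV={self.TV}")
        for name in ("mu_B", "mu_Ct", "mu_Tb"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def get(self, parameter: str) -> float | None:
        """Value by conventional name ('TV', 'Ct.BV', 'mu.Ct', ...)."""
        return getattr(self, PARAMETER_ATTRS[parameter])


def _median_or_none(values: np.ndarray) -> float | None:
    return float(np.median(values)) if values.size else None


def _region_record(sample_id: str, day: int, region: str, grid: np.ndarray,
                   labels: LabelMap, zslice: slice, voxel_volume: float) -> MorphometryRecord:
    env = labels.envelope[zslice]
    cort = labels.cortical[zslice]
    trab = labels.trabecular[zslice]
    bone = cort | trab
    vals = grid[zslice]

    tv = float(env.sum()) * voxel_volume
    ct_bv = float(cort.sum()) * voxel_volume
    tb_bv = float(trab.sum()) * voxel_volume
    bv = ct_bv + tb_bv
    return MorphometryRecord(
        sample_id=sample_id,
        day=day,
        region=region,
        TV=tv,
        BV=bv,
        Ct_BV=ct_bv,
        Tb_BV=tb_bv,
        BV_TV=bone_volume_fraction(bv, tv) if tv > 0 else None,
        mu_B=_median_or_none(vals[bone]),
        mu_Ct=_median_or_none(vals[cort]),
        mu_Tb=_median_or_none(vals[trab]),
    )


def compute_morphometry(volume: Volume, labels: LabelMap,
                        partition: RegionPartition) -> list[MorphometryRecord]:
    """Morphometry for the whole sample and each anatomical region.

    Returns four records (whole sample, proximal EM-zone, diaphysis, distal
    EM-zone).  Volumes are voxel counts scaled by the voxel volume; attenuation
    coefficients are medians over the class voxels; empty classes yield absent
    medians and zero volumes.

    Raises
    ------
    ValueError
        If the label map or partition does not match the volume's grid.
    """
    if labels.labels.shape != volume.grid.shape:
        raise ValueError(
            f"label map shape {labels.labels.shape} does not match "
            f"volume shape {volume.grid.shape}"
        )
    if partition.n_slices != volume.grid.shape[0]:
        raise ValueError("partition covers a different number of axial slices")

    voxvol = volume.voxel_volume_mm3
    records = [
        _region_record(volume.sample_id, volume.day, WHOLE_SAMPLE, volume.grid,
                       labels, slice(None), voxvol)
    ]
    for region, zsl in partition.region_slices().items():
        records.append(
            _region_record(volume.sample_id, volume.day, region, volume.grid,
                           labels, zsl, voxvol)
        )
    return records


def bone_volume_fraction(BV: float, TV: float) -> float:
    """Bone volume fraction BV/TV in percent: ``100 * BV / TV``.

    Raises
    ------
    ValueError
        If ``TV <= 0`` or ``BV`` falls outside ``[0, TV]``.
    """
    if TV <= 0:
        raise ValueError(f"TV must be positive, got {TV}")
    if not (0 <= BV <= TV * (1 + 1e-12)):
        raise ValueError(f"need 0 <= BV <= TV, got BV={BV}, TV={TV}")
    return 100.0 * BV / TV


def apply_trabecular_exclusion(
    records: Sequence[MorphometryRecord],
    threshold_fraction: float = DEFAULT_EXCLUSION_FRACTION,
) -> list[MorphometryRecord]:
    """Blank trabecular fields of regions with negligible trabecular content.

    For every region whose ``Tb.BV`` is less than ``threshold_fraction`` of
    the whole-sample ``Tb.BV`` (same sample and day), ``Tb.BV`` and ``mu.Tb``
    are marked absent.  All other fields — and the whole-sample record — are
    untouched.  A no-op when nothing qualifies or no whole-sample reference
    exists.
    """
    totals: dict[tuple[str, int], float] = {}
    for r in records:
        if r.region == WHOLE_SAMPLE and r.Tb_BV:
            totals[(r.sample_id, r.day)] = r.Tb_BV

    out: list[MorphometryRecord] = []
    for r in records:
        total = totals.get((r.sample_id, r.day))
        if (
            r.region != WHOLE_SAMPLE
            and total
            and r.Tb_BV is not None
            and r.Tb_BV / total < threshold_fraction
        ):
            out.append(replace(r, Tb_BV=None, mu_Tb=None))
        else:
            out.append(r)
    return out
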