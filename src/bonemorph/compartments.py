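"""Cortical/trabecular compartment separation and anatomical region delineation.

Given a binary bone mask of a long bone, this module

1. builds the filled periosteal **envelope** (the total-volume region TV:
   bone plus enclosed marrow space),
2. splits the bone mask into **cortical** and **trabecular** compartments by
   mathematical morphology (opening removes structures thinner than roughly
   twice the opening radius, isolating the cortical shell), and
3. partitions the bone's long axis into the **proximal EM zone**
   (epiphysis + metaphysis), **diaphysis** and **distal EM zone**.

Region delineation defaults to an area-profile rule: the diaphysis is the
contiguous axial run whose envelope cross-sectional area stays below a level
set between the mid-shaft minimum and the flared end maxima.  A fixed-fraction
rule is available for exact reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .segmentation import STRUCT_26, BoneMask

__all__ = [
    "LabelMap",
    "RegionPartition",
    "build_envelope",
    "separate_compartments",
    "delineate_regions",
    "ParameterizationError",
    "LABEL_BACKGROUND",
    "LABEL_CORTICAL",
    "LABEL_TRABECULAR",
    "REGION_NAMES",
]

LABEL_BACKGROUND = 0
LABEL_CORTICAL = 1
LABEL_TRABECULAR = 2

REGION_NAMES = ("proximal EM-zone", "diaphysis", "distal EM-zone")

#: Default envelope closing radius (voxels): must bridge the largest
#: trabecular pore so the marrow space is sealed before hole filling.
DEFAULT_CLOSE_RADIUS_VOX = 5

#: Default opening radius (voxels) for cortical extraction; about 1.5x the
#: expected trabecular rod *radius* so rods are erased but the cortex survives.
DEFAULT_OPEN_RADIUS_VOX = 2


class ParameterizationError(ValueError):
    """Morphological parameters destroy the structure they should isolate."""


@dataclass
class LabelMap:
    """Per-voxel compartment labels plus the filled periosteal envelope.

    ``labels`` holds {0: background, 1: cortical, 2: trabecular}; cortical and
    trabecular are disjoint and their union equals the input bone mask
    exactly.  ``envelope`` is a boolean superset of the bone mask covering the
    enclosed marrow space as well.
    """

    labels: np.ndarray  # uint8
    envelope: np.ndarray  # bool
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.shape != self.envelope.shape:
            raise ValueError("labels and envelope must share a shape")

    @property
    def cortical(self) -> np.ndarray:
        return self.labels == LABEL_CORTICAL

    @property
    def trabecular(self) -> np.ndarray:
        return self.labels == LABEL_TRABECULAR

    @property
    def bone(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND


@dataclass
class RegionPartition:
    """Axial split into proximal EM-zone / diaphysis / distal EM-zone.

    Slices ``z < z1`` are proximal, ``z1 <= z < z2`` diaphyseal and
    ``z >= z2`` distal, so the three slabs are contiguous, disjoint and cover
    the full axial extent.
    """

    z1: int
    z2: int
    n_slices: int
    method: str = "area-profile"

    def __post_init__(self) -> None:
        if not (0 <= self.z1 < self.z2 <= self.n_slices):
            raise ValueError(
                f"cuts must satisfy 0 <= z1 < z2 <= n_slices, got "
                f"z1={self.z1}, z2={self.z2}, n={self.n_slices}"
            )

    def region_slices(self) -> dict[str, slice]:
        return {
            REGION_NAMES[0]: slice(0, self.z1),
            REGION_NAMES[1]: slice(self.z1, self.z2),
            REGION_NAMES[2]: slice(self.z2, self.n_slices),
        }


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask, structure=STRUCT_26)
    if n <= 1:
        return mask
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    return labeled == int(np.argmax(sizes))


def _major_components(mask: np.ndarray, min_fraction: float) -> np.ndarray:
    """Components no smaller than ``min_fraction`` of the largest one."""
    labeled, n = ndimage.label(mask, structure=STRUCT_26)
    if n <= 1:
        return mask
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    keep = sizes >= min_fraction * sizes.max()
    keep[0] = False
    return keep[labeled]


def build_envelope(mask: BoneMask | np.ndarray,
                   close_radius_vox: int = DEFAULT_CLOSE_RADIUS_VOX) -> np.ndarray:
    """Filled periosteal envelope of a bone mask (the TV region).

    Morphological closing with a ball of ``close_radius_vox`` seals pores,
    then interior holes are filled per axial slice (the marrow cavity of an
    open-ended shaft is a 2D hole in every cross-section but not a 3D cavity)
    and in 3D; finally the largest 26-connected component is kept so the
    envelope is a single object.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    m = mask.mask if isinstance(mask, BoneMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot build an envelope from an empty mask")
    if close_radius_vox > 0:
        selem = ball(close_radius_vox)
        # pad so border voxels are closed correctly, then crop back
        r = close_radius_vox
        padded = np.pad(m, r)
        closed = ndimage.binary_closing(padded, structure=selem)[r:-r, r:-r, r:-r]
        closed |= m
    else:
        closed = m.copy()
    for z in range(closed.shape[0]):
        closed[z] = ndimage.binary_fill_holes(closed[z])
    closed = ndimage.binary_fill_holes(closed)
    return _largest_component(closed)


def separate_compartments(mask: BoneMask | np.ndarray, envelope: np.ndarray,
                          open_radius_vox: int = DEFAULT_OPEN_RADIUS_VOX,
                          min_core_fraction: float = 0.05,
                          params: dict | None = None) -> LabelMap:
    """Split the bone mask into cortical and trabecular compartments.

    The cortical core is the morphological opening of the mask with a ball of
    ``open_radius_vox`` (erasing rods and plates thinner than about twice
    that radius), keeping only core components at least ``min_core_fraction``
    of the largest one — the shell may briefly lose continuity where it runs
    steeply (epiphyseal caps), whereas surviving trabecular clumps are orders
    of magnitude smaller than any shell piece.  The core is re-dilated by the
    opening ball and intersected with the mask to restore the exact cortical
    boundary.  Everything else in the mask is trabecular, so every bone voxel
    lands in exactly one class.

    Raises
    ------
    ParameterizationError
        If the opening erases the entire mask (opening radius exceeds the
        cortical thickness).
    """
    m = mask.mask if isinstance(mask, BoneMask) else np.asarray(mask, dtype=bool)
    selem = ball(open_radius_vox)
    opened = ndimage.binary_opening(m, structure=selem)
    if not opened.any():
        raise ParameterizationError(
            f"opening with radius {open_radius_vox} removed every bone voxel; "
            f"the radius likely exceeds the cortical half-thickness"
        )
    core = _major_components(opened, min_core_fraction)
    cortical = ndimage.binary_dilation(core, structure=selem) & m
    trabecular = m & ~cortical
    labels = np.zeros(m.shape, dtype=np.uint8)
    labels[cortical] = LABEL_CORTICAL
    labels[trabecular] = LABEL_TRABECULAR
    p = {"open_radius_vox": open_radius_vox}
    if params:
        p.update(params)
    return LabelMap(labels=labels, envelope=np.asarray(envelope, dtype=bool), params=p)


def delineate_regions(envelope: np.ndarray, method: str = "area-profile",
                      beta: float = 0.5,
                      fractions: tuple[float, float] = (0.33, 0.67)) -> RegionPartition:
    """Place the two axial cuts separating EM zones from the diaphysis.

    ``area-profile`` (default): with A(z) the envelope cross-sectional area,
    the diaphysis is the maximal contiguous run where
    ``A(z) <= A_min + beta * (A_end - A_min)``, ``A_min`` being the minimal
    mid-shaft area and ``A_end`` the mean of the two end-maximal areas.  If no
    interior run exists (e.g. a cylinder with no flared ends) the method falls
    back to fixed fractions with a warning.

    ``fixed-fraction``: cuts at the given fractions of the bone's axial
    extent.
    """
    env = np.asarray(envelope, dtype=bool)
    if not env.any():
        raise ValueError("empty envelope")
    area = env.sum(axis=(1, 2))
    occupied = np.flatnonzero(area > 0)
    z_lo, z_hi = int(occupied[0]), int(occupied[-1])  # inclusive extent
    n_ext = z_hi - z_lo + 1

    if method == "fixed-fraction":
        return _fixed_fraction_cuts(env.shape[0], z_lo, n_ext, fractions)
    if method != "area-profile":
        raise ValueError(f"unknown delineation method {method!r}")

    a = area[z_lo : z_hi + 1].astype(float)
    mid = n_ext // 2
    a_min = float(a.min())
    a_end = 0.5 * (float(a[:mid].max()) + float(a[mid:].max()))
    level = a_min + beta * (a_end - a_min)
    low = a <= level
    run = _longest_true_run(low)
    if run is None or (run[0] == 0 and run[1] == n_ext):
        warnings.warn(
            "area profile has no interior low-area run (no flared ends "
            "detected); falling back to fixed fractions",
            stacklevel=2,
        )
        return _fixed_fraction_cuts(env.shape[0], z_lo, n_ext, fractions)
    z1 = z_lo + run[0]
    z2 = z_lo + run[1]
    return RegionPartition(z1=z1, z2=z2, n_slices=env.shape[0], method="area-profile")


def _fixed_fraction_cuts(n_slices: int, z_lo: int, n_ext: int,
                         fractions: tuple[float, float]) -> RegionPartition:
    f1, f2 = fractions
    if not (0 < f1 < f2 < 1):
        raise ValueError(f"fractions must satisfy 0 < f1 < f2 < 1, got {fractions}")
    z1 = z_lo + int(round(f1 * n_ext))
    z2 = z_lo + int(round(f2 * n_ext))
    return RegionPartition(z1=z1, z2=z2, n_slices=n_slices, method="fixed-fraction")


def _longest_true_run(flags: np.ndarray) -> tuple[int, int] | None:
    """Half-open (start, stop) of the longest contiguous True run, or None."""
    if not flags.any():
        return None
    padded = np.concatenate(([False], flags, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    i = int(np.argmax(stops - starts))
    return int(starts[i]), int(stops[i])
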