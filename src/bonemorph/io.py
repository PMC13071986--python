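"""Volume, label-map, manifest and report I/O with explicit physical metadata.

All grids follow one axis convention: **axis 0 is the bone's long (z) axis**.
Attenuation values are linear attenuation coefficients in mm^-1; voxel sizes
are isotropic and given in mm; acquisition times are integer days since the
series baseline.  Every artifact written to disk carries these units in a JSON
sidecar (volumes) or in its column metadata (reports), so nothing is implicit.

Formats
-------
* Volumes: multi-page TIFF stacks (page = axial slice) with a ``.json`` sidecar
  holding ``voxel_size_mm``, ``day``, ``sample_id`` and ``units``.  NIfTI-style
  single-file volumes (``.nii``/``.nii.gz``) are also read if nibabel is
  installed.
* Series manifests: YAML mapping a sample to an ordered day -> path table.
* Morphometry reports: CSV, one row per (sample, day, region), with absent
  trabecular entries written as empty cells (never as zeros).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Volume",
    "SeriesManifest",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]


class MetadataError(ValueError):
    """Required physical metadata (voxel size, day) is missing or invalid."""


class FormatError(ValueError):
    """The on-disk data does not describe a 3D volume."""


@dataclass
class Volume:
    """A reconstructed 3D attenuation map with physical metadata.

    Parameters
    ----------
    grid
        3D array of linear attenuation coefficients (mm^-1); axis 0 is the
        bone's long axis.
    voxel_size_mm
        Isotropic voxel edge length in mm.
    day
        Acquisition day, in days since the series baseline (0 = baseline).
    sample_id
        Free-text specimen identifier.
    """

    grid: np.ndarray
    voxel_size_mm: float
    day: int = 0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(f"volume grid must be 3D, got ndim={self.grid.ndim}")
        if min(self.grid.shape) < 1:
            raise FormatError(f"all dimensions must be >= 1, got {self.grid.shape}")
        if not (self.voxel_size_mm > 0):
            raise MetadataError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        if self.day < 0:
            raise MetadataError(f"day must be >= 0, got {self.day}")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)  # type: ignore[return-value]

    def with_grid(self, grid: np.ndarray) -> "Volume":
        return replace(self, grid=grid)


@dataclass
class SeriesManifest:
    """Ordered longitudinal scan series for one specimen.

    ``entries`` maps acquisition day to volume path; days must be strictly
    increasing and start at day 0 (the baseline scan).
    """

    sample_id: str
    entries: list[tuple[int, str]] = field(default_factory=list)
    fixative: str = ""

    def __post_init__(self) -> None:
        days = [d for d, _ in self.entries]
        if days and days[0] != 0:
            raise MetadataError("first manifest entry must be the day-0 baseline")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise MetadataError(f"manifest days must be strictly increasing: {days}")

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.entries]


# ---------------------------------------------------------------------------
# volumes


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF stack plus a JSON sidecar.

    Float grids are written as float32 only if they already are float32;
    otherwise the native dtype is preserved so that write -> read round-trips
    bitwise.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.grid, photometric="minisblack")
    sidecar = {
        "voxel_size_mm": float(volume.voxel_size_mm),
        "day": int(volume.day),
        "sample_id": volume.sample_id,
        "units": {"values": "mm^-1", "voxel_size": "mm", "day": "days since baseline"},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path, sidecar: str | Path | dict | None = None) -> Volume:
    """Read a volume from a TIFF stack (or NIfTI file) with its metadata.

    ``sidecar`` may be a path to a JSON file, an already-parsed dict, or None
    to look for ``<path>.json`` next to the volume.  The sidecar must supply
    ``voxel_size_mm`` (and may supply ``day`` and ``sample_id``) unless the
    container embeds them (NIfTI affines supply the voxel size).

    Raises
    ------
    MetadataError
        If no voxel size can be determined, or voxels are anisotropic.
    FormatError
        If the data is not 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    meta: dict = {}
    if isinstance(sidecar, dict):
        meta = dict(sidecar)
    else:
        sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
        if sc.exists():
            meta = json.loads(sc.read_text())

    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        grid, vox = _read_nifti(path)
        meta.setdefault("voxel_size_mm", vox)
    else:
        grid = tifffile.imread(path)

    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise FormatError(
            f"{path.name}: expected a 3D stack, got shape {grid.shape}; "
            "a single 2D image has no stack context"
        )
    if "voxel_size_mm" not in meta:
        raise MetadataError(f"{path.name}: voxel_size_mm missing from sidecar")
    return Volume(
        grid=grid,
        voxel_size_mm=float(meta["voxel_size_mm"]),
        day=int(meta.get("day", 0)),
        sample_id=str(meta.get("sample_id", path.stem)),
    )


def _read_nifti(path: Path) -> tuple[np.ndarray, float]:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not all(math.isclose(z, zooms[0], rel_tol=1e-6) for z in zooms):
        raise MetadataError(f"{path.name}: anisotropic voxels {zooms} are not supported")
    # NIfTI is x,y,z fastest-first; reorder so the long axis is axis 0.
    grid = np.asarray(img.dataobj).T
    return grid, float(zooms[0])


# ---------------------------------------------------------------------------
# manifests


def write_manifest(manifest: SeriesManifest, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "sample_id": manifest.sample_id,
        "fixative": manifest.fixative,
        "units": {"day": "days since baseline"},
        "series": [{"day": int(d), "path": str(p)} for d, p in manifest.entries],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_manifest(path: str | Path) -> SeriesManifest:
    doc = yaml.safe_load(Path(path).read_text())
    entries = [(int(e["day"]), str(e["path"])) for e in doc.get("series", [])]
    return SeriesManifest(
        sample_id=str(doc.get("sample_id", "sample")),
        entries=entries,
        fixative=str(doc.get("fixative", "")),
    )


# ---------------------------------------------------------------------------
# tabular reports

#: Report column order: identifiers, then volumes (mm^3), bone volume fraction
#: (%), then median attenuation coefficients (mm^-1).
REPORT_COLUMNS = [
    "sample_id",
    "day",
    "region",
    "TV_mm3",
    "BV_mm3",
    "CtBV_mm3",
    "TbBV_mm3",
    "BVTV_pct",
    "mu_B_mm-1",
    "mu_Ct_mm-1",
    "mu_Tb_mm-1",
]


def write_report(records: Sequence, path: str | Path) -> Path:
    """Write morphometry records to CSV, one row per (sample, day, region).

    Absent trabecular entries (regions where trabecular content was excluded)
    become empty cells, mirroring how such regions are conventionally tabled
    with "-" rather than a misleading 0.

    Raises
    ------
    ValueError
        If ``records`` is empty.
    """
    if not records:
        raise ValueError("cannot write an empty report")
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "day": r.day,
                "region": r.region,
                "TV_mm3": r.TV,
                "BV_mm3": r.BV,
                "CtBV_mm3": r.Ct_BV,
                "TbBV_mm3": r.Tb_BV,
                "BVTV_pct": r.BV_TV,
                "mu_B_mm-1": r.mu_B,
                "mu_Ct_mm-1": r.mu_Ct,
                "mu_Tb_mm-1": r.mu_Tb,
            }
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.10g keeps 6-significant-digit round-trips comfortably; None -> empty cell
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a morphometry report; empty cells come back as NaN (absent)."""
    return pd.read_csv(path)
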