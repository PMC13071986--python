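"""End-to-end driver: scan series in, per-day morphometry and endpoints out.

Every scan in a series is binarized with ONE common Otsu threshold (pooled
series histogram), then processed independently — envelope, compartments and
region cuts are re-derived per scan, because specimen volume itself changes
over time and must be re-measured, not propagated from baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import compartments as cp
from . import morphometry as mm
from . import segmentation as seg
from .io import Volume
from .longitudinal import ChangeCurve, EndpointTable, endpoint_differences, relative_change
from .morphometry import MorphometryRecord

__all__ = ["PipelineParams", "process_volume", "process_series", "series_curves"]


@dataclass
class PipelineParams:
    """Tunable parameters of the segmentation/morphometry chain."""

    n_bins: int = seg.DEFAULT_N_BINS
    min_component_vox: int = seg.DEFAULT_MIN_COMPONENT_VOX
    close_radius_vox: int = cp.DEFAULT_CLOSE_RADIUS_VOX
    open_radius_vox: int = cp.DEFAULT_OPEN_RADIUS_VOX
    region_method: str = "area-profile"
    beta: float = 0.5
    fractions: tuple[float, float] = (0.33, 0.67)
    exclusion_fraction: float = mm.DEFAULT_EXCLUSION_FRACTION


def process_volume(volume: Volume, threshold: float,
                   params: PipelineParams = PipelineParams(),
                   provenance: str = "common") -> list[MorphometryRecord]:
    """Segment one scan at a given threshold and compute its morphometry."""
    mask = seg.binarize_and_clean(volume, threshold,
                                  min_component_vox=params.min_component_vox,
                                  provenance=provenance)
    envelope = cp.build_envelope(mask, close_radius_vox=params.close_radius_vox)
    labels = cp.separate_compartments(mask, envelope,
                                      open_radius_vox=params.open_radius_vox)
    partition = cp.delineate_regions(envelope, method=params.region_method,
                                     beta=params.beta, fractions=params.fractions)
    records = mm.compute_morphometry(volume, labels, partition)
    return mm.apply_trabecular_exclusion(records, params.exclusion_fraction)


def process_series(series: Sequence[Volume],
                   params: PipelineParams = PipelineParams(),
                   ) -> tuple[list[MorphometryRecord], float]:
    """Process a longitudinal series with a common threshold.

    Returns all per-day records (whole sample + regions) and the common
    threshold used.
    """
    if not series:
        raise ValueError("empty series")
    thr = seg.common_threshold(series, n_bins=params.n_bins)
    records: list[MorphometryRecord] = []
    for vol in series:
        records.extend(process_volume(vol, thr, params))
    return records, thr


def series_curves(records: Sequence[MorphometryRecord],
                  parameters: Sequence[str] = ("TV", "BV", "Ct.BV", "Tb.BV",
                                               "mu.B", "mu.Ct", "mu.Tb"),
                  ) -> tuple[list[ChangeCurve], EndpointTable]:
    """Change curves per region/parameter plus the endpoint table."""
    by_region: dict[str, list[MorphometryRecord]] = {}
    for r in records:
        by_region.setdefault(r.region, []).append(r)
    curves = []
    for region, recs in by_region.items():
        for p in parameters:
            base = sorted(recs, key=lambda r: r.day)[0]
            if base.get(p) in (None, 0):
                continue  # absent/zero baseline: no curve (e.g. excluded Tb)
            curves.append(relative_change(recs, p))
    return curves, endpoint_differences(records)
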