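"""Baseline-relative change curves and first/last endpoint tables.

Every longitudinal quantity is expressed relative to the baseline (day 0)
scan of the same specimen, region and parameter:

    delta(day) = 100 * (x(day) - x(0)) / x(0)   [percent]

so the first point of every curve is exactly 0 and positive values mean
growth relative to baseline.  No smoothing or interpolation is applied; the
curves are the raw per-scan points.  Endpoint tables condense a series to
(first-day value, last-day value, difference %) per region and parameter,
with absent entries (e.g. excluded diaphyseal trabecular values) rendered as
"-" — absent propagates as absent, never as zero.

Because single-specimen series have no replicates, no significance test is
attached; instead the *experimental spread* — the largest absolute excursion
of a stable control series (ethanol-stored specimen) — can be reported next
to the curves as an informal measurement-error band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .morphometry import PARAMETER_ATTRS, MorphometryRecord

__all__ = [
    "ChangeCurve",
    "EndpointTable",
    "relative_change",
    "endpoint_differences",
    "experimental_spread",
    "relative_difference",
    "plot_change_curves",
]

#: Printed precision per parameter family, matching conventional morphometry
#: tables: volumes to 2 decimals (mm^3), attenuation to 3 (mm^-1), percent
#: differences to 2.
_VALUE_DECIMALS = {"TV": 2, "BV": 2, "Ct.BV": 2, "Tb.BV": 2, "BV/TV": 1,
                   "mu.B": 3, "mu.Ct": 3, "mu.Tb": 3}


def relative_difference(first: float, last: float) -> float:
    """Signed percent change from ``first`` to ``last``: 100*(last-first)/first."""
    if first == 0:
        raise ValueError("baseline value must be nonzero")
    return 100.0 * (last - first) / first


@dataclass
class ChangeCurve:
    """Baseline-relative percent change of one parameter over time.

    ``points`` is a list of ``(day, delta_percent)`` with strictly increasing
    days; a ``None`` delta marks a day where the parameter was absent.
    """

    sample_id: str
    region: str
    parameter: str
    points: list[tuple[int, float | None]]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.points]
        if not days or days[0] != 0:
            raise ValueError("curve must start at day 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"days must be strictly increasing: {days}")
        if self.points[0][1] != 0.0:
            raise ValueError("baseline point must be exactly 0 %")

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.points]

    @property
    def deltas(self) -> list[float | None]:
        return [v for _, v in self.points]

    @property
    def endpoint(self) -> float | None:
        return self.points[-1][1]


@dataclass
class EndpointTable:
    """First-day / last-day / difference-% rows per (region, parameter)."""

    frame: pd.DataFrame  # columns: region, parameter, first, last, diff_pct

    def formatted(self) -> pd.DataFrame:
        """Rows formatted at conventional printed precision; absent -> '-'."""
        rows = []
        for _, r in self.frame.iterrows():
            dec = _VALUE_DECIMALS.get(r["parameter"], 3)
            if pd.isna(r["first"]) or pd.isna(r["last"]):
                rows.append((r["region"], r["parameter"], "-", "-", "-"))
            else:
                rows.append(
                    (
                        r["region"],
                        r["parameter"],
                        f"{r['first']:.{dec}f}",
                        f"{r['last']:.{dec}f}",
                        f"{r['diff_pct']:.2f}",
                    )
                )
        return pd.DataFrame(rows, columns=["region", "parameter", "first", "last",
                                           "diff_pct"])


def _sorted_series(series: Sequence[MorphometryRecord]) -> list[MorphometryRecord]:
    recs = sorted(series, key=lambda r: r.day)
    if not recs or recs[0].day != 0:
        raise ValueError("series must contain a day-0 baseline record")
    return recs


def relative_change(series: Sequence[MorphometryRecord],
                    parameter: str) -> ChangeCurve:
    """Baseline-relative change curve of one parameter for one region series.

    All records must belong to the same specimen and region.  Absent values
    after baseline yield absent curve points; an absent or zero baseline is
    an error (there is nothing to normalize by).
    """
    if parameter not in PARAMETER_ATTRS:
        raise KeyError(f"unknown parameter {parameter!r}")
    recs = _sorted_series(series)
    base = recs[0].get(parameter)
    if base is None or base == 0:
        raise ValueError(
            f"baseline {parameter} is {'absent' if base is None else 'zero'}; "
            "cannot form a relative-change curve"
        )
    points: list[tuple[int, float | None]] = []
    for r in recs:
        v = r.get(parameter)
        points.append((r.day, None if v is None else relative_difference(base, v)))
    return ChangeCurve(sample_id=recs[0].sample_id, region=recs[0].region,
                       parameter=parameter, points=points)


def endpoint_differences(series: Sequence[MorphometryRecord],
                         parameters: Iterable[str] = PARAMETER_ATTRS,
                         ) -> EndpointTable:
    """First/last endpoint table over a full per-day record series.

    ``series`` may mix regions (as produced by per-scan morphometry); rows
    are emitted per (region, parameter) in input order of first appearance.

    Raises
    ------
    ValueError
        If any region has fewer than two time points.
    """
    regions: dict[str, list[MorphometryRecord]] = {}
    for r in series:
        regions.setdefault(r.region, []).append(r)

    rows = []
    for region, recs in regions.items():
        recs = sorted(recs, key=lambda r: r.day)
        if len(recs) < 2:
            raise ValueError(f"region {region!r} has fewer than two time points")
        first_rec, last_rec = recs[0], recs[-1]
        for p in parameters:
            a, b = first_rec.get(p), last_rec.get(p)
            if a is None or b is None:
                rows.append((region, p, None, None, None))
            else:
                rows.append((region, p, a, b, relative_difference(a, b)))
    return EndpointTable(
        frame=pd.DataFrame(rows, columns=["region", "parameter", "first", "last",
                                          "diff_pct"])
    )


def experimental_spread(control_curves: Sequence[ChangeCurve]) -> float:
    """Largest absolute baseline-relative excursion across control curves.

    With a chemically inert fixative the true change is zero, so this spread
    is an empirical measurement-error band against which changes under the
    active fixative can be judged.
    """
    excursions = [abs(v) for c in control_curves for v in c.deltas if v is not None]
    if not excursions:
        raise ValueError("control curves contain no values")
    return max(excursions)


def plot_change_curves(curves: Sequence[ChangeCurve], path: str,
                       spread: float | None = None) -> None:
    """Write a panel of change curves (one subplot per region) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = sorted({c.region for c in curves})
    fig, axes = plt.subplots(1, max(len(regions), 1),
                             figsize=(4 * max(len(regions), 1), 3.2), squeeze=False)
    for ax, region in zip(axes[0], regions):
        for c in (c for c in curves if c.region == region):
            days = [d for d, v in c.points if v is not None]
            vals = [v for _, v in c.points if v is not None]
            ax.plot(days, vals, marker="o", label=c.parameter)
        if spread is not None:
            ax.axhspan(-spread, spread, alpha=0.15, color="grey")
        ax.axhline(0.0, lw=0.5, color="k")
        ax.set_title(region)
        ax.set_xlabel("day")
        ax.set_ylabel("change from baseline, %")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
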