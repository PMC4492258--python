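"""Raw records -> aligned, transformed site x period panels.

Daily regulatory samples are averaged within each 2-week period (subject
to a completeness rule), 2-week integrated samples are used directly, and
the resulting raw panel is log-transformed with a small additive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .grid import PeriodGrid, assign_period
from .panel import PanelMatrix, Scale
from .records import MeasurementRecord, SiteRecord, ValidationError


class ConflictError(ValueError):
    """A site/period cell holds both an integrated and daily records."""


@dataclass(frozen=True)
class AggregationPolicy:
    """How daily records are aggregated and panels transformed.

    ``min_daily_per_period``: minimum number of 24-hr samples required to
    form a 2-week average (an every-6th-day schedule yields 2-3 per
    period, so the default of 2 keeps those cells). ``transform``: LOG1P
    is ln(x + 1); LOGC is ln(x + c) with c = ``logc_factor`` times the
    mean observed value of the panel (a detection-limit-scaled
    alternative). ``prefer_integrated``: resolve integrated-vs-daily cell
    conflicts in favour of the 2-week sample instead of raising.
    """

    min_daily_per_period: int = 2
    transform: Scale = Scale.LOG1P
    logc_factor: float = 0.1
    prefer_integrated: bool = False
    min_overlap_days: int = 10

    def __post_init__(self):
        if self.min_daily_per_period < 1:
            raise ValueError("min_daily_per_period must be >= 1")
        if Scale(self.transform) not in (Scale.LOG1P, Scale.LOGC):
            raise ValueError("transform must be LOG1P or LOGC")


def to_two_week_panel(
    records: Sequence[MeasurementRecord],
    sites: Sequence[SiteRecord],
    grid: PeriodGrid,
    policy: AggregationPolicy = AggregationPolicy(),
) -> PanelMatrix:
    """Align records to the grid and aggregate into a RAW panel.

    Per site/period cell: an assigned 14-day record is used directly (the
    mean, if several map to one period); otherwise the arithmetic mean of
    assigned 24-hr records provided their count reaches
    ``min_daily_per_period``; otherwise the cell is missing. A cell with
    both durations raises :class:`ConflictError` unless
    ``prefer_integrated`` is set.
    """
    records = list(records)
    pollutants = {r.pollutant for r in records}
    if len(pollutants) > 1:
        raise ValidationError(
            f"mixed pollutants in one panel: {sorted(p.value for p in pollutants)}"
        )
    site_ids = [s.site_id for s in sites]
    row = {sid: i for i, sid in enumerate(site_ids)}
    n, t = len(site_ids), grid.n_periods
    daily: List[List[List[float]]] = [[[] for _ in range(t)] for _ in range(n)]
    integ: List[List[List[float]]] = [[[] for _ in range(t)] for _ in range(n)]
    for r in records:
        if r.site_id not in row:
            raise ValidationError(f"record for unknown site {r.site_id!r}")
        k = assign_period(grid, r.start_date, r.duration_days,
                          min_overlap_days=policy.min_overlap_days)
        if k is None:
            continue
        (integ if r.duration_days == 14 else daily)[row[r.site_id]][k].append(
            float(r.value)
        )

    values = np.full((n, t), np.nan)
    mask = np.zeros((n, t), dtype=bool)
    for i in range(n):
        for k in range(t):
            if integ[i][k]:
                if daily[i][k] and not policy.prefer_integrated:
                    raise ConflictError(
                        f"site {site_ids[i]} period {k}: both 14-day and "
                        f"24-hr records present"
                    )
                values[i, k] = float(np.mean(integ[i][k]))
                mask[i, k] = True
            elif len(daily[i][k]) >= policy.min_daily_per_period:
                values[i, k] = float(np.mean(daily[i][k]))
                mask[i, k] = True
    return PanelMatrix(site_ids=site_ids, grid=grid, values=values,
                       mask=mask, scale=Scale.RAW)


def transform_panel(
    panel: PanelMatrix, policy: AggregationPolicy = AggregationPolicy()
) -> PanelMatrix:
    """ln(value + c) with c = 1 (LOG1P) or 0.1 x mean observed (LOGC)."""
    if panel.scale != Scale.RAW:
        raise ValueError(f"panel already transformed (scale {panel.scale.value})")
    target = Scale(policy.transform)
    if target == Scale.LOG1P:
        c = 1.0
    else:
        obs = panel.values[panel.mask]
        if obs.size == 0:
            raise ValueError("cannot compute LOGC constant of an empty panel")
        c = policy.logc_factor * float(obs.mean())
    values = np.where(panel.mask, np.log(panel.values + c), np.nan)
    return PanelMatrix(site_ids=panel.site_ids, grid=panel.grid,
                       values=values, mask=panel.mask.copy(), scale=target,
                       transform_c=c)


def subsample_every_sixth(
    records: Sequence[MeasurementRecord], phase: int = 0
) -> List[MeasurementRecord]:
    """Thin an every-3rd-day series to every 6th day.

    Sorts the records by date and keeps alternating dates (phase 0 keeps
    the 1st, 3rd, 5th, ... of the sorted sequence; phase 1 the
    complement), exactly halving the calendar density. A warning is
    emitted if the input is not a regular 3-day calendar; thinning is
    still applied to the sorted sequence.
    """
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    recs = sorted(records, key=lambda r: r.start_date)
    dates = [r.start_date for r in recs]
    gaps = {(b - a).days for a, b in zip(dates, dates[1:])}
    if gaps and gaps != {3}:
        warnings.warn(
            f"irregular sampling calendar (day gaps {sorted(gaps)}); "
            f"thinning the sorted date sequence anyway"
        )
    return recs[phase::2]
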