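"""The common 2-week period grid and sample-to-period alignment.

All networks are aligned to contiguous half-open 14-day intervals whose
centre day (interval start + 7 days) is a Wednesday, with centres spaced
14 days apart. Half-open intervals make the tiling gap-free, so every
calendar day inside the grid span belongs to exactly one period.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import List, Optional, Tuple

WEDNESDAY = 2  # date.weekday() convention: Monday == 0

#: Minimum day-overlap for a 14-day sample to be assigned to a period.
DEFAULT_MIN_OVERLAP_DAYS = 10


@dataclass(frozen=True)
class PeriodGrid:
    """Ordered 14-day half-open intervals centred on every other Wednesday.

    Period ``k`` runs ``[anchor - 7d + 14k, anchor + 7d + 14k)`` so its
    centre day is ``anchor + 14k``, a Wednesday.
    """

    anchor_wednesday: date
    n_periods: int

    def __post_init__(self):
        if self.anchor_wednesday.weekday() != WEDNESDAY:
            raise ValueError(
                f"anchor {self.anchor_wednesday} is not a Wednesday"
            )
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")

    @property
    def start_date(self) -> date:
        """First day of period 0 (inclusive)."""
        return self.anchor_wednesday - timedelta(days=7)

    @property
    def end_date(self) -> date:
        """Day after the last day of the last period (exclusive)."""
        return self.start_date + timedelta(days=14 * self.n_periods)

    def period_start(self, k: int) -> date:
        return self.start_date + timedelta(days=14 * k)

    def period_end(self, k: int) -> date:
        return self.start_date + timedelta(days=14 * (k + 1))

    def period_center(self, k: int) -> date:
        return self.anchor_wednesday + timedelta(days=14 * k)

    @property
    def centers(self) -> List[date]:
        return [self.period_center(k) for k in range(self.n_periods)]

    @property
    def periods(self) -> List[Tuple[date, date]]:
        """Half-open [start, end) intervals, in order."""
        return [(self.period_start(k), self.period_end(k))
                for k in range(self.n_periods)]

    def __len__(self) -> int:
        return self.n_periods


def build_period_grid(anchor_wednesday: date, n_periods: int) -> PeriodGrid:
    """Build the 2-week grid anchored on a given Wednesday.

    Raises ``ValueError`` if the anchor is not a Wednesday or
    ``n_periods < 1``.
    """
    return PeriodGrid(anchor_wednesday=anchor_wednesday,
                      n_periods=n_periods)


def first_wednesday_on_or_after(d: date) -> date:
    """Default anchor rule: first Wednesday on/after the earliest sample."""
    return d + timedelta(days=(WEDNESDAY - d.weekday()) % 7)


def assign_period(
    grid: PeriodGrid,
    sample_start: date,
    duration_days: int,
    min_overlap_days: int = DEFAULT_MIN_OVERLAP_DAYS,
) -> Optional[int]:
    """Map one sample to a grid period, or ``None`` if it falls outside.

    A 24-hr sample maps to the unique half-open interval containing its
    start date. A 14-day sample maps to the interval with maximal day
    overlap, provided the overlap is at least ``min_overlap_days``
    (default 10); ties cannot occur above that threshold because two
    adjacent 14-day windows share at most 7 overlap days each.
    """
    if duration_days == 1:
        off = (sample_start - grid.start_date).days
        if 0 <= off < 14 * grid.n_periods:
            return off // 14
        return None
    if duration_days != 14:
        raise ValueError(f"duration_days must be 1 or 14, got {duration_days}")

    s0 = sample_start
    s1 = sample_start + timedelta(days=14)
    best_k, best_ov = None, 0
    # the sample can only overlap the period containing its start and the
    # following one
    off = (s0 - grid.start_date).days
    for k in (off // 14, off // 14 + 1):
        if 0 <= k < grid.n_periods:
            p0, p1 = grid.period_start(k), grid.period_end(k)
            ov = (min(s1, p1) - max(s0, p0)).days
            if ov > best_ov:
                best_k, best_ov = k, ov
    if best_ov >= min_overlap_days:
        return best_k
    return None
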