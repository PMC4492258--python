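"""Site x period panel container with an explicit missingness mask."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Sequence

import numpy as np

from .grid import PeriodGrid


class Scale(str, Enum):
    RAW = "RAW"        # concentrations, µg/m³
    LOG1P = "LOG1P"    # ln(value + 1)
    LOGC = "LOGC"      # ln(value + 0.1 * mean observed value)
    LOG = "LOG"        # ln(concentration); used for latent simulator fields


@dataclass
class PanelMatrix:
    """Sites x 2-week-periods matrix of concentrations.

    ``values[i, k]`` is the value for ``site_ids[i]`` in grid period ``k``;
    ``mask[i, k]`` is True where observed. Unobserved cells are stored as
    NaN and carry no information. ``scale`` tags the transform applied;
    ``transform_c`` records the additive constant used by a log transform
    so it can be inverted exactly.
    """

    site_ids: List[str]
    grid: PeriodGrid
    values: np.ndarray
    mask: np.ndarray
    scale: Scale = Scale.RAW
    transform_c: float = float("nan")

    def __post_init__(self):
        self.site_ids = list(self.site_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.scale = Scale(self.scale)
        n, t = len(self.site_ids), self.grid.n_periods
        if self.values.shape != (n, t) or self.mask.shape != (n, t):
            raise ValueError(
                f"panel shape mismatch: {n} sites x {t} periods but "
                f"values {self.values.shape}, mask {self.mask.shape}"
            )
        if len(set(self.site_ids)) != n:
            raise ValueError("duplicate site ids in panel")
        # hygiene: unobserved cells carry no information
        self.values = np.where(self.mask, self.values, np.nan)
        obs = self.values[self.mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError("observed cells must be finite")
        if self.scale == Scale.RAW and obs.size and np.any(obs < 0):
            raise ValueError("RAW panel has negative observed values")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_periods(self) -> int:
        return self.grid.n_periods

    def row(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def subset(self, site_ids: Sequence[str]) -> "PanelMatrix":
        """Panel restricted to the given sites (order as given)."""
        idx = [self.row(s) for s in site_ids]
        return PanelMatrix(
            site_ids=list(site_ids),
            grid=self.grid,
            values=self.values[idx].copy(),
            mask=self.mask[idx].copy(),
            scale=self.scale,
            transform_c=self.transform_c,
        )

    def observed_fraction(self) -> np.ndarray:
        """Per-site fraction of observed periods."""
        return self.mask.mean(axis=1)

    def copy(self) -> "PanelMatrix":
        return PanelMatrix(
            site_ids=list(self.site_ids),
            grid=self.grid,
            values=self.values.copy(),
            mask=self.mask.copy(),
            scale=self.scale,
            transform_c=self.transform_c,
        )
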