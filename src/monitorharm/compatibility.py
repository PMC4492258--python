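"""Between-network comparability at co-located monitors.

Co-located monitor pairs yield paired 2-week series; their agreement is
summarized by the Pearson correlation, the best-fit line of y on x on the
transformed scale (a non-unit slope or non-zero intercept flags systematic
method differences), and the mean difference. Smoothed temporal patterns
pooled across sites summarize what each network says about the shared
seasonal behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .panel import PanelMatrix
from .records import Network, SiteRecord
from .smoothing import local_linear_smooth

DEFAULT_PATTERN_BANDWIDTH = 6.0  # periods


@dataclass
class PairedSeries:
    """Paired observations of one co-location group on a common grid."""

    group_id: str
    network_x: Network
    network_y: Network
    periods: np.ndarray  # grid period indices observed in both
    x: np.ndarray
    y: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.periods)


@dataclass
class ColocationComparison:
    group_id: str
    network_x: Network
    network_y: Network
    n_pairs: int
    pearson_r: float
    slope: float
    intercept: float
    mean_diff: float
    method: str = "ols"

    def __post_init__(self):
        if self.n_pairs >= 2 and not (abs(self.pearson_r) <= 1 + 1e-12):
            raise ValueError("|pearson_r| must be <= 1")


def _same_grid(a: PanelMatrix, b: PanelMatrix) -> bool:
    return (a.grid.anchor_wednesday == b.grid.anchor_wednesday
            and a.grid.n_periods == b.grid.n_periods)


def pair_colocated(
    panel_x: PanelMatrix,
    panel_y: PanelMatrix,
    sites: Sequence[SiteRecord],
    period_window: Optional[Tuple[date, date]] = None,
) -> Dict[str, PairedSeries]:
    """Per-co-location-group lists of periods observed in both panels.

    Both panels must share grid and scale. For each co-location group with
    exactly one member site in each panel, returns the values of the
    periods observed in both, optionally restricted to periods whose
    centre falls in ``period_window`` (inclusive date range).
    """
    if not _same_grid(panel_x, panel_y):
        raise ValueError("panels are on different period grids")
    if panel_x.scale != panel_y.scale:
        raise ValueError("panels are on different scales")
    groups: Dict[str, Dict[str, List[SiteRecord]]] = {}
    for s in sites:
        if s.coloc_group is None:
            continue
        g = groups.setdefault(s.coloc_group, {"x": [], "y": []})
        if s.site_id in panel_x.site_ids:
            g["x"].append(s)
        if s.site_id in panel_y.site_ids:
            g["y"].append(s)

    in_window = np.ones(panel_x.grid.n_periods, dtype=bool)
    if period_window is not None:
        lo, hi = period_window
        in_window = np.array(
            [lo <= c <= hi for c in panel_x.grid.centers]
        )

    out: Dict[str, PairedSeries] = {}
    for gid in sorted(groups):
        g = groups[gid]
        if not g["x"] or not g["y"]:
            continue
        if len(g["x"]) > 1 or len(g["y"]) > 1:
            raise ValueError(
                f"co-location group {gid!r} has more than one site in a "
                f"network panel"
            )
        sx, sy = g["x"][0], g["y"][0]
        ix, iy = panel_x.row(sx.site_id), panel_y.row(sy.site_id)
        both = panel_x.mask[ix] & panel_y.mask[iy] & in_window
        ks = np.flatnonzero(both)
        out[gid] = PairedSeries(
            group_id=gid, network_x=sx.network, network_y=sy.network,
            periods=ks, x=panel_x.values[ix, ks], y=panel_y.values[iy, ks],
        )
    return out


def compare_colocated(
    pairs: PairedSeries, method: str = "ols"
) -> ColocationComparison:
    """Correlation and best-fit line (y on x) for one co-located pair.

    ``method='ols'`` is the default, matching the usual scatter-plot
    best-fit line; ``'deming'`` fits an errors-in-variables line with
    equal error variances in x and y.
    """
    if pairs.n_pairs < 3:
        raise ValueError(f"need >= 3 pairs, got {pairs.n_pairs}")
    x, y = pairs.x, pairs.y
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    if sxx <= 0:
        raise ValueError("zero variance in x: slope undefined")
    if method == "ols":
        slope = sxy / sxx
    elif method == "deming":
        if sxy == 0:
            slope = 0.0 if syy < sxx else math.inf
        else:
            slope = ((syy - sxx + math.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2))
                     / (2 * sxy))
    else:
        raise ValueError(f"unknown method {method!r}")
    intercept = ym - slope * xm
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else float("nan")
    return ColocationComparison(
        group_id=pairs.group_id, network_x=pairs.network_x,
        network_y=pairs.network_y, n_pairs=pairs.n_pairs,
        pearson_r=float(r), slope=float(slope), intercept=float(intercept),
        mean_diff=float((y - x).mean()), method=method,
    )


@dataclass
class SmoothedPattern:
    """Smoothed mean trajectory on the grid; NaN outside the data's span."""

    grid: object  # PeriodGrid
    values: np.ndarray
    bandwidth: float
    n_sites_used: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_periods,):
            raise ValueError("pattern length must equal n_periods")


def smooth_temporal_pattern(
    panel: PanelMatrix,
    site_subset: Optional[Sequence[str]] = None,
    bandwidth: float = DEFAULT_PATTERN_BANDWIDTH,
) -> SmoothedPattern:
    """Pool observed (period, value) points across sites and smooth.

    Fits the deterministic local-linear tri-cube smoother to all observed
    points of the chosen sites and evaluates it at every grid period;
    periods outside the observed period range stay missing.
    """
    sub = panel if site_subset is None else panel.subset(list(site_subset))
    if sub.n_sites < 1:
        raise ValueError("need at least one site")
    ii, kk = np.nonzero(sub.mask)
    if len(np.unique(kk)) < 3:
        raise ValueError(
            f"need >= 3 observed periods, got {len(np.unique(kk))}"
        )
    k_eval = np.arange(panel.grid.n_periods, dtype=float)
    values = local_linear_smooth(kk.astype(float), sub.values[ii, kk],
                                 k_eval, bandwidth)
    return SmoothedPattern(
        grid=panel.grid, values=values, bandwidth=bandwidth,
        n_sites_used=int(len(np.unique(ii))),
    )


@dataclass
class PatternAgreement:
    pearson_r: float
    rmse: float       # after unit-L2-normalizing both on common support
    n_common: int


def compare_patterns(a: SmoothedPattern, b: SmoothedPattern) -> PatternAgreement:
    """Correlation and normalized RMSE of two patterns on common support."""
    if a.grid.n_periods != b.grid.n_periods or \
            a.grid.anchor_wednesday != b.grid.anchor_wednesday:
        raise ValueError("patterns are on different grids")
    ok = np.isfinite(a.values) & np.isfinite(b.values)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 common periods, got {n}")
    va, vb = a.values[ok], b.values[ok]
    sa, sb = va.std(), vb.std()
    r = float(np.corrcoef(va, vb)[0, 1]) if sa > 0 and sb > 0 else float("nan")
    na = va / np.linalg.norm(va) if np.linalg.norm(va) > 0 else va
    nb = vb / np.linalg.norm(vb) if np.linalg.norm(vb) > 0 else vb
    rmse = float(np.sqrt(np.mean((na - nb) ** 2)))
    return PatternAgreement(pearson_r=r, rmse=rmse, n_common=n)
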