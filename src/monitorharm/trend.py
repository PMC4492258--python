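"""Shared temporal trend functions and their SVD-based extraction.

The exposure model assumes one spatially homogeneous smooth temporal trend
f(t) on the 2-week grid, scaled at each site by a trend coefficient. The
trend is estimated as the leading right singular vector of the
row-centred site x period panel, restricted to sites with long time
series; missing cells are handled by iterative imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .grid import PeriodGrid
from .panel import PanelMatrix
from .smoothing import local_linear_smooth

SIGN_CONVENTION = "corr(values, panel column means) >= 0"


@dataclass
class TrendFunction:
    """A unit-L2-norm temporal basis on the 2-week period grid.

    The sign is fixed so the trend correlates non-negatively with the
    column means of its source panel (documented in ``sign_convention``),
    making the extraction invariant to the sign indeterminacy of the SVD.
    """

    grid: PeriodGrid
    values: np.ndarray
    sign_convention: str = SIGN_CONVENTION
    bandwidth: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_periods,):
            raise ValueError(
                f"trend length {self.values.shape} != grid "
                f"({self.grid.n_periods} periods)"
            )
        nrm = float(np.linalg.norm(self.values))
        if not np.isfinite(nrm) or abs(nrm - 1.0) > 1e-9:
            raise ValueError(f"trend must have unit L2 norm, got {nrm}")

    @classmethod
    def from_values(
        cls,
        grid: PeriodGrid,
        values: np.ndarray,
        sign_convention: str = SIGN_CONVENTION,
        bandwidth: Optional[float] = None,
    ) -> "TrendFunction":
        """Normalize arbitrary finite values to unit L2 norm."""
        values = np.asarray(values, dtype=float)
        nrm = np.linalg.norm(values)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValueError("cannot normalize zero or non-finite trend")
        return cls(grid=grid, values=values / nrm,
                   sign_convention=sign_convention, bandwidth=bandwidth)


@dataclass
class SvdConvergence:
    converged: bool
    n_iter: int
    max_change: float
    n_sites_used: int
    site_ids_used: list = field(default_factory=list)


def _resolve_sign(v: np.ndarray, col_means: np.ndarray) -> np.ndarray:
    """Flip ``v`` so it correlates non-negatively with the column means."""
    ok = np.isfinite(col_means)
    if ok.sum() >= 2 and np.std(v[ok]) > 0 and np.std(col_means[ok]) > 0:
        r = np.corrcoef(v[ok], col_means[ok])[0, 1]
        if np.isfinite(r) and r != 0:
            return -v if r < 0 else v
    # degenerate fallback: make the largest-magnitude element positive
    return -v if v[np.argmax(np.abs(v))] < 0 else v


def extract_trend_svd(
    panel: PanelMatrix,
    rank: int = 1,
    impute_tol: float = 1e-6,
    max_iter: int = 100,
    min_obs_frac: float = 0.5,
) -> Tuple[TrendFunction, SvdConvergence]:
    """Leading temporal component of an incomplete panel.

    Sites observed in fewer than ``min_obs_frac`` of periods are dropped
    ("long series" eligibility); at least two sites must remain. Missing
    cells are initialized with column means (falling back to row means,
    then the grand mean) and refined by iterating {row-centre, rank-k SVD
    reconstruction, refill originally-missing cells} until the largest
    imputed-cell change drops below ``impute_tol`` or ``max_iter`` is hit
    (a warning is emitted and ``converged=False`` reported). The returned
    trend is the leading right singular vector, unit-normalized, with the
    sign convention of :class:`TrendFunction`. On a complete panel the
    loop is a no-op and the result is the direct SVD.
    """
    keep = panel.observed_fraction() >= min_obs_frac
    if keep.sum() < 2:
        raise ValueError(
            f"need >= 2 sites observed in >= {min_obs_frac:.0%} of periods; "
            f"got {int(keep.sum())}"
        )
    site_ids = [s for s, k in zip(panel.site_ids, keep) if k]
    V = panel.values[keep].copy()
    M = panel.mask[keep].copy()
    if np.any(~M.any(axis=0)):
        bad = np.flatnonzero(~M.any(axis=0))
        raise ValueError(f"periods with no observations at all: {bad.tolist()}")

    # initial fill: column mean -> row mean -> grand mean
    grand = V[M].mean()
    col = np.where(M.any(axis=0), np.nanmean(np.where(M, V, np.nan), axis=0),
                   grand)
    row = np.where(M.any(axis=1), np.nanmean(np.where(M, V, np.nan), axis=1),
                   grand)
    X = V.copy()
    miss = ~M
    ii, jj = np.nonzero(miss)
    X[ii, jj] = col[jj]

    def rank_k_recon(Xc):
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        k = min(rank, len(s))
        return (U[:, :k] * s[:k]) @ Vt[:k], Vt

    n_iter, max_change = 0, 0.0
    converged = not miss.any()
    for n_iter in range(1, max_iter + 1):
        if not miss.any():
            break
        m = X.mean(axis=1, keepdims=True)
        recon, _ = rank_k_recon(X - m)
        new = recon + m
        max_change = float(np.max(np.abs(new[miss] - X[miss])))
        X[miss] = new[miss]
        if max_change < impute_tol:
            converged = True
            break
    if not converged and miss.any():
        warnings.warn(
            f"trend SVD imputation did not converge in {max_iter} "
            f"iterations (last max change {max_change:.3g})"
        )

    m = X.mean(axis=1, keepdims=True)
    _, Vt = rank_k_recon(X - m)
    v = Vt[0]
    # sign against the column means of the row-centred observed panel
    Vc = np.where(M, V - np.where(M, V, np.nan).mean(
        axis=1, where=M, keepdims=True), np.nan)
    col_means = np.nanmean(Vc, axis=0)
    v = _resolve_sign(v, col_means)
    trend = TrendFunction(grid=panel.grid, values=v / np.linalg.norm(v))
    report = SvdConvergence(
        converged=converged, n_iter=n_iter, max_change=max_change,
        n_sites_used=len(site_ids), site_ids_used=site_ids,
    )
    return trend, report


def smooth_trend(raw: TrendFunction, bandwidth: float = 6.0) -> TrendFunction:
    """Local-linear smooth of the trend, then re-normalization to unit L2."""
    k = np.arange(raw.grid.n_periods, dtype=float)
    smoothed = local_linear_smooth(k, raw.values, k, bandwidth)
    return TrendFunction.from_values(
        raw.grid, smoothed, sign_convention=raw.sign_convention,
        bandwidth=bandwidth,
    )
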