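"""Simplified single-trend spatiotemporal exposure model.

The model for the transformed concentration at site s and 2-week period t is

    y(s, t) = x(s)' g0 + A(s) f(t) + e(s, t)

with A(s) = theta (constant amplitude) or A(s) = x(s)' g1 (covariate-driven
amplitude), f the shared unit-norm temporal trend, and residuals treated as
independent and homoscedastic — deliberately without any spatial dependence
structure, which is what makes the model fittable from a handful of fixed
sites plus many one-to-three-sample home-outdoor snapshots pooled as
ordinary regression rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .compatibility import PatternAgreement, SmoothedPattern, compare_patterns
from .grid import build_period_grid
from .panel import PanelMatrix
from .records import SiteRecord
from .trend import TrendFunction

Window = Union[None, Tuple[int, int], Sequence[int]]


def _window_indices(trend: TrendFunction, window: Window) -> np.ndarray:
    if window is None:
        return np.arange(trend.grid.n_periods)
    if isinstance(window, tuple) and len(window) == 2:
        k0, k1 = window
        if not (0 <= k0 <= k1 < trend.grid.n_periods):
            raise ValueError(f"window {window} outside grid")
        return np.arange(k0, k1 + 1)
    idx = np.asarray(window, dtype=int)
    if idx.size == 0 or idx.min() < 0 or idx.max() >= trend.grid.n_periods:
        raise ValueError("window indices outside grid")
    return idx


def _site_design(
    sites: Sequence[SiteRecord], names: List[str], add_intercept: bool
) -> np.ndarray:
    for s in sites:
        if sorted(s.covariates) != sorted(names):
            raise ValueError(
                f"site {s.site_id}: covariates {sorted(s.covariates)} do "
                f"not match model covariates {sorted(names)}"
            )
    X = np.array([[s.covariates[c] for c in names] for s in sites],
                 dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return X


@dataclass
class SimplifiedModelFit:
    """Fitted simplified model plus everything needed to predict from it."""

    amplitude_mode: str                 # "constant" | "covariate"
    covariate_names: List[str]          # order of x(s); no intercept entry
    add_intercept: bool
    gamma0_hat: np.ndarray              # incl. leading intercept if used
    gamma1_hat: Optional[np.ndarray]    # covariate mode
    theta_hat: Optional[float]          # constant mode
    trend: TrendFunction
    sigma2_hat: float
    n_obs: int
    r2: float
    param_names: List[str]
    cov_params: np.ndarray
    per_site_residuals: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def amplitude(self, X_site: np.ndarray) -> np.ndarray:
        if self.amplitude_mode == "constant":
            return np.full(len(X_site), self.theta_hat)
        return X_site @ self.gamma1_hat

    def to_json(self, path=None) -> str:
        obj = {
            "amplitude_mode": self.amplitude_mode,
            "covariate_names": self.covariate_names,
            "add_intercept": self.add_intercept,
            "gamma0_hat": self.gamma0_hat.tolist(),
            "gamma1_hat": None if self.gamma1_hat is None
            else self.gamma1_hat.tolist(),
            "theta_hat": self.theta_hat,
            "trend": {
                "anchor_wednesday":
                    self.trend.grid.anchor_wednesday.isoformat(),
                "n_periods": self.trend.grid.n_periods,
                "values": self.trend.values.tolist(),
                "bandwidth": self.trend.bandwidth,
            },
            "sigma2_hat": self.sigma2_hat,
            "n_obs": self.n_obs,
            "r2": self.r2,
            "param_names": self.param_names,
            "cov_params": self.cov_params.tolist(),
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SimplifiedModelFit":
        if isinstance(source, (str, Path)) and Path(source).exists():
            obj = json.loads(Path(source).read_text())
        else:
            obj = json.loads(source)
        t = obj["trend"]
        grid = build_period_grid(date.fromisoformat(t["anchor_wednesday"]),
                                 int(t["n_periods"]))
        trend = TrendFunction(grid=grid, values=np.asarray(t["values"]),
                              bandwidth=t["bandwidth"])
        return cls(
            amplitude_mode=obj["amplitude_mode"],
            covariate_names=list(obj["covariate_names"]),
            add_intercept=bool(obj["add_intercept"]),
            gamma0_hat=np.asarray(obj["gamma0_hat"], dtype=float),
            gamma1_hat=None if obj["gamma1_hat"] is None
            else np.asarray(obj["gamma1_hat"], dtype=float),
            theta_hat=obj["theta_hat"],
            trend=trend,
            sigma2_hat=float(obj["sigma2_hat"]),
            n_obs=int(obj["n_obs"]),
            r2=float(obj["r2"]),
            param_names=list(obj["param_names"]),
            cov_params=np.asarray(obj["cov_params"], dtype=float),
        )


def fit_simplified(
    panel: PanelMatrix,
    sites: Sequence[SiteRecord],
    trend: TrendFunction,
    amplitude_mode: str = "constant",
    add_intercept: bool = False,
) -> SimplifiedModelFit:
    """Pooled least-squares fit of the simplified model.

    Every observed cell becomes one regression row; home-outdoor snapshot
    sites contribute their one to three rows with no per-site intercepts —
    the covariates carry all spatial mean structure. ``sigma2_hat`` is the
    residual mean square with the (n - p) degrees-of-freedom divisor.
    """
    if amplitude_mode not in ("constant", "covariate"):
        raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")
    if trend.grid.n_periods != panel.grid.n_periods:
        raise ValueError("trend grid does not match panel grid")
    site_map = {s.site_id: s for s in sites}
    missing = [sid for sid in panel.site_ids if sid not in site_map]
    if missing:
        raise ValueError(f"panel sites without metadata: {missing}")
    names = sorted(site_map[panel.site_ids[0]].covariates)
    panel_sites = [site_map[sid] for sid in panel.site_ids]
    Xs = _site_design(panel_sites, names, add_intercept)

    ii, kk = np.nonzero(panel.mask)
    y = panel.values[ii, kk]
    f = trend.values[kk]
    x_names = (["(intercept)"] if add_intercept else []) + names
    if amplitude_mode == "constant":
        D = np.column_stack([Xs[ii], f])
        param_names = [f"gamma0:{c}" for c in x_names] + ["theta"]
    else:
        D = np.column_stack([Xs[ii], Xs[ii] * f[:, None]])
        param_names = ([f"gamma0:{c}" for c in x_names]
                       + [f"gamma1:{c}" for c in x_names])

    n, p = D.shape
    if n < p:
        raise ValueError(f"{n} observations but {p} parameters")
    rank = np.linalg.matrix_rank(D)
    if rank < p:
        _, _, piv = qr(D, pivoting=True)
        bad = sorted(param_names[j] for j in piv[rank:])
        raise ValueError(f"design matrix rank-deficient; collinear "
                         f"columns: {bad}")

    res = sm.OLS(y, D).fit()
    n_x = len(x_names)
    gamma0 = res.params[:n_x]
    if amplitude_mode == "constant":
        gamma1, theta = None, float(res.params[n_x])
    else:
        gamma1, theta = res.params[n_x:], None

    resid = res.resid
    per_site = pd.DataFrame({
        "site_id": [panel.site_ids[i] for i in ii],
        "resid": resid,
    }).groupby("site_id")["resid"].agg(["count", "mean", "std"]).reset_index()

    return SimplifiedModelFit(
        amplitude_mode=amplitude_mode, covariate_names=names,
        add_intercept=add_intercept, gamma0_hat=np.asarray(gamma0),
        gamma1_hat=None if gamma1 is None else np.asarray(gamma1),
        theta_hat=theta, trend=trend,
        sigma2_hat=float(res.ssr / res.df_resid), n_obs=int(n),
        r2=float(res.rsquared), param_names=param_names,
        cov_params=np.asarray(res.cov_params()),
        per_site_residuals=per_site,
    )


def predict_long_term(
    fit: SimplifiedModelFit,
    new_sites: Sequence[SiteRecord],
    averaging_window: Window = None,
) -> pd.DataFrame:
    """Predicted long-term average (log scale) with plug-in standard error.

    The prediction at site s is ``x(s)' g0 + A(s) * mean(f)`` over the
    averaging window; the standard error propagates the coefficient
    covariance under the fitted model's residual-independence assumption
    (it excludes the residual term itself, i.e. it is the SE of the mean
    surface, not of a new observation).
    """
    Xs = _site_design(list(new_sites), fit.covariate_names,
                      fit.add_intercept)
    idx = _window_indices(fit.trend, averaging_window)
    fbar = float(fit.trend.values[idx].mean())
    pred = Xs @ fit.gamma0_hat + fit.amplitude(Xs) * fbar
    if fit.amplitude_mode == "constant":
        Z = np.column_stack([Xs, np.full(len(Xs), fbar)])
    else:
        Z = np.column_stack([Xs, Xs * fbar])
    se = np.sqrt(np.einsum("ij,jk,ik->i", Z, fit.cov_params, Z))
    return pd.DataFrame({
        "site_id": [s.site_id for s in new_sites],
        "prediction": pred,
        "se": se,
    })


@dataclass
class LosoResult:
    per_site: pd.DataFrame   # site_id, n_obs, observed_mean, predicted_mean
    cv_r2: float
    failed_sites: List[str] = field(default_factory=list)


def loso_cv(
    panel: PanelMatrix,
    sites: Sequence[SiteRecord],
    trend: TrendFunction,
    amplitude_mode: str = "constant",
    add_intercept: bool = False,
) -> LosoResult:
    """Leave-one-site-out cross-validation of site-level long-term means.

    Each fold refits the regression without one site (the trend, estimated
    from fixed sites, is held fixed) and predicts that site's mean over
    exactly the periods it observed; ``cv_r2`` compares those predictions
    with the observed-period means across sites. Folds whose refit fails
    are flagged, excluded and reported with a warning.
    """
    site_map = {s.site_id: s for s in sites}
    with_data = [sid for i, sid in enumerate(panel.site_ids)
                 if panel.mask[i].any()]
    if len(with_data) < 5:
        raise ValueError(f"need >= 5 sites with data, got {len(with_data)}")
    rows, failed = [], []
    for sid in with_data:
        rest = [s for s in panel.site_ids if s != sid]
        try:
            fold = fit_simplified(panel.subset(rest), sites, trend,
                                  amplitude_mode=amplitude_mode,
                                  add_intercept=add_intercept)
        except ValueError as exc:
            failed.append(sid)
            warnings.warn(f"LOSO fold for site {sid} failed: {exc}")
            continue
        i = panel.row(sid)
        ks = np.flatnonzero(panel.mask[i])
        obs_mean = float(panel.values[i, ks].mean())
        pred = predict_long_term(fold, [site_map[sid]],
                                 averaging_window=ks)
        rows.append({
            "site_id": sid, "n_obs": int(len(ks)),
            "observed_mean": obs_mean,
            "predicted_mean": float(pred["prediction"].iloc[0]),
        })
    per_site = pd.DataFrame(rows)
    obs = per_site["observed_mean"].to_numpy()
    prd = per_site["predicted_mean"].to_numpy()
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    ss_err = float(((obs - prd) ** 2).sum())
    cv_r2 = 1.0 - ss_err / ss_tot if ss_tot > 0 else float("nan")
    return LosoResult(per_site=per_site, cv_r2=cv_r2, failed_sites=failed)


@dataclass
class TrendAgreement:
    pearson_r: float
    rmse: float
    n_common: int
    threshold: float
    adequate: bool


def trend_surrogacy_check(
    trend_component: TrendFunction,
    trend_target: TrendFunction,
    threshold: float = 0.9,
) -> TrendAgreement:
    """Can one pollutant's trend stand in for another's?

    Judges adequacy by the correlation of the two trends on their common
    grid: adequate iff r >= ``threshold``.
    """
    a = SmoothedPattern(grid=trend_component.grid,
                        values=trend_component.values,
                        bandwidth=trend_component.bandwidth or 0.0,
                        n_sites_used=0)
    b = SmoothedPattern(grid=trend_target.grid,
                        values=trend_target.values,
                        bandwidth=trend_target.bandwidth or 0.0,
                        n_sites_used=0)
    pa: PatternAgreement = compare_patterns(a, b)
    return TrendAgreement(
        pearson_r=pa.pearson_r, rmse=pa.rmse, n_common=pa.n_common,
        threshold=threshold, adequate=bool(pa.pearson_r >= threshold),
    )
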