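"""Synthetic study regions with the monitoring networks' sampling designs.

The generator draws a ground-truth log-normal concentration field

    log C(s, t) = x(s)' g0 + (x(s)' g1) f(t) + eps(s, t) + eta(s)

with covariate-driven long-term means, one smooth seasonal trend scaled by
spatially varying coefficients, per-period Gaussian residual fields with
exponential spatial covariance (temporally independent), and a
location-level nugget. Observations are then sampled per network: fixed
study sites take one 2-week integrated sample per period, rotating
home-outdoor sites take one to three 2-week samples, and regulatory sites
take 24-hr samples every 3rd or 6th day. Network-specific measurement
distortions (multiplicative/additive bias standing in for protocol and
blank-correction differences, independent log-normal sampler noise, extra
day-to-day variability of 24-hr samples) are applied on the concentration
scale.

Co-located sites share coordinates, covariates and the location-level
random draws, so with zero distortion their series coincide exactly and a
paired comparison isolates the configured method distortions.

Randomness: a single study seed fans out to stage-specific child streams
via ``numpy.random.SeedSequence([seed, code])`` with codes 1 = sites,
2 = field, 3 = sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .grid import PeriodGrid
from .panel import PanelMatrix, Scale
from .records import (
    MeasurementRecord,
    Method,
    Network,
    Pollutant,
    SiteRecord,
)
from .trend import TrendFunction

_SEED_SITES, _SEED_FIELD, _SEED_SAMPLING = 1, 2, 3

#: Site counts per network for six study regions (regulatory sites within
#: 200 km of the city centre; study fixed and home-outdoor sites).
CITY_PRESETS: Dict[str, Dict[Network, int]] = {
    "los_angeles": {Network.CSN_CORE: 3, Network.CSN_SUPP: 3,
                    Network.IMPROVE: 8, Network.NPACT_FIXED: 7,
                    Network.NPACT_HOME: 116},
    "chicago": {Network.CSN_CORE: 4, Network.CSN_SUPP: 11,
                Network.IMPROVE: 1, Network.NPACT_FIXED: 7,
                Network.NPACT_HOME: 99},
    "minneapolis_st_paul": {Network.CSN_CORE: 2, Network.CSN_SUPP: 4,
                            Network.IMPROVE: 1, Network.NPACT_FIXED: 3,
                            Network.NPACT_HOME: 104},
    "baltimore": {Network.CSN_CORE: 8, Network.CSN_SUPP: 19,
                  Network.IMPROVE: 5, Network.NPACT_FIXED: 5,
                  Network.NPACT_HOME: 87},
    "new_york": {Network.CSN_CORE: 14, Network.CSN_SUPP: 11,
                 Network.IMPROVE: 3, Network.NPACT_FIXED: 3,
                 Network.NPACT_HOME: 107},
    "winston_salem": {Network.CSN_CORE: 2, Network.CSN_SUPP: 10,
                      Network.IMPROVE: 3, Network.NPACT_FIXED: 4,
                      Network.NPACT_HOME: 92},
}

#: Default per-network method tags (protocol bookkeeping only).
DEFAULT_METHODS: Dict[Network, Method] = {
    Network.NPACT_FIXED: Method.TOR_BLANKCORR,
    Network.NPACT_HOME: Method.TOR_BLANKCORR,
    Network.CSN_CORE: Method.TOR_NOBLANK,
    Network.CSN_SUPP: Method.TOT_NOBLANK,
    Network.IMPROVE: Method.TOR_BLANKCORR,
}

#: Default home-site visit-count distribution P(1,2,3) = (0.35, 0.5, 0.15),
#: mean 1.8 samples per site.
DEFAULT_VISIT_PROBS: Tuple[float, float, float] = (0.35, 0.5, 0.15)


@dataclass(frozen=True)
class FieldTruth:
    """Ground-truth parameters of the latent log-concentration field."""

    gamma0: np.ndarray          # covariate coefficients, long-term mean
    gamma1: np.ndarray          # covariate coefficients, trend amplitude
    trend_true: TrendFunction
    resid_sill: float = 0.04    # variance of the spatiotemporal residual
    resid_range_km: float = 10.0
    nugget: float = 0.0         # location-level iid variance
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "gamma0",
                           np.asarray(self.gamma0, dtype=float))
        object.__setattr__(self, "gamma1",
                           np.asarray(self.gamma1, dtype=float))
        if self.resid_sill < 0 or self.nugget < 0:
            raise ValueError("variances must be >= 0")
        if self.resid_range_km <= 0:
            raise ValueError("resid_range_km must be > 0")
        if self.gamma0.shape != self.gamma1.shape:
            raise ValueError("gamma0 and gamma1 must have equal length")


@dataclass(frozen=True)
class NetworkDistortion:
    """Measurement distortions applied to one network's records.

    ``mult_bias``/``add_bias`` act on the concentration scale (an additive
    offset after exponentiation shows up as a non-unit intercept on the log
    scale, the signature of blank-correction differences). ``noise_cv`` is
    the coefficient of variation of mean-one log-normal sampler noise;
    ``daily_cv`` adds day-to-day variability to 24-hr samples around the
    2-week latent mean.
    """

    mult_bias: float = 1.0
    add_bias: float = 0.0
    noise_cv: float = 0.0
    daily_cv: float = 0.0

    def __post_init__(self):
        if self.mult_bias <= 0:
            raise ValueError("mult_bias must be > 0")
        if self.noise_cv < 0 or self.daily_cv < 0:
            raise ValueError("noise CVs must be >= 0")


@dataclass(frozen=True)
class NetworkDesign:
    """Sampling schedule for one network.

    kind 'integrated': one 14-day record per grid period.
    kind 'home_visits': 1-3 14-day records at random periods.
    kind 'daily': 24-hr records every ``every_n_days`` across the grid.
    """

    kind: str
    every_n_days: int = 3
    offset_days: int = 0
    visit_probs: Tuple[float, float, float] = DEFAULT_VISIT_PROBS

    def __post_init__(self):
        if self.kind not in ("integrated", "home_visits", "daily"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if abs(sum(self.visit_probs) - 1.0) > 1e-9:
            raise ValueError("visit_probs must sum to 1")


DEFAULT_DESIGNS: Dict[Network, NetworkDesign] = {
    Network.NPACT_FIXED: NetworkDesign(kind="integrated"),
    Network.NPACT_HOME: NetworkDesign(kind="home_visits"),
    Network.CSN_CORE: NetworkDesign(kind="daily", every_n_days=3),
    Network.CSN_SUPP: NetworkDesign(kind="daily", every_n_days=6),
    Network.IMPROVE: NetworkDesign(kind="daily", every_n_days=3),
}


def default_trend(grid: PeriodGrid, phase_days: float = 0.0) -> TrendFunction:
    """Smooth annual seasonal trend evaluated at the period centres."""
    t0 = grid.period_center(0)
    days = np.array([(c - t0).days for c in grid.centers], dtype=float)
    f = np.sin(2 * np.pi * (days + phase_days) / 365.25)
    if np.linalg.norm(f) == 0:  # grid too short to resolve the cycle
        f = np.ones(grid.n_periods)
    return TrendFunction.from_values(grid, f)


def generate_sites(
    region_size_km: float,
    counts: Mapping[Network, int],
    n_covariates: int = 3,
    coloc_spec: Sequence[Tuple[Network, Network]] = (),
    seed: int = 0,
) -> List[SiteRecord]:
    """Draw site locations, covariates and co-location groups.

    Study (NPACT) and urban regulatory (CSN) sites cluster near the region
    centre; IMPROVE sites sit on the rural periphery. Covariates are one
    standardized distance-to-centre predictor (``dist_center``) plus
    ``n_covariates - 1`` iid standard normals. Each ``coloc_spec`` pair
    turns the next unused site of each named network into a co-located
    group sharing coordinates and covariates.
    """
    counts = {Network(k): int(v) for k, v in counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("site counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _SEED_SITES]))
    L = float(region_size_km)
    sites: List[SiteRecord] = []
    by_network: Dict[Network, List[int]] = {}

    def _covariates(x, y):
        dist = math.hypot(x, y) / (L / 4)  # ~unit scale near the core
        cov = {"dist_center": dist}
        for j in range(1, n_covariates):
            cov[f"g{j}"] = float(rng.standard_normal())
        return cov

    for network in Network:
        n = counts.get(network, 0)
        for i in range(n):
            if network == Network.IMPROVE:
                # peripheral ring
                r = rng.uniform(0.25 * L, 0.5 * L)
                th = rng.uniform(0, 2 * np.pi)
                x, y = r * np.cos(th), r * np.sin(th)
            else:
                # urban core cluster
                x, y = rng.normal(0.0, L / 10, size=2)
            sid = f"{network.value}_{i:03d}"
            sites.append(SiteRecord(
                site_id=sid, network=network, x_km=float(x), y_km=float(y),
                covariates=_covariates(x, y),
            ))
            by_network.setdefault(network, []).append(len(sites) - 1)

    used: Dict[Network, int] = {}
    for gi, (net_a, net_b) in enumerate(coloc_spec):
        net_a, net_b = Network(net_a), Network(net_b)
        for net in (net_a, net_b):
            if used.get(net, 0) >= len(by_network.get(net, [])):
                raise ValueError(
                    f"co-location requested for network {net.value} with "
                    f"no unused sites"
                )
        ia = by_network[net_a][used.get(net_a, 0)]
        ib = by_network[net_b][used.get(net_b, 0)]
        used[net_a] = used.get(net_a, 0) + 1
        used[net_b] = used.get(net_b, 0) + 1
        group = f"coloc_{gi}"
        a = sites[ia]
        sites[ia] = SiteRecord(
            site_id=a.site_id, network=a.network, x_km=a.x_km, y_km=a.y_km,
            covariates=a.covariates, coloc_group=group,
        )
        b = sites[ib]
        sites[ib] = SiteRecord(
            site_id=b.site_id, network=b.network, x_km=a.x_km, y_km=a.y_km,
            covariates=dict(a.covariates), coloc_group=group,
        )
    return sites


def _covariate_matrix(sites: Sequence[SiteRecord]) -> Tuple[np.ndarray, List[str]]:
    names = sorted(sites[0].covariates)
    X = np.array([[s.covariates[c] for c in names] for s in sites],
                 dtype=float)
    return X, names


def simulate_latent_panel(
    sites: Sequence[SiteRecord],
    grid: PeriodGrid,
    truth: FieldTruth,
) -> PanelMatrix:
    """Fully observed latent log-concentration panel.

    Per-period residual fields are zero-mean Gaussian with covariance
    ``resid_sill * exp(-d / resid_range_km)``, independent across periods;
    the nugget is drawn once per distinct location (co-located sites share
    both). Deterministic given ``truth.seed``.
    """
    sites = list(sites)
    X, _ = _covariate_matrix(sites)
    if X.shape[1] != truth.gamma0.shape[0]:
        raise ValueError(
            f"{X.shape[1]} covariates but gamma has length "
            f"{truth.gamma0.shape[0]}"
        )
    if truth.trend_true.grid.n_periods != grid.n_periods:
        raise ValueError("trend_true grid does not match the period grid")
    f = truth.trend_true.values
    mu = X @ truth.gamma0
    amp = X @ truth.gamma1
    latent = mu[:, None] + np.outer(amp, f)

    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed, _SEED_FIELD])
    )
    coords = np.array([[s.x_km, s.y_km] for s in sites])
    # distinct locations so co-located sites share the same draws
    uniq, inv = np.unique(coords.round(9), axis=0, return_inverse=True)
    m = len(uniq)
    if truth.resid_sill > 0:
        d = np.linalg.norm(uniq[:, None, :] - uniq[None, :, :], axis=-1)
        cov = truth.resid_sill * np.exp(-d / truth.resid_range_km)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
        eps = (chol @ rng.standard_normal((m, grid.n_periods)))[inv]
        latent = latent + eps
    if truth.nugget > 0:
        eta = math.sqrt(truth.nugget) * rng.standard_normal(m)
        latent = latent + eta[inv][:, None]

    return PanelMatrix(
        site_ids=[s.site_id for s in sites], grid=grid, values=latent,
        mask=np.ones_like(latent, dtype=bool), scale=Scale.LOG,
    )


def _lognormal_factor(rng, cv: float, size=None):
    """Mean-one log-normal multiplier with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size else 1.0
    s2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-s2 / 2, math.sqrt(s2), size=size))


def sample_network(
    latent: PanelMatrix,
    sites: Sequence[SiteRecord],
    design: Optional[Mapping[Network, NetworkDesign]] = None,
    distortion: Optional[Mapping[Network, NetworkDistortion]] = None,
    seed: int = 0,
    pollutant: Pollutant = Pollutant.EC,
) -> List[MeasurementRecord]:
    """Observe the latent field through each network's sampling design.

    Records carry concentrations ``exp(latent) * mult_bias + add_bias``
    perturbed by mean-one log-normal noise (``noise_cv``; 24-hr records
    additionally get ``daily_cv``), floored at zero. 24-hr values vary
    around the containing period's latent mean rather than a daily latent
    process — enough to reproduce the aggregation mismatch between 2-week
    and every-Nth-day sampling without daily meteorology.
    """
    if latent.scale != Scale.LOG:
        raise ValueError("latent panel must be on the LOG scale")
    design = {Network(k): v for k, v in (design or DEFAULT_DESIGNS).items()}
    distortion = {Network(k): v for k, v in (distortion or {}).items()}
    site_map = {s.site_id: s for s in sites}
    for sid in latent.site_ids:
        if sid not in site_map:
            raise ValueError(f"latent panel references unknown site {sid!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _SEED_SAMPLING])
    )
    grid = latent.grid
    records: List[MeasurementRecord] = []

    for i, sid in enumerate(latent.site_ids):
        site = site_map[sid]
        if site.network not in design:
            continue
        des = design[site.network]
        dist = distortion.get(site.network, NetworkDistortion())
        method = DEFAULT_METHODS[site.network]

        def conc(k: int, extra_cv: float = 0.0) -> float:
            v = math.exp(latent.values[i, k]) * dist.mult_bias + dist.add_bias
            v *= float(_lognormal_factor(rng, dist.noise_cv))
            if extra_cv > 0:
                v *= float(_lognormal_factor(rng, extra_cv))
            return max(v, 0.0)

        if des.kind == "integrated":
            for k in range(grid.n_periods):
                records.append(MeasurementRecord(
                    site_id=sid, pollutant=pollutant,
                    start_date=grid.period_start(k), duration_days=14,
                    value=conc(k), method=method,
                ))
        elif des.kind == "home_visits":
            n = int(rng.choice([1, 2, 3], p=des.visit_probs))
            n = min(n, grid.n_periods)
            ks = np.sort(rng.choice(grid.n_periods, size=n, replace=False))
            for k in ks:
                records.append(MeasurementRecord(
                    site_id=sid, pollutant=pollutant,
                    start_date=grid.period_start(int(k)), duration_days=14,
                    value=conc(int(k)), method=method,
                ))
        else:  # daily
            day = grid.start_date + timedelta(days=des.offset_days)
            while day < grid.end_date:
                k = (day - grid.start_date).days // 14
                records.append(MeasurementRecord(
                    site_id=sid, pollutant=pollutant,
                    start_date=day, duration_days=1,
                    value=conc(k, extra_cv=dist.daily_cv), method=method,
                ))
                day += timedelta(days=des.every_n_days)
    return records
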