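"""End-to-end orchestration: simulate -> harmonize -> compare -> trend ->
fit -> cv -> feasibility from one validated config, with a content-hashed
run manifest so identical config + seed reproduce identical artifacts."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from datetime import date
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .compatibility import (
    compare_colocated,
    compare_patterns,
    pair_colocated,
    smooth_temporal_pattern,
)
from .feasibility import FeasibilityInputs, FeasibilityThresholds, assess
from .grid import build_period_grid
from .harmonize import AggregationPolicy, to_two_week_panel, transform_panel
from .io import write_measurements, write_panel, write_sites
from .model import fit_simplified, loso_cv
from .panel import Scale
from .records import Network, Pollutant, REGULATORY_NETWORKS
from .synthetic import (
    CITY_PRESETS,
    FieldTruth,
    NetworkDistortion,
    default_trend,
    generate_sites,
    sample_network,
    simulate_latent_panel,
)
from .trend import extract_trend_svd, smooth_trend

STAGES = ["simulate", "harmonize", "compare", "trend", "fit", "cv",
          "feasibility"]


class ConfigError(ValueError):
    """The run configuration is malformed or has unknown keys."""


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Either ``region_preset`` (a named study-region preset) or explicit
    per-network ``counts`` selects the site design. Unknown keys anywhere
    in the config are rejected before any stage runs.
    """

    seed: int = 0
    region_preset: Optional[str] = "los_angeles"
    counts: Optional[Dict[str, int]] = None
    region_size_km: float = 60.0
    n_covariates: int = 3
    coloc_pairs: List[List[str]] = field(
        default_factory=lambda: [["NPACT_FIXED", "CSN_CORE"]])
    anchor_wednesday: str = "2007-03-07"
    n_periods: int = 40
    pollutant: str = "EC"
    gamma0: List[float] = field(default_factory=lambda: [0.5, 0.3, 0.0])
    gamma1: List[float] = field(default_factory=lambda: [1.5, 0.0, 0.2])
    resid_sill: float = 0.04
    resid_range_km: float = 10.0
    nugget: float = 0.01
    distortions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    min_daily_per_period: int = 2
    transform: str = "LOG1P"
    pattern_bandwidth: float = 6.0
    trend_bandwidth: float = 6.0
    min_obs_frac: float = 0.5
    amplitude_mode: str = "constant"
    add_intercept: bool = True
    single_trend_min_r: float = 0.8
    min_regulatory_sites: int = 10
    min_colocated_r: float = 0.8
    min_trend_r: float = 0.9
    min_study_fixed_sites: int = 3

    def __post_init__(self):
        if self.region_preset is not None \
                and self.region_preset not in CITY_PRESETS:
            raise ConfigError(
                f"unknown region preset {self.region_preset!r}; "
                f"known: {sorted(CITY_PRESETS)}"
            )
        if self.region_preset is None and not self.counts:
            raise ConfigError("either region_preset or counts is required")
        if len(self.gamma0) != self.n_covariates \
                or len(self.gamma1) != self.n_covariates:
            raise ConfigError(
                f"gamma0/gamma1 must have length n_covariates="
                f"{self.n_covariates}"
            )
        date.fromisoformat(self.anchor_wednesday)  # raises if malformed

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(obj) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**obj)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(obj, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(obj)

    def site_counts(self) -> Dict[Network, int]:
        if self.counts:
            return {Network(k): int(v) for k, v in self.counts.items()}
        return dict(CITY_PRESETS[self.region_preset])

    def network_distortions(self) -> Dict[Network, NetworkDistortion]:
        out = {}
        for net, spec in self.distortions.items():
            out[Network(net)] = NetworkDistortion(**spec)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute all stages, writing artifacts and a hashed manifest.

    Returns the manifest: per-stage artifact paths with SHA-256 content
    hashes, the config echo, and library versions. Any stage failure is
    re-raised annotated with the stage name; the partial manifest is still
    written to ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "versions": {
            "monitorharm": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    def record(stage: str, *paths: Path):
        manifest["stages"][stage] = {
            "artifacts": {p.name: _sha256(p) for p in sorted(paths)}
        }

    state: dict = {}
    try:
        for stage in STAGES:
            paths = _STAGE_FUNCS[stage](config, outdir, state)
            record(stage, *paths)
    except Exception as exc:
        _write_manifest(manifest, outdir)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _stage_simulate(cfg: RunConfig, outdir: Path, st: dict) -> Tuple[Path, ...]:
    grid = build_period_grid(date.fromisoformat(cfg.anchor_wednesday),
                             cfg.n_periods)
    sites = generate_sites(
        region_size_km=cfg.region_size_km, counts=cfg.site_counts(),
        n_covariates=cfg.n_covariates,
        coloc_spec=[tuple(p) for p in cfg.coloc_pairs], seed=cfg.seed,
    )
    truth = FieldTruth(
        gamma0=np.asarray(cfg.gamma0), gamma1=np.asarray(cfg.gamma1),
        trend_true=default_trend(grid), resid_sill=cfg.resid_sill,
        resid_range_km=cfg.resid_range_km, nugget=cfg.nugget,
        seed=cfg.seed,
    )
    latent = simulate_latent_panel(sites, grid, truth)
    records = sample_network(
        latent, sites, distortion=cfg.network_distortions(),
        seed=cfg.seed, pollutant=Pollutant(cfg.pollutant),
    )
    st.update(grid=grid, sites=sites, truth=truth, records=records)
    p_sites, p_meas = outdir / "sites.csv", outdir / "measurements.csv"
    p_truth = outdir / "truth.json"
    write_sites(sites, p_sites)
    write_measurements(records, p_meas)
    p_truth.write_text(json.dumps({
        "gamma0": truth.gamma0.tolist(), "gamma1": truth.gamma1.tolist(),
        "resid_sill": truth.resid_sill,
        "resid_range_km": truth.resid_range_km, "nugget": truth.nugget,
        "seed": truth.seed, "trend_true": truth.trend_true.values.tolist(),
    }, indent=2, sort_keys=True) + "\n")
    return p_sites, p_meas, p_truth


def _stage_harmonize(cfg: RunConfig, outdir: Path, st: dict):
    policy = AggregationPolicy(
        min_daily_per_period=cfg.min_daily_per_period,
        transform=Scale(cfg.transform),
    )
    raw = to_two_week_panel(st["records"], st["sites"], st["grid"], policy)
    panel = transform_panel(raw, policy)
    st.update(policy=policy, panel=panel)
    p_csv, p_json = outdir / "panel.csv", outdir / "panel.json"
    write_panel(panel, p_csv, p_json)
    return p_csv, p_json


def _stage_compare(cfg: RunConfig, outdir: Path, st: dict):
    sites, panel = st["sites"], st["panel"]
    by_net = lambda nets: [s.site_id for s in sites if s.network in nets]
    rows = []
    x_ids = by_net({Network.NPACT_FIXED})
    y_ids = by_net(REGULATORY_NETWORKS)
    pairs = pair_colocated(panel.subset(x_ids), panel.subset(y_ids), sites)
    for gid, ps in pairs.items():
        if ps.n_pairs >= 3:
            c = compare_colocated(ps)
            rows.append({
                "group_id": c.group_id, "network_x": c.network_x.value,
                "network_y": c.network_y.value, "n_pairs": c.n_pairs,
                "pearson_r": c.pearson_r, "slope": c.slope,
                "intercept": c.intercept, "mean_diff": c.mean_diff,
            })
    p_cmp = outdir / "comparisons.csv"
    pd.DataFrame(rows, columns=["group_id", "network_x", "network_y",
                                "n_pairs", "pearson_r", "slope",
                                "intercept", "mean_diff"]).to_csv(
        p_cmp, index=False)

    patterns = {}
    for label, nets in [("npact_fixed", {Network.NPACT_FIXED}),
                        ("npact_home", {Network.NPACT_HOME}),
                        ("regulatory", REGULATORY_NETWORKS)]:
        ids = [s for s in by_net(nets) if panel.mask[panel.row(s)].any()]
        if ids:
            try:
                pat = smooth_temporal_pattern(panel, ids,
                                              cfg.pattern_bandwidth)
            except ValueError:
                continue
            patterns[label] = pat
    st["patterns"] = patterns
    st["colocated_r"] = [r["pearson_r"] for r in rows]
    p_pat = outdir / "patterns.json"
    p_pat.write_text(json.dumps({
        k: {"values": [None if not np.isfinite(v) else float(v)
                       for v in pat.values],
            "bandwidth": pat.bandwidth, "n_sites_used": pat.n_sites_used}
        for k, pat in patterns.items()
    }, indent=2, sort_keys=True) + "\n")
    return p_cmp, p_pat


def _stage_trend(cfg: RunConfig, outdir: Path, st: dict):
    sites, panel = st["sites"], st["panel"]
    fixed = [s.site_id for s in sites if s.network == Network.NPACT_FIXED]
    raw_trend, report = extract_trend_svd(panel.subset(fixed),
                                          min_obs_frac=cfg.min_obs_frac)
    trend = smooth_trend(raw_trend, cfg.trend_bandwidth)
    st.update(trend=trend, trend_report=report)
    p = outdir / "trend.json"
    p.write_text(json.dumps({
        "anchor_wednesday": trend.grid.anchor_wednesday.isoformat(),
        "n_periods": trend.grid.n_periods,
        "values": trend.values.tolist(),
        "raw_values": raw_trend.values.tolist(),
        "bandwidth": cfg.trend_bandwidth,
        "converged": report.converged, "n_iter": report.n_iter,
        "n_sites_used": report.n_sites_used,
    }, indent=2, sort_keys=True) + "\n")
    return (p,)


def _stage_fit(cfg: RunConfig, outdir: Path, st: dict):
    sites, panel = st["sites"], st["panel"]
    npact = [s.site_id for s in sites
             if s.network in (Network.NPACT_FIXED, Network.NPACT_HOME)]
    npact_panel = panel.subset(npact)
    fit = fit_simplified(npact_panel, sites, st["trend"],
                         amplitude_mode=cfg.amplitude_mode,
                         add_intercept=cfg.add_intercept)
    st.update(fit=fit, npact_panel=npact_panel)
    p = outdir / "fit.json"
    fit.to_json(p)
    return (p,)


def _stage_cv(cfg: RunConfig, outdir: Path, st: dict):
    res = loso_cv(st["npact_panel"], st["sites"], st["trend"],
                  amplitude_mode=cfg.amplitude_mode,
                  add_intercept=cfg.add_intercept)
    st["cv"] = res
    p = outdir / "cv.json"
    p.write_text(json.dumps({
        "cv_r2": res.cv_r2,
        "failed_sites": res.failed_sites,
        "per_site": res.per_site.to_dict(orient="records"),
    }, indent=2, sort_keys=True) + "\n")
    return (p,)


def _stage_feasibility(cfg: RunConfig, outdir: Path, st: dict):
    sites, patterns = st["sites"], st["patterns"]
    n_reg = sum(1 for s in sites if s.network in REGULATORY_NETWORKS)
    n_fixed = sum(1 for s in sites if s.network == Network.NPACT_FIXED)
    groups = {s.coloc_group for s in sites if s.coloc_group}

    trend_agreement = []
    if "npact_fixed" in patterns and "regulatory" in patterns:
        try:
            pa = compare_patterns(patterns["npact_fixed"],
                                  patterns["regulatory"])
            trend_agreement.append(pa.pearson_r)
        except ValueError:
            pass
    single_trend_ok = False
    if "npact_fixed" in patterns and "npact_home" in patterns:
        try:
            pa = compare_patterns(patterns["npact_fixed"],
                                  patterns["npact_home"])
            single_trend_ok = pa.pearson_r >= cfg.single_trend_min_r
        except ValueError:
            pass

    inputs = FeasibilityInputs(
        n_regulatory_sites=n_reg, n_colocated_groups=len(groups),
        colocated_r=st.get("colocated_r", []),
        trend_agreement_r=trend_agreement,
        n_study_fixed_sites=n_fixed, single_trend_ok=single_trend_ok,
    )
    report = assess(inputs, FeasibilityThresholds(
        min_regulatory_sites=cfg.min_regulatory_sites,
        min_colocated_r=cfg.min_colocated_r,
        min_trend_r=cfg.min_trend_r,
        min_study_fixed_sites=cfg.min_study_fixed_sites,
    ))
    st["feasibility"] = report
    p_json, p_txt = outdir / "feasibility.json", outdir / "report.txt"
    report.to_json(p_json)
    p_txt.write_text(report.format_text() + "\n")
    return p_json, p_txt


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "harmonize": _stage_harmonize,
    "compare": _stage_compare,
    "trend": _stage_trend,
    "fit": _stage_fit,
    "cv": _stage_cv,
    "feasibility": _stage_feasibility,
}
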