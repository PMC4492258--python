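"""Domain record types shared by every pipeline stage.

A study region is described by a collection of :class:`SiteRecord` (one per
monitoring or home-outdoor location) and a long-format collection of
:class:`MeasurementRecord` (one per integrated sample). Both are plain
frozen dataclasses validated on construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Optional


class ValidationError(ValueError):
    """A record or a set of records violates a domain invariant."""


class SchemaError(ValueError):
    """An input table is missing required columns or is malformed."""


class Network(str, Enum):
    """Monitoring network / sampling design a site belongs to.

    NPACT_FIXED   fixed study sites, continuous 2-week integrated samples
    NPACT_HOME    rotating home-outdoor sites, one to three 2-week samples
    CSN_CORE      regulatory speciation sites sampling 24-hr every 3rd day
    CSN_SUPP      regulatory speciation sites sampling 24-hr every 6th day
    IMPROVE       mostly rural regulatory sites sampling 24-hr every 3rd day
    """

    NPACT_FIXED = "NPACT_FIXED"
    NPACT_HOME = "NPACT_HOME"
    CSN_CORE = "CSN_CORE"
    CSN_SUPP = "CSN_SUPP"
    IMPROVE = "IMPROVE"


#: Regulatory (non-study) networks, used for feasibility site counts.
REGULATORY_NETWORKS = frozenset(
    {Network.CSN_CORE, Network.CSN_SUPP, Network.IMPROVE}
)


class Pollutant(str, Enum):
    EC = "EC"
    OC = "OC"
    SILICON = "SILICON"
    SULFUR = "SULFUR"
    PM25 = "PM25"
    NOX = "NOX"


class Method(str, Enum):
    """Filter analysis / correction protocol tag.

    The statistical consequences of protocol differences (reflectance vs
    transmittance carbon splits, presence or absence of backup-filter blank
    correction) are emulated by the simulator as multiplicative/additive
    distortions; the tag records which protocol a record claims.
    """

    TOR_BLANKCORR = "TOR_BLANKCORR"
    TOR_NOBLANK = "TOR_NOBLANK"
    TOT_NOBLANK = "TOT_NOBLANK"
    GENERIC = "GENERIC"


@dataclass(frozen=True)
class SiteRecord:
    """One monitoring or home-outdoor location.

    Coordinates are pre-projected planar kilometres. ``covariates`` holds
    the geographic predictors used by the exposure model's mean structure;
    names must be identical across all sites of a region. Sites sharing a
    ``coloc_group`` value are co-located (same physical location, different
    networks/instruments).
    """

    site_id: str
    network: Network
    x_km: float
    y_km: float
    covariates: Mapping[str, float] = field(default_factory=dict)
    coloc_group: Optional[str] = None

    def __post_init__(self):
        if not self.site_id:
            raise ValidationError("site_id must be non-empty")
        if not (math.isfinite(self.x_km) and math.isfinite(self.y_km)):
            raise ValidationError(
                f"site {self.site_id}: coordinates must be finite"
            )
        object.__setattr__(self, "network", Network(self.network))
        object.__setattr__(self, "covariates", dict(self.covariates))
        for name, v in self.covariates.items():
            if not math.isfinite(float(v)):
                raise ValidationError(
                    f"site {self.site_id}: covariate {name!r} not finite"
                )


@dataclass(frozen=True)
class MeasurementRecord:
    """One integrated sample of one pollutant at one site.

    ``duration_days`` is 1 for regulatory 24-hr samples and 14 for the
    study's 2-week integrated samples. ``value`` is a concentration in
    µg/m³ and must be finite and non-negative.
    """

    site_id: str
    pollutant: Pollutant
    start_date: date
    duration_days: int
    value: float
    method: Method = Method.GENERIC
    flags: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "pollutant", Pollutant(self.pollutant))
        object.__setattr__(self, "method", Method(self.method))
        object.__setattr__(self, "flags", frozenset(self.flags))
        if self.duration_days not in (1, 14):
            raise ValidationError(
                f"{self.site_id} {self.start_date}: duration_days must be "
                f"1 or 14, got {self.duration_days}"
            )
        v = float(self.value)
        if not math.isfinite(v) or v < 0:
            raise ValidationError(
                f"{self.site_id} {self.start_date}: value must be finite "
                f"and >= 0, got {self.value}"
            )

    @property
    def key(self):
        return (self.site_id, self.pollutant, self.start_date,
                self.duration_days)


def check_unique_measurements(records: Iterable[MeasurementRecord]) -> None:
    """Raise if two records share (site, pollutant, start date, duration)."""
    seen = set()
    for r in records:
        if r.key in seen:
            raise ValidationError(f"duplicate measurement key {r.key}")
        seen.add(r.key)


def check_sites(sites: Iterable[SiteRecord]) -> None:
    """Raise if site ids repeat or covariate names differ across sites."""
    sites = list(sites)
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate site ids: {dup}")
    if sites:
        names = set(sites[0].covariates)
        for s in sites[1:]:
            if set(s.covariates) != names:
                raise ValidationError(
                    f"site {s.site_id}: covariate names "
                    f"{sorted(s.covariates)} differ from {sorted(names)}"
                )
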