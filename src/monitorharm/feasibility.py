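"""The three-approach modeling-feasibility decision as an explicit rule set.

Three candidate modeling strategies exist for PM2.5 component exposure
surfaces in a study region:

1. COMBINE_ALL — a full spatiotemporal model pooling the study campaign
   with the regulatory networks; viable only with enough regulatory sites
   and demonstrated between-network comparability at co-located monitors.
3. SURROGATE_TREND — the full model with temporal trends borrowed from a
   better-monitored pollutant; viable when the surrogate's trend agrees
   with the component's own.
2. STUDY_ONLY_SIMPLIFIED — the simplified single-trend model fit to study
   data alone; viable when one trend represents the home-site variability
   and enough fixed sites exist to estimate it.

The rules are evaluated in the order 1, 3, 2 (the narrative order in which
the alternatives are considered), falling through to NONE. Every numeric
threshold is configurable and echoed in the report so the decision is
auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from statistics import median
from typing import List, Optional, Sequence


class Approach(str, Enum):
    COMBINE_ALL = "COMBINE_ALL"                     # approach 1
    STUDY_ONLY_SIMPLIFIED = "STUDY_ONLY_SIMPLIFIED"  # approach 2
    SURROGATE_TREND = "SURROGATE_TREND"             # approach 3
    NONE = "NONE"

    @property
    def number(self) -> Optional[int]:
        return {"COMBINE_ALL": 1, "STUDY_ONLY_SIMPLIFIED": 2,
                "SURROGATE_TREND": 3}.get(self.value)


@dataclass(frozen=True)
class FeasibilityInputs:
    """Evidence summary the decision is made from."""

    n_regulatory_sites: int
    n_colocated_groups: int
    colocated_r: Sequence[float]
    trend_agreement_r: Sequence[float]
    n_study_fixed_sites: int
    single_trend_ok: bool

    def __post_init__(self):
        if self.n_regulatory_sites < 0 or self.n_colocated_groups < 0 \
                or self.n_study_fixed_sites < 0:
            raise ValueError("counts must be >= 0")
        for r in list(self.colocated_r) + list(self.trend_agreement_r):
            if not -1.0 <= float(r) <= 1.0:
                raise ValueError(f"correlation {r} outside [-1, 1]")


@dataclass(frozen=True)
class FeasibilityThresholds:
    min_regulatory_sites: int = 10
    min_colocated_r: float = 0.8
    min_trend_r: float = 0.9
    min_study_fixed_sites: int = 3


@dataclass
class Criterion:
    name: str
    passed: bool
    detail: str


@dataclass
class FeasibilityReport:
    approach: Approach
    criteria: List[Criterion]
    thresholds: FeasibilityThresholds
    narrative: List[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        obj = {
            "approach": self.approach.value,
            "approach_number": self.approach.number,
            "criteria": [
                {"name": c.name, "passed": c.passed, "detail": c.detail}
                for c in self.criteria
            ],
            "thresholds": {
                "min_regulatory_sites": self.thresholds.min_regulatory_sites,
                "min_colocated_r": self.thresholds.min_colocated_r,
                "min_trend_r": self.thresholds.min_trend_r,
                "min_study_fixed_sites":
                    self.thresholds.min_study_fixed_sites,
            },
            "narrative": self.narrative,
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def format_text(self) -> str:
        lines = [f"Recommended approach: {self.approach.value}"
                 + (f" (approach {self.approach.number})"
                    if self.approach.number else "")]
        for c in self.criteria:
            lines.append(f"  [{'PASS' if c.passed else 'fail'}] "
                         f"{c.name}: {c.detail}")
        lines.extend(f"  - {s}" for s in self.narrative)
        return "\n".join(lines)


def assess(
    inputs: FeasibilityInputs,
    thresholds: FeasibilityThresholds = FeasibilityThresholds(),
) -> FeasibilityReport:
    """Deterministic decision among the three approaches.

    Approach 1 requires both regulatory-site density and co-location
    comparability; failing that, approach 3 requires adequate surrogate
    trend agreement; failing that, approach 2 requires that a single trend
    represents the study data and enough fixed sites exist; else NONE.
    Per-group correlations are aggregated by the median (robust to one bad
    co-location). An empty correlation list fails its branch with reason
    "no evidence".
    """
    crits: List[Criterion] = []
    narrative: List[str] = []

    density_ok = inputs.n_regulatory_sites >= thresholds.min_regulatory_sites
    crits.append(Criterion(
        "regulatory site density", density_ok,
        f"{inputs.n_regulatory_sites} regulatory sites "
        f"(need >= {thresholds.min_regulatory_sites})",
    ))
    if inputs.colocated_r:
        med = median(inputs.colocated_r)
        compat_ok = med >= thresholds.min_colocated_r
        detail = (f"median co-located r = {med:.3f} over "
                  f"{len(inputs.colocated_r)} groups "
                  f"(need >= {thresholds.min_colocated_r})")
    else:
        compat_ok, detail = False, "no evidence (no co-located pairs)"
    crits.append(Criterion("between-network comparability", compat_ok,
                           detail))

    if inputs.trend_agreement_r:
        med_t = median(inputs.trend_agreement_r)
        surr_ok = med_t >= thresholds.min_trend_r
        detail_t = (f"median surrogate-trend r = {med_t:.3f} over "
                    f"{len(inputs.trend_agreement_r)} pollutants "
                    f"(need >= {thresholds.min_trend_r})")
    else:
        surr_ok, detail_t = False, "no evidence (no surrogate trends)"
    crits.append(Criterion("surrogate trend agreement", surr_ok, detail_t))

    crits.append(Criterion(
        "single-trend adequacy", inputs.single_trend_ok,
        "fixed-site pattern represents home-site variability"
        if inputs.single_trend_ok else
        "fixed-site pattern does not represent home-site variability",
    ))
    fixed_ok = inputs.n_study_fixed_sites >= thresholds.min_study_fixed_sites
    crits.append(Criterion(
        "study fixed-site count", fixed_ok,
        f"{inputs.n_study_fixed_sites} fixed sites "
        f"(need >= {thresholds.min_study_fixed_sites})",
    ))

    if density_ok and compat_ok:
        approach = Approach.COMBINE_ALL
        narrative.append(
            "Networks are dense and comparable: combine all data in the "
            "full spatiotemporal model."
        )
    elif surr_ok:
        approach = Approach.SURROGATE_TREND
        narrative.append(
            "Networks cannot be combined, but a surrogate pollutant's "
            "trend agrees well: fit the full model with borrowed trends."
        )
    elif inputs.single_trend_ok and fixed_ok:
        approach = Approach.STUDY_ONLY_SIMPLIFIED
        narrative.append(
            "Networks cannot be combined and no surrogate trend is "
            "adequate: fit the simplified single-trend model on study "
            "data only."
        )
    else:
        approach = Approach.NONE
        narrative.append(
            "No modeling approach is supported by the available evidence."
        )
    return FeasibilityReport(approach=approach, criteria=crits,
                             thresholds=thresholds, narrative=narrative)
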