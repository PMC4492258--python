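"""Readers and writers for the long-format measurement and site tables.

Measurement CSV columns: ``site_id,pollutant,start_date,duration_days,
value,method`` (ISO-8601 dates). Site CSV columns: ``site_id,network,x_km,
y_km,coloc_group`` plus one ``cov_<name>`` column per covariate. Panels are
exported as a wide CSV (one row per site, one column per period centre
date, empty cell = missing) with a JSON sidecar holding the scale tag and
grid anchor.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .grid import PeriodGrid, build_period_grid
from .panel import PanelMatrix, Scale
from .records import (
    MeasurementRecord,
    Method,
    Network,
    Pollutant,
    SchemaError,
    SiteRecord,
    ValidationError,
    check_sites,
    check_unique_measurements,
)

MEASUREMENT_COLUMNS = [
    "site_id", "pollutant", "start_date", "duration_days", "value", "method",
]
SITE_COLUMNS = ["site_id", "network", "x_km", "y_km", "coloc_group"]


def _resolve_schema(columns, required, schema):
    """Map canonical column names to file column names; raise on absence."""
    schema = dict(schema or {})
    mapping = {}
    missing = []
    for name in required:
        col = schema.get(name, name)
        if col not in columns:
            missing.append(col)
        mapping[name] = col
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    return mapping


def read_measurements(
    path, schema: Optional[Dict[str, str]] = None
) -> List[MeasurementRecord]:
    """Read a delimited measurement table into validated records.

    ``schema`` optionally maps canonical column names to the file's column
    names. Rows failing validation are reported together with their
    1-based file line numbers (header is line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_schema(df.columns, MEASUREMENT_COLUMNS[:5], schema)
    method_col = (schema or {}).get("method", "method")
    records, errors = [], []
    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        try:
            start = date.fromisoformat(row[cols["start_date"]].strip())
        except ValueError:
            errors.append(
                f"line {line}: unparseable date "
                f"{row[cols['start_date']]!r}"
            )
            continue
        try:
            method = (Method(row[method_col]) if method_col in df.columns
                      and row[method_col] else Method.GENERIC)
            rec = MeasurementRecord(
                site_id=row[cols["site_id"]],
                pollutant=Pollutant(row[cols["pollutant"]]),
                start_date=start,
                duration_days=int(row[cols["duration_days"]]),
                value=float(row[cols["value"]]),
                method=method,
            )
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            "invalid measurement rows:\n  " + "\n  ".join(errors)
        )
    check_unique_measurements(records)
    return records


def write_measurements(records: Sequence[MeasurementRecord], path) -> None:
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "pollutant": [r.pollutant.value for r in records],
            "start_date": [r.start_date.isoformat() for r in records],
            "duration_days": [r.duration_days for r in records],
            "value": [repr(float(r.value)) for r in records],
            "method": [r.method.value for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_sites(path, schema: Optional[Dict[str, str]] = None) -> List[SiteRecord]:
    """Read the site metadata table; ``cov_*`` columns become covariates."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_schema(df.columns, SITE_COLUMNS[:4], schema)
    coloc_col = (schema or {}).get("coloc_group", "coloc_group")
    cov_cols = [c for c in df.columns if c.startswith("cov_")]
    sites, errors = [], []
    for i, row in df.iterrows():
        line = i + 2
        try:
            coloc = (row[coloc_col] or None) if coloc_col in df.columns else None
            sites.append(SiteRecord(
                site_id=row[cols["site_id"]],
                network=Network(row[cols["network"]]),
                x_km=float(row[cols["x_km"]]),
                y_km=float(row[cols["y_km"]]),
                covariates={c[len("cov_"):]: float(row[c]) for c in cov_cols},
                coloc_group=coloc,
            ))
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError("invalid site rows:\n  " + "\n  ".join(errors))
    check_sites(sites)
    return sites


def write_sites(sites: Sequence[SiteRecord], path) -> None:
    cov_names = sorted(sites[0].covariates) if sites else []
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "network": s.network.value,
            "x_km": repr(float(s.x_km)),
            "y_km": repr(float(s.y_km)),
            "coloc_group": s.coloc_group or "",
        }
        for c in cov_names:
            row[f"cov_{c}"] = repr(float(s.covariates[c]))
        rows.append(row)
    pd.DataFrame(rows, columns=SITE_COLUMNS + [f"cov_{c}" for c in cov_names]
                 ).to_csv(path, index=False)


def write_panel(panel: PanelMatrix, csv_path, sidecar_path=None) -> None:
    """Wide CSV (site rows, period-centre columns) plus JSON sidecar."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    cols = [c.isoformat() for c in panel.grid.centers]
    body = np.full(panel.values.shape, "", dtype=object)
    for i, j in zip(*np.nonzero(panel.mask)):
        body[i, j] = repr(float(panel.values[i, j]))
    df = pd.DataFrame(body, columns=cols)
    df.insert(0, "site_id", panel.site_ids)
    df.to_csv(csv_path, index=False)
    meta = {
        "scale": panel.scale.value,
        "transform_c": None if np.isnan(panel.transform_c) else panel.transform_c,
        "anchor_wednesday": panel.grid.anchor_wednesday.isoformat(),
        "n_periods": panel.grid.n_periods,
    }
    sidecar_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_panel(csv_path, sidecar_path=None) -> PanelMatrix:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    grid = build_period_grid(
        date.fromisoformat(meta["anchor_wednesday"]), int(meta["n_periods"])
    )
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    if "site_id" not in df.columns:
        raise SchemaError("panel CSV lacks site_id column")
    expected = [c.isoformat() for c in grid.centers]
    if list(df.columns[1:]) != expected:
        raise SchemaError("panel CSV period columns do not match sidecar grid")
    cells = df[expected].to_numpy()
    mask = cells != ""
    values = np.full(cells.shape, np.nan)
    values[mask] = [float(v) for v in cells[mask]]
    c = meta.get("transform_c")
    return PanelMatrix(
        site_ids=list(df["site_id"]),
        grid=grid,
        values=values,
        mask=mask,
        scale=Scale(meta["scale"]),
        transform_c=float("nan") if c is None else float(c),
    )
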