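from datetime import date

import numpy as np
import pytest

from monitorharm import (
    FieldTruth,
    Network,
    SiteRecord,
    build_period_grid,
    default_trend,
)

ANCHOR = date(2007, 3, 7)  # a Wednesday


@pytest.fixture
def grid20():
    return build_period_grid(ANCHOR, 20)


@pytest.fixture
def grid100():
    return build_period_grid(ANCHOR, 100)


def make_sites(n, n_cov=2, network=Network.NPACT_FIXED, seed=0,
               coloc_group=None, prefix=None):
    """Simple hand-rolled site collection with iid normal covariates."""
    rng = np.random.default_rng(seed)
    prefix = prefix or network.value
    return [
        SiteRecord(
            site_id=f"{prefix}_{i:03d}",
            network=network,
            x_km=float(rng.uniform(-30, 30)),
            y_km=float(rng.uniform(-30, 30)),
            covariates={f"c{j}": float(rng.standard_normal())
                        for j in range(n_cov)},
            coloc_group=coloc_group,
        )
        for i in range(n)
    ]


def make_truth(grid, gamma0, gamma1, sill=0.0, range_km=10.0, nugget=0.0,
               seed=0):
    return FieldTruth(
        gamma0=np.asarray(gamma0, dtype=float),
        gamma1=np.asarray(gamma1, dtype=float),
        trend_true=default_trend(grid),
        resid_sill=sill, resid_range_km=range_km, nugget=nugget, seed=seed,
    )
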