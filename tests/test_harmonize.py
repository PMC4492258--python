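"""Aggregation to the 2-week grid, log transforms, and calendar thinning."""

from datetime import date, timedelta

import numpy as np
import pytest

from monitorharm import (
    AggregationPolicy,
    Network,
    Scale,
    build_period_grid,
    sample_network,
    simulate_latent_panel,
    subsample_every_sixth,
    to_two_week_panel,
    transform_panel,
)
from monitorharm.harmonize import ConflictError
from monitorharm.records import MeasurementRecord, Pollutant, ValidationError

from conftest import make_sites, make_truth


def daily(site, day, value):
    return MeasurementRecord(site, Pollutant.EC, day, 1, value)


def integrated(site, day, value):
    return MeasurementRecord(site, Pollutant.EC, day, 14, value)


@pytest.fixture
def grid3():
    return build_period_grid(date(2007, 3, 7), 3)


def test_daily_mean_and_completeness_rule(grid3):
    sites = make_sites(1, network=Network.CSN_CORE, seed=0)
    sid = sites[0].site_id
    d0 = grid3.period_start(0)
    recs = [daily(sid, d0 + timedelta(days=i), v)
            for i, v in [(0, 2.0), (3, 4.0), (6, 6.0)]]
    recs.append(daily(sid, grid3.period_start(1), 9.0))  # lone sample
    panel = to_two_week_panel(recs, sites, grid3,
                              AggregationPolicy(min_daily_per_period=2))
    assert panel.values[0, 0] == pytest.approx(4.0)
    assert not panel.mask[0, 1]  # one daily value < min 2 -> missing
    assert not panel.mask[0, 2]


def test_integrated_value_used_directly(grid3):
    sites = make_sites(1, seed=1)
    sid = sites[0].site_id
    recs = [integrated(sid, grid3.period_start(1), 3.25)]
    panel = to_two_week_panel(recs, sites, grid3)
    assert panel.values[0, 1] == 3.25
    assert panel.mask.sum() == 1


def test_conflict_between_durations(grid3):
    sites = make_sites(1, seed=2)
    sid = sites[0].site_id
    recs = [integrated(sid, grid3.period_start(0), 3.0),
            daily(sid, grid3.period_start(0) + timedelta(days=2), 2.0),
            daily(sid, grid3.period_start(0) + timedelta(days=5), 2.5)]
    with pytest.raises(ConflictError):
        to_two_week_panel(recs, sites, grid3)
    panel = to_two_week_panel(
        recs, sites, grid3, AggregationPolicy(prefer_integrated=True))
    assert panel.values[0, 0] == 3.0


def test_mixed_pollutants_rejected(grid3):
    sites = make_sites(1, seed=3)
    sid = sites[0].site_id
    recs = [daily(sid, grid3.period_start(0), 1.0),
            MeasurementRecord(sid, Pollutant.SILICON,
                              grid3.period_start(0) + timedelta(days=3),
                              1, 1.0)]
    with pytest.raises(ValidationError, match="mixed pollutants"):
        to_two_week_panel(recs, sites, grid3)


def test_aggregation_matches_brute_force_oracle():
    """Cell-by-cell equality with an oracle that re-scans all records."""
    grid = build_period_grid(date(2007, 3, 7), 40)
    sites = (make_sites(3, network=Network.NPACT_FIXED, seed=4)
             + make_sites(4, network=Network.CSN_CORE, seed=5)
             + make_sites(3, network=Network.CSN_SUPP, seed=6))
    truth = make_truth(grid, [0.5, 0.2], [0.6, 0.0], sill=0.05, seed=7)
    latent = simulate_latent_panel(sites, grid, truth)
    records = sample_network(latent, sites, seed=7)
    assert len(records) > 1000
    policy = AggregationPolicy(min_daily_per_period=2)
    panel = to_two_week_panel(records, sites, grid, policy)

    for i, sid in enumerate(panel.site_ids):
        for k, (p0, p1) in enumerate(grid.periods):
            ints, dailies = [], []
            for r in records:  # brute-force re-scan per cell
                if r.site_id != sid:
                    continue
                if r.duration_days == 1 and p0 <= r.start_date < p1:
                    dailies.append(r.value)
                elif r.duration_days == 14:
                    s_days = {r.start_date + timedelta(days=j)
                              for j in range(14)}
                    p_days = {p0 + timedelta(days=j) for j in range(14)}
                    if len(s_days & p_days) >= 10:
                        ints.append(r.value)
            if ints:
                assert panel.mask[i, k]
                assert panel.values[i, k] == np.mean(ints)
            elif len(dailies) >= 2:
                assert panel.mask[i, k]
                assert panel.values[i, k] == np.mean(dailies)
            else:
                assert not panel.mask[i, k]


def test_mask_monotone_in_min_daily(grid20):
    sites = make_sites(5, network=Network.CSN_SUPP, seed=8)
    truth = make_truth(grid20, [0.3, 0.0], [0.4, 0.1], sill=0.02, seed=8)
    latent = simulate_latent_panel(sites, grid20, truth)
    records = sample_network(latent, sites, seed=8)
    masks = [
        to_two_week_panel(records, sites, grid20,
                          AggregationPolicy(min_daily_per_period=m)).mask
        for m in (1, 2, 3, 4)
    ]
    for lo, hi in zip(masks, masks[1:]):
        assert not np.any(hi & ~lo)  # raising threshold never unmasks


@pytest.mark.parametrize("value, expected", [(0.0, 0.0),
                                             (np.e - 1.0, 1.0)])
def test_log1p_transform_values(grid3, value, expected):
    sites = make_sites(1, seed=9)
    recs = [integrated(sites[0].site_id, grid3.period_start(0), value)]
    panel = transform_panel(to_two_week_panel(recs, sites, grid3),
                            AggregationPolicy(transform=Scale.LOG1P))
    assert panel.values[0, 0] == pytest.approx(expected, abs=1e-12)
    assert panel.scale == Scale.LOG1P


def test_logc_constant_recomputed_directly(grid3):
    sites = make_sites(1, seed=10)
    sid = sites[0].site_id
    vals = [2.0, 3.0, 4.0]
    recs = [integrated(sid, grid3.period_start(k), v)
            for k, v in enumerate(vals)]
    raw = to_two_week_panel(recs, sites, grid3)
    panel = transform_panel(raw, AggregationPolicy(transform=Scale.LOGC))
    c = 0.1 * np.mean(vals)
    np.testing.assert_allclose(panel.values[0], np.log(np.array(vals) + c))
    assert panel.transform_c == pytest.approx(c)


def test_transform_is_invertible_and_single_shot(grid20):
    sites = make_sites(4, network=Network.NPACT_FIXED, seed=11)
    truth = make_truth(grid20, [0.5, 0.1], [0.3, 0.0], sill=0.03, seed=11)
    latent = simulate_latent_panel(sites, grid20, truth)
    raw = to_two_week_panel(sample_network(latent, sites, seed=11), sites,
                            grid20)
    for scale in (Scale.LOG1P, Scale.LOGC):
        t = transform_panel(raw, AggregationPolicy(transform=scale))
        back = np.exp(t.values[t.mask]) - t.transform_c
        np.testing.assert_allclose(back, raw.values[raw.mask], rtol=1e-12)
        with pytest.raises(ValueError, match="already transformed"):
            transform_panel(t)


def test_zero_noise_round_trip_recovers_latent(grid20):
    """Zero-distortion sampling then aggregation inverts the simulator."""
    sites = (make_sites(3, network=Network.NPACT_FIXED, seed=12)
             + make_sites(3, network=Network.CSN_CORE, seed=13))
    truth = make_truth(grid20, [0.8, 0.2], [0.5, 0.0], sill=0.04, seed=12)
    latent = simulate_latent_panel(sites, grid20, truth)
    raw = to_two_week_panel(sample_network(latent, sites, seed=12), sites,
                            grid20)
    assert raw.mask.all()
    np.testing.assert_allclose(raw.values, np.exp(latent.values), rtol=1e-10)


def test_subsample_phases_partition_the_calendar():
    d0 = date(2007, 3, 1)
    recs = [daily("a", d0 + timedelta(days=3 * i), float(i))
            for i in range(10)]
    p0 = subsample_every_sixth(recs, phase=0)
    p1 = subsample_every_sixth(recs, phase=1)
    assert [r.value for r in p0] == [0.0, 2.0, 4.0, 6.0, 8.0]
    assert [r.value for r in p1] == [1.0, 3.0, 5.0, 7.0, 9.0]
    assert sorted(p0 + p1, key=lambda r: r.start_date) == recs
    gaps = {(b.start_date - a.start_date).days for a, b in zip(p0, p0[1:])}
    assert gaps == {6}


def test_subsample_irregular_calendar_warns():
    recs = [daily("a", date(2007, 3, 1), 1.0),
            daily("a", date(2007, 3, 4), 2.0),
            daily("a", date(2007, 3, 9), 3.0)]
    with pytest.warns(UserWarning, match="irregular"):
        out = subsample_every_sixth(recs, phase=0)
    assert len(out) == 2


def test_thinned_panel_matches_full_panel_noise_free(grid20):
    """1-in-3 vs thinned 1-in-6 aggregation agrees exactly without noise."""
    sites = make_sites(1, network=Network.CSN_CORE, seed=14)
    truth = make_truth(grid20, [1.0, 0.0], [1.2, 0.0], seed=14)
    latent = simulate_latent_panel(sites, grid20, truth)
    records = sample_network(latent, sites, seed=14)
    thinned = subsample_every_sixth(records, phase=0)
    full = to_two_week_panel(records, sites, grid20)
    thin = to_two_week_panel(thinned, sites, grid20)
    both = full.mask[0] & thin.mask[0]
    assert both.sum() >= 10
    r = np.corrcoef(full.values[0, both], thin.values[0, both])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)
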