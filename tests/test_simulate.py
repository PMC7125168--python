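"""Synthetic-data generator: shapes, reproducibility, planted-effect recovery,
and the coupled-oscillator timeseries mode."""

import numpy as np
import pytest

from connectoml import (
    Band,
    PlantedEdge,
    SyntheticSpec,
    compute_wpli,
    edge_ttest,
    generate_coupled_timeseries,
    generate_edge_dataset,
    study_spec,
    timeseries_dataset,
)


def test_study_scale_dataset_has_4005_edges():
    spec = study_spec(seed=0, n_planted=0, effect_size=0.0)
    ds = generate_edge_dataset(spec, "Theta")
    assert ds.X.shape == (44, 4005)
    assert ds.class_counts() == (21, 23)
    assert 0 <= ds.X.min() and ds.X.max() <= 1


def test_reproducible_and_band_validated():
    spec = study_spec(seed=5, n_planted=3, n_regions=10, n_group1=4, n_group2=4)
    a = generate_edge_dataset(spec, "Alpha")
    b = generate_edge_dataset(spec, "Alpha")
    assert np.array_equal(a.X, b.X)
    c = generate_edge_dataset(spec.with_seed(6), "Alpha")
    assert not np.array_equal(a.X, c.X)
    with pytest.raises(KeyError, match="Delta"):
        generate_edge_dataset(spec, "Delta")


def test_null_spec_rejects_at_nominal_rate():
    """With no planted effect the per-edge test is calibrated near alpha."""
    rates = []
    for seed in range(5):
        spec = study_spec(seed=seed, n_planted=0, effect_size=0.0)
        ds = generate_edge_dataset(spec, "Beta")
        rates.append(edge_ttest(ds, alpha=0.01).significant.mean())
    pooled = np.mean(rates)  # 5 x 4005 edges
    assert 0.005 < pooled < 0.016


def test_single_strong_edge_attains_smallest_p():
    """One planted edge at d=3 should win the p-value race almost always."""
    wins = 0
    n_reps = 100
    for seed in range(n_reps):
        spec = SyntheticSpec(
            n_group1=22, n_group2=21, n_regions=15, seed=seed,
            planted={"Alpha": (PlantedEdge(edge=17, direction="increase", effect_size=3.0),)},
        )
        ds = generate_edge_dataset(spec, "Alpha")
        res = edge_ttest(ds)
        wins += int(np.argmin(res.p_value) == 17)
    assert wins >= 0.95 * n_reps


def test_planted_direction_is_monotone_on_the_observed_scale():
    spec = SyntheticSpec(
        n_group1=30, n_group2=30, n_regions=10, seed=1,
        planted={"Alpha": (
            PlantedEdge(edge=2, direction="increase", effect_size=2.0),
            PlantedEdge(edge=5, direction="decrease", effect_size=2.0),
        )},
    )
    ds = generate_edge_dataset(spec, "Alpha")
    case = ds.X[ds.labels == 1]
    ctrl = ds.X[ds.labels == 0]
    assert case[:, 2].mean() > ctrl[:, 2].mean()
    assert case[:, 5].mean() < ctrl[:, 5].mean()


def test_spec_validation():
    with pytest.raises(ValueError, match="out of range"):
        SyntheticSpec(n_regions=5, planted={"Alpha": (PlantedEdge(100, "increase", 1.0),)})
    with pytest.raises(ValueError, match="direction"):
        PlantedEdge(0, "sideways", 1.0)
    with pytest.raises(ValueError, match="degenerate band"):
        Band("X", 10.0, 10.0)


# -- timeseries mode ---------------------------------------------------------


def _ts_spec(seed=0, strength=0.5, d=0.0, lag=np.pi / 2, n1=6, n2=6, n_regions=4):
    planted = {}
    if d or strength:
        planted = {"Alpha": (PlantedEdge(0, "increase", d),)}
    return SyntheticSpec(
        n_group1=n1, n_group2=n2, n_regions=n_regions, seed=seed, mode="timeseries",
        bands=(Band("Alpha", 8, 14),), planted=planted, coupling_strength=strength,
        coupling_phase_lag=lag, n_epochs=40, sampling_rate=200.0, epoch_length=2.0,
    )


def test_uncoupled_regions_show_chance_level_wpli():
    spec = _ts_spec(strength=0.0)
    ds = timeseries_dataset(spec, "Alpha")
    assert ds.X.max() < 0.35  # no pair shows strong synchrony


def test_full_strength_noiseless_pair_attains_wpli_one():
    spec = _ts_spec(strength=1.0, lag=np.pi / 4)
    epochs = generate_coupled_timeseries(spec, "Alpha", subject=spec.n_group1)  # control
    pair = epochs[:, [0, 1], :]
    assert compute_wpli(pair, spec.sampling_rate, (8, 14)) == 1.0


def test_zero_lag_coupling_warns():
    spec = _ts_spec(strength=0.5, lag=0.0)
    with pytest.warns(UserWarning, match="zero-lag"):
        generate_coupled_timeseries(spec, "Alpha", subject=0)


def test_coupling_difference_detected_by_edge_ttest():
    """Case pairs at ~0.8 vs control 0.2 coupling: detected in most replicates."""
    hits = 0
    n_reps = 25
    for seed in range(n_reps):
        spec = _ts_spec(seed=seed, strength=0.2, d=2.0, n1=12, n2=12, n_regions=2)
        ds = timeseries_dataset(spec, "Alpha")
        res = edge_ttest(ds, alpha=0.01)
        hits += int(res.significant[0] and res.direction[0] == "increase")
    assert hits >= 0.9 * n_reps


def test_direct_and_timeseries_modes_agree_on_directionality():
    """Planted edges shift the same way in both generation modes."""
    agree = total = 0
    for seed in range(10):
        base = study_spec(
            seed=seed, n_planted=3, effect_size=1.5, n_regions=6,
            n_group1=10, n_group2=10, bands=(Band("Alpha", 8, 14),),
        )
        direct = generate_edge_dataset(base, "Alpha")
        from dataclasses import replace

        ts = replace(base, mode="timeseries", coupling_strength=0.4,
                     n_epochs=40, sampling_rate=200.0)
        tsds = timeseries_dataset(ts, "Alpha")
        for p in base.ground_truth().edges("Alpha"):
            want = 1 if p.direction == "increase" else -1
            for ds in (direct, tsds):
                col = int(np.where(ds.edge_ids == p.edge)[0][0])
                diff = ds.X[ds.labels == 1, col].mean() - ds.X[ds.labels == 0, col].mean()
                agree += int(np.sign(diff) == want)
                total += 1
    assert agree / total >= 0.9
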