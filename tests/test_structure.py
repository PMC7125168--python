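"""Z-scoring, two-way hierarchical clustering, and PCA reports."""

import numpy as np
import pytest

from connectoml import hierarchical_clusters, pca_report, study_spec, zscore_edges
from connectoml.simulate import generate_edge_dataset
from connectoml.structure import STAGES
from connectoml.univariate import edge_ttest, filter_significant


def test_zscore_arithmetic_and_round_trip():
    X = np.array([[0.2, 0.5], [0.4, 0.5], [0.6, 0.5]])
    z, zero_var = zscore_edges(X)
    assert np.allclose(z[:, 0], [-1, 0, 1])  # sample SD (ddof=1)
    assert zero_var.tolist() == [False, True]
    assert np.all(z[:, 1] == 0)
    # de-standardising recovers the input
    mu, sd = X.mean(0), X.std(0, ddof=1)
    back = z * np.where(zero_var, 1.0, sd) + mu
    assert np.allclose(back[:, 0], X[:, 0], atol=1e-12)


def _dataset(seed=0, d=0.0, n_planted=0, n1=10, n2=10):
    spec = study_spec(seed=seed, n_planted=n_planted, effect_size=d, n_regions=12,
                      n_group1=n1, n_group2=n2)
    return spec, generate_edge_dataset(spec, "Alpha")


def test_separated_groups_cluster_perfectly():
    _, ds = _dataset(seed=1, d=4.0, n_planted=12)
    rep = hierarchical_clusters(ds, k=2)
    assert rep.n_misplaced == 0
    assert rep.ari == 1.0
    assert rep.confusion.to_numpy().sum() == ds.n_subjects


def test_single_cluster_is_label_marginals():
    _, ds = _dataset(seed=2)
    rep = hierarchical_clusters(ds, k=1)
    assert set(rep.assignments) == {0}
    counts = rep.confusion.to_numpy().ravel()
    assert sorted(counts.tolist()) == sorted(ds.class_counts())


def test_null_data_clusters_near_chance():
    misplaced = [
        hierarchical_clusters(_dataset(seed=s)[1], k=2).n_misplaced for s in range(20)
    ]
    # with no group structure the 2-cut should misplace a nontrivial number
    assert np.mean(misplaced) > 2


def test_clustering_invariant_to_subject_order():
    _, ds = _dataset(seed=3, d=2.0, n_planted=6)
    rep = hierarchical_clusters(ds, k=2)
    rng = np.random.default_rng(0)
    perm = rng.permutation(ds.n_subjects)
    shuffled = ds.select_subjects([ds.subject_ids[i] for i in perm])
    rep2 = hierarchical_clusters(shuffled, k=2)
    assert rep.n_misplaced == rep2.n_misplaced
    assert rep.ari == pytest.approx(rep2.ari, abs=1e-12)


def test_pca_rank_one_data_explains_everything():
    rng = np.random.default_rng(5)
    direction = rng.uniform(size=10)
    coords = np.linspace(0.1, 0.9, 8)
    X = 0.05 + np.outer(coords, direction) / 3
    from connectoml import ConnectomeDataset, EdgeIndex

    ds = ConnectomeDataset(
        subject_ids=[f"s{i}" for i in range(8)], labels=[0] * 4 + [1] * 4,
        band="Alpha", X=X, edge_index=EdgeIndex([f"r{i}" for i in range(5)]),
    )
    rep = pca_report(ds, n_components=2)
    assert rep.explained_pct[0] == pytest.approx(100.0, abs=1e-8)


def test_pca_matches_eigendecomposition_oracle():
    _, ds = _dataset(seed=6)
    sub = ds.select_edges(range(20)).select_subjects(ds.subject_ids[:10])
    rep = pca_report(sub, n_components=5)
    z, _ = zscore_edges(sub.X)
    eig = np.sort(np.linalg.eigvalsh(np.cov(z, rowvar=False)))[::-1]
    expected = 100 * eig[:5] / eig.sum()
    assert np.allclose(rep.explained_pct, expected, atol=1e-8)
    assert np.all(np.diff(rep.explained_pct) <= 1e-12)  # non-increasing
    assert rep.explained_pct.sum() <= 100 + 1e-9


def test_filtering_concentrates_leading_variance():
    """The significant-edge stage should load more variance on PC1+PC2 than
    the all-edges stage when a real group effect exists."""
    wins = 0
    for seed in range(10):
        spec = study_spec(seed=seed, n_planted=10, effect_size=2.0, n_regions=20,
                          n_group1=12, n_group2=12)
        ds = generate_edge_dataset(spec, "Alpha")
        res = edge_ttest(ds)
        if res.significant.sum() < 3:
            continue
        filt = filter_significant(ds, res)
        all_pct = pca_report(ds, stage="all_edges").leading_pct()
        sig_pct = pca_report(filt, stage="significant").leading_pct()
        wins += int(sig_pct > all_pct)
    assert wins >= 8


def test_stage_tags_validated():
    _, ds = _dataset(seed=7)
    with pytest.raises(ValueError):
        pca_report(ds, stage="bogus")
    assert set(STAGES) == {"all_edges", "significant", "selected"}
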