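"""PLS-DA / VIP verification arm: NIPALS identities, VIP formula oracle,
cross-validated classification, and concordance with the SVM arm."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression

from connectoml import (
    PipelineConfig,
    fit_plsda,
    generate_edge_dataset,
    plsda_cv_performance,
    study_spec,
    train_final_svm,
    vip_scores,
)


def _toy(seed=0, n=12, p=6, signal=2.0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    X = rng.standard_normal((n, p))
    X[y == 1, 0] += signal
    return X, y


def test_exact_predictor_concentrates_component_one():
    rng = np.random.default_rng(1)
    n, p = 14, 5
    y = np.r_[np.ones(7, int), np.zeros(7, int)]
    f = np.where(y == 1, 1.0, -1.0)
    X = rng.standard_normal((n, p))
    X -= np.outer(f, f @ X) / (f @ f)  # noise columns orthogonal to the classes
    X[:, 2] = f  # y is exactly this column
    model = fit_plsda(X, y, n_components=1)
    w = np.abs(model.weights[:, 0])
    assert w[2] == pytest.approx(1.0, abs=1e-6)
    assert np.all(w[np.arange(p) != 2] < 1e-6)


def test_deflation_leaves_residual_orthogonal_to_scores():
    X, y = _toy(seed=2)
    model = fit_plsda(X, y, n_components=2)
    z = (X - model.x_mean) / model.x_sd
    residual = z - model.scores @ model.loadings.T
    assert np.allclose(model.scores.T @ residual, 0, atol=1e-8)
    # scores orthogonal across components
    gram = model.scores.T @ model.scores
    assert abs(gram[0, 1]) < 1e-8


def test_component_one_is_dominant_cross_covariance_direction():
    """Oracle: the first weight vector is the top eigenvector of X'yy'X."""
    X, y = _toy(seed=3, n=10, p=6)
    model = fit_plsda(X, y, n_components=1)
    z = (X - X.mean(0)) / X.std(0, ddof=1)
    f = np.where(y == 1, 1.0, -1.0)
    f = f - f.mean()
    m = np.outer(z.T @ f, f @ z)
    eigvals, eigvecs = np.linalg.eigh(m)
    top = eigvecs[:, -1]
    w = model.weights[:, 0]
    assert abs(abs(top @ w) - 1.0) < 1e-8  # collinear up to sign


def test_matches_sklearn_pls_first_direction():
    X, y = _toy(seed=4, n=16, p=8)
    model = fit_plsda(X, y, n_components=2)
    ref = PLSRegression(n_components=2, scale=True).fit(X, np.where(y == 1, 1.0, -1.0))
    for a in range(2):
        w_mine = model.weights[:, a]
        w_ref = ref.x_weights_[:, a]
        assert abs(abs(w_mine @ w_ref) - 1.0) < 1e-6


def test_vip_single_predictor_and_symmetry():
    rng = np.random.default_rng(5)
    y = np.r_[np.ones(8, int), np.zeros(8, int)]
    # two exchangeable informative predictors, one component
    X = np.column_stack([np.where(y == 1, 1.0, -1.0), np.where(y == 1, 1.0, -1.0)])
    X = X + 1e-6 * rng.standard_normal(X.shape)
    model = fit_plsda(X, y, n_components=1)
    vip = vip_scores(model)
    assert np.allclose(vip, 1.0, atol=1e-3)  # equal weights -> all VIP = 1


def test_vip_matches_formula_transcription():
    X, y = _toy(seed=6, n=10, p=6)
    model = fit_plsda(X, y, n_components=2)
    vip = vip_scores(model)
    # literal transcription: VIP_j = sqrt(p * sum_a ssy_a (w_aj/||w_a||)^2 / sum_a ssy_a)
    p = X.shape[1]
    ssy = model.y_loadings**2 * np.sum(model.scores**2, axis=0)
    expected = np.empty(p)
    for j in range(p):
        acc = sum(
            ssy[a] * (model.weights[j, a] / np.linalg.norm(model.weights[:, a])) ** 2
            for a in range(2)
        )
        expected[j] = np.sqrt(p * acc / ssy.sum())
    assert np.allclose(vip, expected, atol=1e-12)


@given(st.integers(min_value=0, max_value=5000))
@settings(deadline=None, max_examples=20)
def test_vip_normalisation_identity(seed):
    """Sum of squared VIPs equals the number of predictors, always."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 20))
    p = int(rng.integers(2, 9))
    y = np.zeros(n, int)
    y[: n // 2] = 1
    X = rng.standard_normal((n, p)) + 0.5 * y[:, None] * rng.standard_normal(p)[None, :]
    a = min(2, min(n - 1, p))
    model = fit_plsda(X, y, n_components=a)
    vip = vip_scores(model)
    assert np.all(vip >= 0)
    assert np.sum(vip**2) == pytest.approx(p, abs=1e-8)


def test_separable_and_shuffled_cv_accuracy():
    X, y = _toy(seed=7, n=20, p=4, signal=6.0)
    acc, fold_accs = plsda_cv_performance(X, y, n_components=2, k_folds=5, seed=0)
    assert acc == 1.0 and len(fold_accs) == 5
    null_accs = []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        null_accs.append(
            plsda_cv_performance(X, rng.permutation(y), n_components=2, k_folds=5, seed=seed)[0]
        )
    assert 0.3 < np.mean(null_accs) < 0.7


def test_concordance_with_svm_on_strong_effect():
    """Both classifiers should agree (within 0.15) on clearly separable data."""
    gaps = []
    for seed in range(10):
        spec = study_spec(seed=seed, n_planted=6, effect_size=2.5, n_regions=12,
                          n_group1=12, n_group2=12)
        ds = generate_edge_dataset(spec, "Alpha")
        edges = spec.ground_truth().edge_ids("Alpha")
        cfg = PipelineConfig(k_folds=5)
        svm = train_final_svm(ds, edges, cfg, seed=seed)
        sel = ds.select_edges(edges)
        pls, _ = plsda_cv_performance(sel.X, sel.labels, n_components=2, k_folds=5, seed=seed)
        gaps.append(abs(svm.cv_mean - pls))
    assert np.median(gaps) <= 0.15


def test_planted_edges_get_higher_vip(light_config):
    above = 0
    for seed in range(10):
        spec = study_spec(seed=seed, n_planted=5, effect_size=1.5, n_regions=12,
                          n_group1=14, n_group2=14)
        ds = generate_edge_dataset(spec, "Alpha")
        model = fit_plsda(ds.X, ds.labels, n_components=2)
        vip = vip_scores(model)
        planted = spec.ground_truth().edge_ids("Alpha")
        mask = np.isin(ds.edge_ids, planted)
        above += int(vip[mask].mean() > vip[~mask].mean())
    assert above >= 9  # one-sided sign test at 10 trials


def test_degenerate_inputs_rejected():
    X, y = _toy(seed=8)
    with pytest.raises(ValueError):
        fit_plsda(X, np.ones_like(y), n_components=1)  # single class
    with pytest.raises(ValueError):
        fit_plsda(X, y, n_components=50)
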