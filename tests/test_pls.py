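"""NIPALS PLS engine: oracle equivalences, VIP, CV, jackknife, pruning."""

import numpy as np
import pandas as pd
import pytest

from gcqsrr import pls_qsrr as pls


def _ols_predictions(X, y):
    D = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return D @ beta


def test_single_descriptor_equal_to_response_fits_exactly():
    y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    model = pls.fit_pls(y[:, None], y, 1)
    np.testing.assert_allclose(model.predict(y[:, None]), y, atol=1e-10)
    assert model.vip_[0] == pytest.approx(1.0)


def test_full_rank_pls_equals_least_squares():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(40, 6))
    y = rng.normal(size=40)
    model = pls.fit_pls(X, y, 6)
    np.testing.assert_allclose(model.predict(X), _ols_predictions(X, y), rtol=1e-6, atol=1e-8)


def test_matches_sklearn_pls_at_fixed_components():
    """Independent cross-check against the reference PLS implementation."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(22)
    X = rng.normal(size=(50, 8))
    y = X[:, 0] - 2 * X[:, 3] + rng.normal(0, 0.3, 50)
    for A in (1, 2, 4):
        ours = pls.fit_pls(X, y, A).predict(X)
        theirs = PLSRegression(n_components=A, scale=True).fit(X, y).predict(X).ravel()
        np.testing.assert_allclose(ours, theirs, rtol=1e-8, atol=1e-8)


def test_constant_response_rejected():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError, match="zero variance"):
        pls.fit_pls(X, np.ones(10), 1)


def test_components_beyond_rank_truncated():
    rng = np.random.default_rng(23)
    base = rng.normal(size=(20, 2))
    X = np.column_stack([base, base @ rng.normal(size=(2, 3))])  # rank 2
    y = rng.normal(size=20)
    with pytest.warns(UserWarning, match="rank"):
        model = pls.fit_pls(X, y, 5)
    assert model.n_components <= 2


def test_training_rmse_non_increasing_in_components():
    rng = np.random.default_rng(24)
    X = rng.normal(size=(60, 10))
    y = X @ rng.normal(size=10) + rng.normal(0, 0.5, 60)
    rmses = []
    for A in range(1, 8):
        m = pls.fit_pls(X, y, A)
        rmses.append(float(np.sqrt(np.mean((y - m.predict(X)) ** 2))))
    assert all(b <= a + 1e-10 for a, b in zip(rmses, rmses[1:]))


def test_vip_mean_square_is_one():
    rng = np.random.default_rng(25)
    X = rng.normal(size=(80, 12))
    y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.2, 80)
    m = pls.fit_pls(X, y, 3)
    assert float((m.vip_**2).mean()) == pytest.approx(1.0, abs=1e-10)


def test_vip_separates_informative_descriptor():
    rng = np.random.default_rng(26)
    X = rng.normal(size=(200, 2))
    y = X[:, 0] + rng.normal(0, 0.1, 200)
    m = pls.fit_pls(X, y, 1)
    assert m.vip_[0] > 1.0 > m.vip_[1]


def test_select_components_two_latent_factors():
    rng = np.random.default_rng(27)
    T = rng.normal(size=(200, 2))
    L = rng.normal(size=(2, 20))
    X = T @ L + rng.normal(0, 1e-6, (200, 20))
    y = T @ np.array([1.0, 1.0])
    y = y + rng.normal(0, 0.01 * y.std(), 200)
    A, record = pls.select_components(X, y, seed=5)
    assert A == 2
    assert record["q2"].iloc[1] > 0.99


def test_select_components_pure_noise():
    rng = np.random.default_rng(28)
    X = rng.normal(size=(100, 10))
    y = rng.normal(size=100)
    A, record = pls.select_components(X, y, seed=5)
    assert A == 1
    assert record["q2"].iloc[0] <= 0.05  # no genuine predictive power


def test_select_components_group_count_exceeds_n():
    with pytest.raises(ValueError):
        pls.select_components(np.ones((5, 2)), np.arange(5.0), n_groups=7)


def test_jackknife_halfwidths_vanish_without_noise():
    rng = np.random.default_rng(29)
    X = rng.normal(size=(70, 4))
    y = X @ np.array([1.0, -2.0, 0.5, 3.0])
    hw = pls.coefficient_uncertainty(X, y, 4, seed=2)
    assert np.abs(hw).max() <= 1e-8


def test_jackknife_within_factor_two_of_bootstrap():
    """The leave-one-group-out half-width tracks a bootstrap SE oracle."""
    from scipy import stats

    rng = np.random.default_rng(30)
    n, k = 500, 5
    X = rng.normal(size=(n, k))
    beta = np.array([1.0, 0.5, -1.0, 0.0, 2.0])
    y = X @ beta + rng.normal(0, 1.0, n)
    hw = pls.coefficient_uncertainty(X, y, k, seed=2)
    boots = []
    for _ in range(60):
        idx = rng.integers(0, n, n)
        boots.append(pls.fit_pls(X[idx], y[idx], k).coef_)
    se = np.asarray(boots).std(axis=0, ddof=1)
    oracle = stats.t.ppf(0.975, 6) * se
    ratio = hw / oracle
    assert np.all(ratio > 0.5) and np.all(ratio < 2.0)


def test_uninformative_descriptor_flagged_uncertain():
    hits = 0
    for rep in range(10):
        rng = np.random.default_rng(100 + rep)
        X = rng.normal(size=(150, 3))
        y = 2.0 * X[:, 0] + rng.normal(0, 0.5, 150)  # columns 1..2 pure noise
        A = 1
        hw = pls.coefficient_uncertainty(X, y, A, seed=rep)
        coef = pls.fit_pls(X, y, A).coef_
        if hw[2] > abs(coef[2]):
            hits += 1
    assert hits >= 9


def test_stepwise_pruning_recovers_informative_descriptors():
    rng = np.random.default_rng(31)
    n = 300
    X_info = rng.normal(size=(n, 5))
    X_noise = rng.normal(size=(n, 45))
    X = pd.DataFrame(
        np.column_stack([X_info, X_noise]),
        columns=[f"info{j}" for j in range(5)] + [f"junk{j}" for j in range(45)],
    )
    y = X_info @ np.array([2.0, -1.5, 1.0, 0.8, -1.2]) + rng.normal(0, 0.3, n)
    result = pls.prune_descriptors(X, y, "stepwise", seed=4)
    kept_info = [c for c in result.kept if c.startswith("info")]
    assert len(kept_info) >= 4
    # batch-size contract: no round removes more than ten descriptors
    assert all(len(h["dropped"]) <= 10 for h in result.history)


def test_importance_pruning_drops_low_vip():
    rng = np.random.default_rng(32)
    X = pd.DataFrame(rng.normal(size=(200, 6)), columns=list("abcdef"))
    y = 3.0 * X["a"] + rng.normal(0, 0.2, 200)
    result = pls.prune_descriptors(X, y, "importance", seed=4)
    assert "a" in result.kept
    assert len(result.kept) < 6


def test_prune_unknown_strategy():
    with pytest.raises(ValueError):
        pls.prune_descriptors(pd.DataFrame(np.ones((10, 2))), np.arange(10.0), "magic")


def test_group_models_dispatch_and_fallback():
    rng = np.random.default_rng(33)
    n = 80
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("wxyz"),
                     index=[f"c{i}" for i in range(n)])
    y = pd.Series(X["w"].to_numpy() + rng.normal(0, 0.1, n), index=X.index)
    groups = {f"c{i}": (1 if i < 3 else 4) for i in range(n)}  # group 1 tiny
    gm = pls.fit_group_models(X, y, groups, seed=6)
    assert 1 in gm.fallback_groups
    assert 4 in gm.local_models
    pred = gm.predict(X, groups)
    assert set(pred["model"]) == {"global", "group_4"}
    assert len(pred) == n
    # unlabeled compound falls back to the global model
    pred2 = gm.predict(X.iloc[:2], {})
    assert set(pred2["model"]) == {"global"}


def test_predictions_in_original_units():
    rng = np.random.default_rng(34)
    X = rng.normal(size=(60, 3))
    y = 1000.0 + 500.0 * X[:, 0] + rng.normal(0, 5.0, 60)  # seconds-scale
    m = pls.fit_pls(X, y, 2)
    pred = m.predict(X)
    assert abs(pred.mean() - y.mean()) < 10.0  # same scale, not standardized


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(35)
    X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    y = X["a"] * 2 + rng.normal(0, 0.1, 50)
    m = pls.fit_pls(X, y, 2, response_name="t1R_s")
    path = tmp_path / "model.json"
    pls.save_model(m, path)
    back = pls.load_model(path)
    np.testing.assert_allclose(back.predict(X), m.predict(X), rtol=1e-12)
    assert back.response_name == "t1R_s"
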