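"""RMSE_P statistics, benchmarks, ensembles, domain checks and screening."""

import numpy as np
import pandas as pd
import pytest

from gcqsrr import evaluation_screening as ev


def test_perfect_predictions():
    rep = ev.evaluate_predictions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert rep.rmsep == 0.0
    assert rep.average_deviation == 0.0
    assert rep.percentile_95 == 0.0


def test_rmsep_n_minus_one_denominator():
    rep = ev.evaluate_predictions([0.0, 0.0], [1.0, 1.0])
    assert rep.rmsep == pytest.approx(np.sqrt(2.0))
    assert rep.n_relative_skipped == 2  # zero observations excluded

    rep2 = ev.evaluate_predictions([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert rep2.rmsep == pytest.approx(1.0)  # SSE = 2, N-1 = 2
    assert rep2.average_deviation == pytest.approx(2.0 / 3.0)


def test_rmsep_constant_offset_identity():
    """RMSE_P(y, y+c) = |c|·sqrt(N/(N−1)) for any constant offset c."""
    rng = np.random.default_rng(51)
    for n, c in [(10, 3.0), (77, -0.4), (2, 5.0)]:
        y = rng.normal(size=n)
        rep = ev.evaluate_predictions(y, y + c)
        assert rep.rmsep == pytest.approx(abs(c) * np.sqrt(n / (n - 1)))


def test_percentile_linear_interpolation_convention():
    resid = np.arange(1.0, 101.0)
    rep = ev.evaluate_predictions(resid, np.zeros(100))
    assert rep.percentile_95 == pytest.approx(95.05)


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        ev.evaluate_predictions([1.0], [1.0])


def test_benchmark_exact_linear_in_descriptor():
    rng = np.random.default_rng(52)
    X = pd.DataFrame({"bp": rng.uniform(50, 350, 100)})
    y = 10.0 * X["bp"] + 5.0
    bench, mean = ev.benchmark_models(X.iloc[:60], y.iloc[:60], X.iloc[60:], y.iloc[60:], ["bp"])
    assert bench.rmsep == pytest.approx(0.0, abs=1e-8)
    assert mean.rmsep > 100.0


def test_mean_baseline_matches_response_sd():
    rng = np.random.default_rng(53)
    X = pd.DataFrame({"bp": rng.normal(size=4000)})
    y = pd.Series(rng.normal(0.0, 2.0, 4000))
    _, mean = ev.benchmark_models(X.iloc[:2000], y.iloc[:2000], X.iloc[2000:], y.iloc[2000:], ["bp"])
    assert mean.rmsep == pytest.approx(2.0, rel=0.1)


def test_benchmark_missing_descriptor():
    X = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(ValueError, match="missing"):
        ev.benchmark_models(X, [1.0, 2.0], X, [1.0, 2.0], ["bp"])


def test_ensemble_average():
    np.testing.assert_allclose(
        ev.ensemble_average([100.0, 200.0], [300.0, 400.0]), [200.0, 300.0]
    )
    x = np.array([1.0, 2.0])
    np.testing.assert_allclose(ev.ensemble_average(x, x), x)
    with pytest.raises(ValueError):
        ev.ensemble_average([1.0], [1.0, 2.0])


def test_ensemble_tightens_error_window():
    """Averaging two unbiased predictors with independent errors shrinks the
    95-percentile in most replicates."""
    rng = np.random.default_rng(54)
    wins = 0
    for _ in range(20):
        y = rng.normal(size=300)
        pa = y + rng.normal(0, 1.0, 300)
        pb = y + rng.normal(0, 1.0, 300)
        p95 = lambda p: ev.evaluate_predictions(y, p).percentile_95
        if p95(ev.ensemble_average(pa, pb)) <= min(p95(pa), p95(pb)):
            wins += 1
    assert wins >= 16  # >= 80% of replicates


def test_applicability_domain_training_and_outliers():
    rng = np.random.default_rng(55)
    X = pd.DataFrame(rng.normal(size=(250, 8)), columns=[f"d{j}" for j in range(8)])
    ad = ev.fit_applicability_domain(X, n_components=3)
    chk = ad.check(X)
    assert chk["in_domain"].mean() >= 0.95
    far = ad.check(X * 10.0)  # ten times the training spread
    assert far["in_domain"].mean() < 0.05


def test_applicability_domain_fresh_draws_mostly_inside():
    rng = np.random.default_rng(56)
    X = pd.DataFrame(rng.normal(size=(300, 6)), columns=[f"d{j}" for j in range(6)])
    Xnew = pd.DataFrame(rng.normal(size=(200, 6)), columns=X.columns)
    ad = ev.fit_applicability_domain(X, n_components=3)
    assert ad.check(Xnew)["in_domain"].mean() >= 0.9


def _candidates(deltas, window, response="LRI"):
    exp = {response: 1500.0}
    cand = pd.DataFrame({response: [1500.0 + d for d in deltas]},
                        index=[f"c{i}" for i in range(len(deltas))])
    return exp, cand, {response: window}


def test_screening_boundary_inclusive():
    exp, cand, win = _candidates([0.0, 100.0, 100.0001], 100.0)
    verdicts = ev.filter_candidates(exp, cand, win)
    assert [v.verdict for v in verdicts] == ["retained", "retained", "eliminated"]


def test_screening_counts():
    w = 100.0
    exp, cand, win = _candidates([0.5 * w, 1.5 * w, 2.0 * w], w)
    verdicts = ev.filter_candidates(exp, cand, win)
    assert sum(v.verdict == "retained" for v in verdicts) == 1
    assert sum(v.verdict == "eliminated" for v in verdicts) == 2


def test_screening_exhaustive_small_enumeration():
    """Cross-check against a brute-force oracle over two responses."""
    rng = np.random.default_rng(57)
    exp = {"LRI": 1500.0, "PEG2I": 40.0}
    win = {"LRI": 90.0, "PEG2I": 12.0}
    cand = pd.DataFrame(
        {
            "LRI": 1500.0 + rng.uniform(-200, 200, 40),
            "PEG2I": 40.0 + rng.uniform(-30, 30, 40),
        },
        index=[f"c{i}" for i in range(40)],
    )
    verdicts = {v.candidate_id: v.verdict for v in ev.filter_candidates(exp, cand, win)}
    for cid, row in cand.iterrows():
        keep = all(abs(row[r] - exp[r]) <= win[r] for r in exp)
        assert verdicts[cid] == ("retained" if keep else "eliminated")


def test_screening_out_of_domain_retained_but_flagged():
    exp, cand, win = _candidates([0.0], 100.0)
    verdicts = ev.filter_candidates(exp, cand, win, in_domain={"c0": False})
    assert verdicts[0].verdict == "retained"
    assert verdicts[0].in_domain is False
    assert verdicts[0].flags


def test_screening_requires_shared_response():
    with pytest.raises(ValueError):
        ev.filter_candidates(
            {"LRI": 1500.0},
            pd.DataFrame({"PEG2I": [40.0]}, index=["c0"]),
            {"LRI": 100.0, "PEG2I": 10.0},
        )


def test_screening_rejects_nonpositive_window():
    exp, cand, _ = _candidates([0.0], 100.0)
    with pytest.raises(ValueError):
        ev.filter_candidates(exp, cand, {"LRI": 0.0})
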