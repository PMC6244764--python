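"""Prediction-quality statistics, benchmarks, applicability domain and
candidate screening.

The central error statistic is the root-mean-square error of prediction
with an N−1 denominator,

    RMSE_P = sqrt( Σ (y_obs − y_pred)² / (N − 1) ),

reported together with the average (absolute) deviation, the average
relative deviation and the 95th percentile of absolute residuals. The
95-percentile doubles as the error window used to screen candidate
structures in non-target work: a candidate whose predicted retention lies
outside the window around the experimental value is eliminated.

Reference models for benchmarking are a one/two-descriptor least-squares
fit (boiling point for the first dimension; logK_OW and weight-normalized
logK_OW for the second) and the constant mean-of-training predictor.

The applicability domain is defined on the training descriptors through
PCA: Hotelling T² over the retained components against the 95% F-based
limit, plus the residual distance to the model against the 95% quantile of
training residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .splitting import PCAModel, run_pca

log = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "ScreeningVerdict",
    "evaluate_predictions",
    "benchmark_models",
    "ensemble_average",
    "ApplicabilityDomain",
    "fit_applicability_domain",
    "filter_candidates",
]


@dataclass
class EvaluationReport:
    """Summary statistics of one set of predictions."""

    n: int
    rmsep: float
    average_deviation: float
    average_relative_deviation: float
    percentile_95: float
    residuals: np.ndarray
    response: str = ""
    set_name: str = ""
    n_relative_skipped: int = 0


def evaluate_predictions(
    y_obs, y_pred, response: str = "", set_name: str = ""
) -> EvaluationReport:
    """Compute RMSE_P (N−1 denominator) and deviation statistics.

    Relative deviations are |residual| / y_obs; points with y_obs = 0 are
    skipped and counted.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("y_obs and y_pred differ in length")
    n = y_obs.size
    if n < 2:
        raise ValueError("need at least 2 points (N-1 denominator)")
    resid = y_obs - y_pred
    rmsep = float(np.sqrt((resid**2).sum() / (n - 1)))
    abs_resid = np.abs(resid)
    nonzero = y_obs != 0
    skipped = int((~nonzero).sum())
    if skipped:
        log.warning("%d observations are zero; skipped in relative deviation", skipped)
    rel = abs_resid[nonzero] / np.abs(y_obs[nonzero]) if nonzero.any() else np.array([np.nan])
    return EvaluationReport(
        n=n,
        rmsep=rmsep,
        average_deviation=float(abs_resid.mean()),
        average_relative_deviation=float(rel.mean()),
        percentile_95=float(np.percentile(abs_resid, 95)),  # linear interpolation
        residuals=resid,
        response=response,
        set_name=set_name,
        n_relative_skipped=skipped,
    )


#: benchmark descriptors per response family
BENCHMARK_DESCRIPTORS = {
    "first": ["bp"],
    "second": ["logKow", "logKow_per_MW"],
}


def benchmark_models(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    descriptors: list[str],
    response: str = "",
) -> tuple[EvaluationReport, EvaluationReport]:
    """Reference models: simple least squares on named descriptors, and the
    mean-of-training constant predictor. Returns (benchmark, mean) reports.
    """
    missing = [d for d in descriptors if d not in X_train.columns]
    if missing:
        raise ValueError(f"benchmark descriptors missing from table: {missing}")
    ytr = np.asarray(y_train, dtype=float).ravel()
    yte = np.asarray(y_test, dtype=float).ravel()
    D = np.column_stack([np.ones(len(X_train))] + [X_train[d].to_numpy(float) for d in descriptors])
    beta, *_ = np.linalg.lstsq(D, ytr, rcond=None)
    Dte = np.column_stack([np.ones(len(X_test))] + [X_test[d].to_numpy(float) for d in descriptors])
    bench = evaluate_predictions(yte, Dte @ beta, response=response, set_name="benchmark")
    mean = evaluate_predictions(
        yte, np.full_like(yte, ytr.mean()), response=response, set_name="mean_baseline"
    )
    return bench, mean


def ensemble_average(pred_a, pred_b) -> np.ndarray:
    """Elementwise mean of two aligned prediction vectors."""
    a = np.asarray(pred_a, dtype=float).ravel()
    b = np.asarray(pred_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("prediction vectors differ in length")
    return (a + b) / 2.0


@dataclass
class ApplicabilityDomain:
    """PCA-based model domain fitted on the training descriptors."""

    pca: PCAModel
    score_var: np.ndarray  # per-component training score variance
    t2_limit: float
    dmodx_limit: float

    def check(self, X: pd.DataFrame) -> pd.DataFrame:
        """Hotelling T² and residual distance for new rows; in-domain iff
        both are within their training-set limits."""
        T = self.pca.transform(X).to_numpy(dtype=float)
        t2 = ((T**2) / self.score_var).sum(axis=1)
        Z = ((X[self.pca.mean.index] - self.pca.mean) / self.pca.scale).to_numpy(float)
        resid = Z - T @ self.pca.loadings.T
        dmodx = np.sqrt((resid**2).mean(axis=1))
        in_domain = (t2 <= self.t2_limit) & (dmodx <= self.dmodx_limit)
        return pd.DataFrame(
            {"t2": t2, "dmodx": dmodx, "in_domain": in_domain}, index=X.index
        )


def fit_applicability_domain(
    X_train: pd.DataFrame, n_components: int = 5, alpha: float = 0.05
) -> ApplicabilityDomain:
    """Fit the PCA domain model.

    ``alpha`` is the overall training-set exclusion rate; it is split
    between the two criteria (Bonferroni), so in-domain = (T² within the
    F-based 1−α/2 limit for a new observation, A(n−1)(n+1)/(n(n−A)) ·
    F(A, n−A)) AND (residual distance within the empirical 1−α/2 training
    quantile). Intersecting two marginal 1−α cuts would exclude up to 2α
    of the training set itself; halving the rates keeps the joint
    training-set coverage at ≥ 1−α.
    """
    pca = run_pca(X_train, n_components=n_components)
    T = pca.scores.to_numpy(dtype=float)
    n, A = T.shape
    score_var = T.var(axis=0, ddof=1)
    score_var = np.where(score_var > 0, score_var, 1.0)
    f = stats.f.ppf(1 - alpha / 2, A, n - A)
    t2_limit = A * (n - 1) * (n + 1) / (n * (n - A)) * f
    Z = ((X_train[pca.mean.index] - pca.mean) / pca.scale).to_numpy(float)
    resid = Z - T @ pca.loadings.T
    dmodx = np.sqrt((resid**2).mean(axis=1))
    dmodx_limit = float(np.quantile(dmodx, 1 - alpha / 2, method="higher"))
    return ApplicabilityDomain(
        pca=pca, score_var=score_var, t2_limit=float(t2_limit), dmodx_limit=dmodx_limit
    )


@dataclass
class ScreeningVerdict:
    """Screening outcome for one candidate structure."""

    candidate_id: str
    predicted: dict
    experimental: dict
    within_window: dict
    in_domain: bool
    verdict: str  # retained | eliminated
    flags: list[str] = field(default_factory=list)


def filter_candidates(
    experimental: dict,
    candidates: pd.DataFrame,
    windows: dict,
    in_domain: dict | None = None,
) -> list[ScreeningVerdict]:
    """Eliminate candidate structures whose predicted retention falls outside
    the error window of the measured peak.

    ``experimental`` maps response → measured value for the unknown;
    ``candidates`` holds one row per candidate with predicted values per
    response; ``windows`` maps response → 95-percentile half-width. A
    candidate is eliminated iff |predicted − experimental| exceeds the
    window for any shared response (boundary inclusive = retained).
    Out-of-domain candidates are retained but flagged: higher errors are to
    be expected outside the model domain.
    """
    for resp, w in windows.items():
        if w <= 0:
            raise ValueError(f"window for {resp} must be positive")
    shared = [r for r in experimental if r in candidates.columns and r in windows]
    if not shared:
        raise ValueError("no response shared between experimental values, "
                         "candidate predictions and windows")
    in_domain = in_domain or {}
    verdicts = []
    for cid, row in candidates.iterrows():
        within = {}
        for resp in shared:
            within[resp] = bool(abs(row[resp] - experimental[resp]) <= windows[resp])
        ok = all(within.values())
        dom = bool(in_domain.get(cid, True))
        flags = [] if dom else ["out_of_domain_higher_errors_expected"]
        verdicts.append(
            ScreeningVerdict(
                candidate_id=str(cid),
                predicted={r: float(row[r]) for r in shared},
                experimental={r: float(experimental[r]) for r in shared},
                within_window=within,
                in_domain=dom,
                verdict="retained" if ok else "eliminated",
                flags=flags,
            )
        )
    return verdicts
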