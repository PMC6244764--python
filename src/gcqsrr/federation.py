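"""Federation-of-local-models retention predictor.

A knowledge base holds compounds with known retention responses and a
vector of physico-chemical similarity properties. For each query the k
most similar entries are selected (continuous Dice coefficient or
Euclidean-distance similarity) and a small least-squares regression is
fitted on just those neighbors, with the number of regression parameters
capped by the "compounds per parameter" rule: at most floor(k/m)
properties enter the local equation (the intercept is free).

First-dimension retention times are handled in minutes inside this module
and converted back to seconds at the boundary; this mirrors how such
knowledge bases are commonly imported and is numerically a pure unit
relabeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FederationConfig",
    "KnowledgeBase",
    "LocalPrediction",
    "similarity",
    "select_neighbors",
    "predict_federated",
    "leave_one_out",
]

#: responses stored internally in minutes (first-dimension times)
_MINUTE_RESPONSES = {"t1R", "t1R_s"}


@dataclass(frozen=True)
class FederationConfig:
    """Settings of the federated predictor.

    metric: similarity metric for the neighbor search.
    k: number of similar compounds used for the local model (20 or 25 in
       typical use).
    m: compounds per regression parameter (3 or 4); at most floor(k/m)
       properties enter the local equation.
    property_set: which similarity properties to use — "all",
       "no_abraham", or "abraham_only" (Abraham = E, S, A, B, L).
    """

    metric: str = "dice"
    k: int = 25
    m: int = 4
    property_set: str = "all"
    include_self: bool = False
    rss_tol: float = 0.01

    def __post_init__(self):
        if self.metric not in {"dice", "euclidean"}:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.k < 2 * self.m:
            raise ValueError("k must allow at least a 2-parameter local model (k >= 2m)")

    @property
    def max_parameters(self) -> int:
        return self.k // self.m


ABRAHAM = ("E", "S", "A", "B", "L")


def _select_properties(names: list[str], property_set: str) -> list[str]:
    if property_set == "all":
        return list(names)
    if property_set == "abraham_only":
        sel = [n for n in names if n in ABRAHAM]
    elif property_set == "no_abraham":
        sel = [n for n in names if n not in ABRAHAM]
    else:
        raise ValueError(f"unknown property set {property_set!r}")
    if not sel:
        raise ValueError(f"property set {property_set!r} selects no properties")
    return sel


class KnowledgeBase:
    """Compounds with known responses and scaled similarity properties."""

    def __init__(
        self,
        properties: pd.DataFrame,
        responses: pd.DataFrame,
        property_set: str = "all",
    ):
        if not properties.index.equals(responses.index):
            responses = responses.reindex(properties.index)
        names = _select_properties([str(c) for c in properties.columns], property_set)
        self.property_names = names
        self.ids = [str(i) for i in properties.index]
        P = properties[names].astype(float)
        self._mean = P.mean()
        self._sd = P.std(ddof=1).where(lambda s: s > 0, 1.0)
        self._min = P.min()
        self._range = (P.max() - P.min()).where(lambda s: s > 0, 1.0)
        self.scaled = ((P - self._mean) / self._sd).to_numpy(dtype=float)
        self.unit = ((P - self._min) / self._range).clip(lower=0.0).to_numpy(dtype=float)
        self.responses = responses

    def __len__(self) -> int:
        return len(self.ids)

    def prepare_query(self, query: pd.Series | dict) -> tuple[np.ndarray, np.ndarray]:
        """Scale a raw property vector into (autoscaled, unit-interval) forms."""
        q = pd.Series(query).reindex(self.property_names).astype(float)
        if q.isna().any():
            missing = q.index[q.isna()].tolist()
            raise ValueError(f"query missing properties: {missing}")
        scaled = ((q - self._mean) / self._sd).to_numpy(dtype=float)
        unit = ((q - self._min) / self._range).clip(lower=0.0).to_numpy(dtype=float)
        return scaled, unit

    def response_vector(self, response: str) -> np.ndarray:
        y = self.responses[response].to_numpy(dtype=float)
        if response in _MINUTE_RESPONSES:
            return y / 60.0  # seconds -> minutes inside the module
        return y


@dataclass
class LocalPrediction:
    """Output of one federated prediction."""

    predicted: float
    neighbor_ids: list[str]
    similarities: list[float]
    parameters: list[str]
    local_rmse: float
    flags: list[str] = field(default_factory=list)


def similarity(a: np.ndarray, b: np.ndarray, metric: str = "dice") -> float:
    """Similarity of two prepared property vectors, in [0, 1].

    Dice (continuous form, on nonnegative min-max-rescaled vectors):
    2·Σaᵢbᵢ / (Σaᵢ² + Σbᵢ²). Euclidean: 1 / (1 + d(a, b)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"property vectors differ in length: {a.shape} vs {b.shape}")
    if metric == "dice":
        denom = (a**2).sum() + (b**2).sum()
        if denom == 0:
            return 1.0  # two all-zero vectors are identical
        return float(2.0 * (a * b).sum() / denom)
    if metric == "euclidean":
        return float(1.0 / (1.0 + np.linalg.norm(a - b)))
    raise ValueError(f"unknown metric {metric!r}")


def select_neighbors(
    kb: KnowledgeBase,
    query: pd.Series | dict,
    config: FederationConfig,
    query_id: str | None = None,
) -> list[tuple[str, float]]:
    """Top-k knowledge-base entries by similarity to the query.

    Ties are broken by lexicographic compound id. The query's own entry is
    excluded (leave-one-out evaluation) unless ``config.include_self``.
    """
    scaled_q, unit_q = kb.prepare_query(query)
    mat = kb.unit if config.metric == "dice" else kb.scaled
    qv = unit_q if config.metric == "dice" else scaled_q
    if config.metric == "dice":
        denom = (mat**2).sum(axis=1) + (qv**2).sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.where(denom > 0, 2.0 * mat @ qv / np.maximum(denom, 1e-300), 1.0)
    else:
        sims = 1.0 / (1.0 + np.linalg.norm(mat - qv, axis=1))

    entries = list(zip(kb.ids, sims.astype(float)))
    if not config.include_self and query_id is not None:
        entries = [(i, s) for i, s in entries if i != str(query_id)]
    if len(entries) < config.k:
        raise ValueError(
            f"knowledge base has {len(entries)} usable entries, fewer than k={config.k}"
        )
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries[: config.k]


def predict_federated(
    kb: KnowledgeBase,
    query: pd.Series | dict,
    response: str,
    config: FederationConfig,
    query_id: str | None = None,
) -> LocalPrediction:
    """Predict ``response`` for a query via a local neighbor regression.

    Properties are added by forward stepwise selection (largest reduction in
    residual sum of squares) into an OLS fit over the k neighbors, stopping
    at floor(k/m) parameters or when the relative RSS reduction drops below
    ``config.rss_tol``. The intercept is always included and not counted.
    """
    neighbors = select_neighbors(kb, query, config, query_id=query_id)
    idx = {cid: j for j, cid in enumerate(kb.ids)}
    rows = [idx[cid] for cid, _ in neighbors]
    scaled_q, _ = kb.prepare_query(query)

    y_all = kb.response_vector(response)
    y = y_all[rows]
    X = kb.scaled[rows]  # regression in autoscaled property space
    k = len(rows)
    flags: list[str] = []

    if np.allclose(y, y[0]):
        pred = float(y[0])
        return _finish(pred, response, neighbors, [], 0.0, flags)

    usable = [
        j
        for j in range(X.shape[1])
        if not np.allclose(X[:, j], X[0, j])
    ]
    if not usable:
        flags.append("all_properties_constant_among_neighbors")
        return _finish(float(y.mean()), response, neighbors, [], float(y.std()), flags)

    chosen: list[int] = []
    resid = y - y.mean()
    rss = float(resid @ resid)
    p_max = config.max_parameters
    while len(chosen) < p_max and usable:
        best_j, best_rss, best_fit = None, rss, None
        for j in usable:
            cols = chosen + [j]
            D = np.column_stack([np.ones(k), X[:, cols]])
            beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
            if rank < D.shape[1]:
                continue  # singular with this property; skip it
            r = y - D @ beta
            cand = float(r @ r)
            if cand < best_rss:
                best_j, best_rss, best_fit = j, cand, beta
        if best_j is None or (rss - best_rss) < config.rss_tol * max(rss, 1e-300):
            break
        chosen.append(best_j)
        usable.remove(best_j)
        rss = best_rss

    if not chosen:
        pred = float(y.mean())
        local_rmse = float(np.sqrt(rss / k))
        return _finish(pred, response, neighbors, [], local_rmse, flags)

    D = np.column_stack([np.ones(k), X[:, chosen]])
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    pred = float(beta[0] + scaled_q[chosen] @ beta[1:])
    local_rmse = float(np.sqrt(rss / k))
    params = [kb.property_names[j] for j in chosen]
    return _finish(pred, response, neighbors, params, local_rmse, flags)


def _finish(pred, response, neighbors, params, local_rmse, flags) -> LocalPrediction:
    if response in _MINUTE_RESPONSES:
        pred *= 60.0  # minutes -> seconds at the boundary
        local_rmse *= 60.0
    return LocalPrediction(
        predicted=pred,
        neighbor_ids=[cid for cid, _ in neighbors],
        similarities=[s for _, s in neighbors],
        parameters=params,
        local_rmse=local_rmse,
        flags=flags,
    )


def leave_one_out(
    kb: KnowledgeBase,
    response: str,
    config: FederationConfig,
    properties: pd.DataFrame,
) -> pd.DataFrame:
    """Leave-one-out federated predictions for every knowledge-base entry."""
    props = properties.copy()
    props.index = props.index.map(str)
    preds = []
    for cid in kb.ids:
        q = props.loc[cid, kb.property_names]
        lp = predict_federated(kb, q, response, config, query_id=cid)
        preds.append({"compound_id": cid, "predicted": lp.predicted})
    out = pd.DataFrame(preds).set_index("compound_id")
    out["observed"] = kb.responses[response].to_numpy(dtype=float)
    return out
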