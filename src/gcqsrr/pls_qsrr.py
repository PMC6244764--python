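"""NIPALS partial-least-squares QSRR engine.

PLS1 regression of a retention response (¹tR, LRI, ²tR or PEG-²I) on an
autoscaled descriptor matrix, with

* cross-validated component selection (seven contiguous CV groups after a
  seeded shuffle; components are added while the gain in Q² = 1 − PRESS/SS
  exceeds a threshold),
* variable importance on projection (VIP; squares average to one),
* jackknife 95% coefficient half-widths from the leave-one-CV-group-out
  submodels,
* the descriptor-pruning ladder (drop high-uncertainty descriptors, drop
  low-importance descriptors, or stepwise removal ten at a time until every
  survivor is important and certain),
* local models per compound group (fluorinated; chlorinated/brominated;
  long carbon chain; remainder) with fallback to the global model for small
  groups and unlabeled queries.

Everything here operates on raw-unit inputs; scaling parameters are stored
in the model and predictions are returned in original response units.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "PLSModel",
    "GroupModelSet",
    "fit_pls",
    "select_components",
    "vip",
    "coefficient_uncertainty",
    "prune_descriptors",
    "fit_group_models",
    "save_model",
    "load_model",
    "GROUP_NAMES",
]

#: compound-group labels used for local models
GROUP_NAMES = {
    1: "fluorinated",
    2: "chlorinated_brominated",
    3: "long_carbon_chain",
    4: "remainder",
}


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


@dataclass
class PLSModel:
    """A fitted PLS1 model with its diagnostics.

    ``coef_`` and ``intercept_`` act on raw (unscaled) descriptors and return
    the response in original units. ``W``, ``P``, ``q`` and ``T`` are the
    NIPALS weights, X-loadings, y-loadings and training scores in autoscaled
    space.
    """

    descriptor_names: list[str]
    response_name: str
    scope: str
    n_components: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    coef_: np.ndarray
    intercept_: float
    vip_: np.ndarray
    coef_halfwidth_: np.ndarray | None = None
    cv_record: pd.DataFrame | None = None

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.reindex(columns=self.descriptor_names)
            if X.isna().any().any():
                missing = X.columns[X.isna().any()].tolist()
                raise ValueError(f"missing descriptors at prediction time: {missing}")
        Xm, _ = _as_matrix(X)
        return Xm @ self.coef_ + self.intercept_

    @property
    def scaled_coef(self) -> np.ndarray:
        """Regression vector in autoscaled (X, y) space."""
        return self.coef_ * self.x_sd / self.y_sd


def _nipals(
    Z: np.ndarray, u: np.ndarray, A: int, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """PLS1 NIPALS with deflation on centered/scaled arrays.

    Returns (W, P, q, T); may stop early if X or y is exhausted.
    """
    n, k = Z.shape
    W = np.zeros((k, A))
    P = np.zeros((k, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    Xa = Z.copy()
    ya = u.copy()
    a_done = 0
    for a in range(A):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w /= nw
        t = Xa @ w
        tt = t @ t
        if tt < tol:
            break
        p = Xa.T @ t / tt
        qa = (ya @ t) / tt
        Xa -= np.outer(t, p)
        ya = ya - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
        a_done += 1
    return W[:, :a_done], P[:, :a_done], q[:a_done], T[:, :a_done]


def fit_pls(
    X,
    y,
    n_components: int,
    response_name: str = "y",
    scope: str = "global",
) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables.

    X and y are raw-unit inputs; autoscaling (sample SD) happens internally
    and the returned coefficients act on raw descriptors. A component count
    exceeding the matrix rank is truncated with a warning.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] != yv.size:
        raise ValueError("X and y have different numbers of rows")
    y_sd = yv.std(ddof=1) if yv.size > 1 else 0.0
    if y_sd == 0:
        raise ValueError("response has zero variance")

    x_mean = Xm.mean(axis=0)
    x_sd = Xm.std(axis=0, ddof=1)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)  # constant columns contribute nothing
    y_mean = float(yv.mean())
    Z = (Xm - x_mean) / x_sd
    u = (yv - y_mean) / y_sd

    rank = np.linalg.matrix_rank(Z)
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncated",
            stacklevel=2,
        )
        n_components = max(rank, 1)

    W, P, q, T = _nipals(Z, u, n_components)
    A = W.shape[1]
    if A == 0:
        raise ValueError("NIPALS extracted no components (X has no variance)")

    # regression vector in scaled space: B = W (P'W)^-1 q
    b_scaled = W @ np.linalg.solve(P.T @ W, q)
    coef = b_scaled * y_sd / x_sd
    intercept = y_mean - float(coef @ x_mean)

    model = PLSModel(
        descriptor_names=names,
        response_name=response_name,
        scope=scope,
        n_components=A,
        W=W,
        P=P,
        q=q,
        T=T,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        coef_=coef,
        intercept_=intercept,
        vip_=np.empty(0),
    )
    model.vip_ = vip(model)
    return model


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance on projection.

    VIP_j = sqrt( K · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ) with SS_a the
    response variance explained by component a; mean of VIP² is 1.
    """
    K = len(model.descriptor_names)
    ss = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)  # q_a^2 * t_a't_a
    total = ss.sum()
    if total == 0:
        return np.ones(K)
    wnorm2 = model.W**2 / np.maximum((model.W**2).sum(axis=0), 1e-300)
    return np.sqrt(K * (wnorm2 @ ss) / total)


def _cv_folds(n: int, n_groups: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded shuffle of the row order."""
    if n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [fold for fold in np.array_split(order, n_groups) if fold.size]


def select_components(
    X,
    y,
    n_groups: int = 7,
    seed: int = 0,
    threshold: float = 0.05,
    max_components: int | None = None,
    response_name: str = "y",
) -> tuple[int, pd.DataFrame]:
    """Choose the component count by seven-group cross-validation.

    Components are added while the *relative* PRESS reduction
    1 − PRESS_{A+1}/PRESS_A exceeds ``threshold`` (equivalently, the Q²
    increment exceeds ``threshold`` × the unexplained variance) and Q²
    stays positive. Judging the increment against the remaining rather
    than the total variance keeps the rule meaningful for strongly
    predictive responses, where Q² is close to 1 from the first component.
    Returns (A, per-A CV record).
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.size
    folds = _cv_folds(n, n_groups, seed)
    if max_components is None:
        max_components = int(min(15, Xm.shape[1], n - max(len(f) for f in folds) - 1))
    max_components = max(max_components, 1)

    ss_tot = ((yv - yv.mean()) ** 2).sum()
    press = np.zeros(max_components)
    achieved = max_components
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, ytr = Xm[mask], yv[mask]
        x_mean, x_sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        x_sd = np.where(x_sd > 0, x_sd, 1.0)
        y_mean = ytr.mean()
        y_sd = ytr.std(ddof=1)
        if y_sd == 0:
            raise ValueError("response constant within a CV training fold")
        W, P, q, T = _nipals((Xtr - x_mean) / x_sd, (ytr - y_mean) / y_sd, max_components)
        achieved = min(achieved, W.shape[1])
        Zv = (Xm[fold] - x_mean) / x_sd
        # cumulative predictions per component count
        last_sse = ((yv[fold] - y_mean) ** 2).sum()
        for a in range(W.shape[1]):
            Wa, Pa = W[:, : a + 1], P[:, : a + 1]
            b = Wa @ np.linalg.solve(Pa.T @ Wa, q[: a + 1])
            pred = (Zv @ b) * y_sd + y_mean
            last_sse = ((yv[fold] - pred) ** 2).sum()
            press[a] += last_sse
        for a in range(W.shape[1], max_components):
            press[a] += last_sse  # fold exhausted: carry the last achievable fit

    max_components = achieved
    press = press[:max_components]
    q2 = 1.0 - press / ss_tot
    record = pd.DataFrame(
        {
            "n_components": np.arange(1, max_components + 1),
            "q2": q2,
            "rmse_cv": np.sqrt(press / max(n - 1, 1)),
        }
    )
    A = 1
    while (
        A < max_components
        and press[A - 1] > 0
        and (1.0 - press[A] / press[A - 1]) > threshold
        and q2[A] > 0
    ):
        A += 1
    return A, record


def coefficient_uncertainty(
    X, y, n_components: int, n_groups: int = 7, seed: int = 0
) -> np.ndarray:
    """Jackknife 95% half-widths of the raw-space regression coefficients.

    One submodel per leave-one-CV-group-out split; half-width =
    t_{0.975, g−1} · sqrt((g−1)/g · Σ_i (b_i − b̄)²).
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    folds = _cv_folds(yv.size, n_groups, seed)
    g = len(folds)
    coefs = []
    for fold in folds:
        mask = np.ones(yv.size, dtype=bool)
        mask[fold] = False
        m = fit_pls(Xm[mask], yv[mask], n_components)
        coefs.append(m.coef_)
    B = np.asarray(coefs)
    var = (g - 1) / g * ((B - B.mean(axis=0)) ** 2).sum(axis=0)
    return stats.t.ppf(0.975, g - 1) * np.sqrt(var)


def _fit_with_diagnostics(
    X: pd.DataFrame, y, n_groups: int, seed: int, response_name: str, scope: str
) -> PLSModel:
    A, record = select_components(X, y, n_groups=n_groups, seed=seed)
    model = fit_pls(X, y, A, response_name=response_name, scope=scope)
    model.cv_record = record
    model.coef_halfwidth_ = coefficient_uncertainty(
        X, y, model.n_components, n_groups=n_groups, seed=seed
    )
    return model


@dataclass
class PruneResult:
    kept: list[str]
    model: PLSModel
    history: list[dict] = field(default_factory=list)


def prune_descriptors(
    X: pd.DataFrame,
    y,
    strategy: str,
    n_groups: int = 7,
    seed: int = 0,
    batch: int = 10,
    max_rounds: int = 50,
    response_name: str = "y",
) -> PruneResult:
    """Descriptor pruning ladder.

    ``uncertainty``: drop descriptors whose jackknife half-width exceeds the
    magnitude of their coefficient. ``importance``: drop descriptors with
    VIP < 1. ``stepwise``: repeatedly drop, ``batch`` at a time, the worst
    descriptors that are *both* of low importance (VIP < 1) and uncertain
    (half-width > |coefficient|), ranked by VIP ascending then
    half-width/|coefficient| descending, until no descriptor shows both
    defects. The component count is re-selected after every refit.

    Requiring both defects for stepwise removal keeps genuinely
    contributing descriptors whose VIP merely falls below 1 because VIP²
    averages to one over the retained set.
    """
    if strategy not in {"uncertainty", "importance", "stepwise"}:
        raise ValueError(f"unknown pruning strategy {strategy!r}")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in X.columns]

    cur = X
    model = _fit_with_diagnostics(cur, y, n_groups, seed, response_name, "global")
    history: list[dict] = []

    for round_no in range(max_rounds):
        hw = model.coef_halfwidth_
        ratio = hw / np.maximum(np.abs(model.coef_), 1e-300)
        uncertain = ratio > 1.0
        unimportant = model.vip_ < 1.0

        if strategy == "uncertainty":
            drop_mask = uncertain
        elif strategy == "importance":
            drop_mask = unimportant
        else:
            drop_mask = uncertain & unimportant
        offenders = [n for n, d in zip(cur.columns, drop_mask) if d]
        if not offenders:
            break

        if strategy == "stepwise":
            order = np.lexsort((-ratio, model.vip_))  # VIP asc, ratio desc
            ranked = [cur.columns[j] for j in order if drop_mask[j]]
            to_drop = ranked[:batch]
        else:
            to_drop = offenders

        survivors = [c for c in cur.columns if c not in set(to_drop)]
        if not survivors:
            warnings.warn(
                "pruning would remove every descriptor; returning last model",
                stacklevel=2,
            )
            break
        history.append({"round": round_no, "dropped": to_drop})
        cur = cur[survivors]
        model = _fit_with_diagnostics(cur, y, n_groups, seed, response_name, "global")
        if strategy in {"uncertainty", "importance"}:
            break  # single-shot strategies

    return PruneResult(kept=list(cur.columns), model=model, history=history)


@dataclass
class GroupModelSet:
    """Global model plus local models for the compound groups."""

    global_model: PLSModel
    local_models: dict[int, PLSModel]
    fallback_groups: list[int]
    response_name: str

    def predict(self, X: pd.DataFrame, groups: dict | None = None) -> pd.DataFrame:
        """Dispatch each compound to its group model (global as fallback)."""
        groups = groups or {}
        preds = np.empty(len(X))
        used = []
        for i, cid in enumerate(X.index):
            g = groups.get(cid)
            model = self.local_models.get(g, self.global_model)
            if g is None:
                log.debug("compound %s unlabeled; global model used", cid)
            preds[i] = model.predict(X.iloc[[i]])[0]
            used.append("global" if model is self.global_model else f"group_{g}")
        return pd.DataFrame(
            {"predicted": preds, "model": used}, index=X.index
        )


def fit_group_models(
    X: pd.DataFrame,
    y: pd.Series,
    groups: dict,
    response_name: str = "y",
    n_groups_cv: int = 7,
    seed: int = 0,
    min_size: int | None = None,
) -> GroupModelSet:
    """Fit the global model and one local model per compound group.

    Groups with fewer than ``min_size`` training members (default
    max(10, 2·n_cv_groups)) fall back to the global model and are flagged.
    """
    if min_size is None:
        min_size = max(10, 2 * n_groups_cv)
    glob = _fit_with_diagnostics(X, y, n_groups_cv, seed, response_name, "global")
    local: dict[int, PLSModel] = {}
    fallback: list[int] = []
    labels = sorted({g for g in groups.values() if g is not None})
    for g in labels:
        members = [cid for cid in X.index if groups.get(cid) == g]
        if len(members) < min_size:
            fallback.append(g)
            log.warning(
                "group %s has %d training members (<%d); falling back to global model",
                g, len(members), min_size,
            )
            continue
        local[g] = _fit_with_diagnostics(
            X.loc[members], y.loc[members], n_groups_cv, seed, response_name, f"group_{g}"
        )
    return GroupModelSet(
        global_model=glob,
        local_models=local,
        fallback_groups=fallback,
        response_name=response_name,
    )


def save_model(model: PLSModel, path) -> None:
    """Serialize a model (with scaling params and diagnostics) to JSON."""
    payload = {
        "descriptor_names": model.descriptor_names,
        "response_name": model.response_name,
        "scope": model.scope,
        "n_components": model.n_components,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_sd": model.x_sd.tolist(),
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
        "coef": model.coef_.tolist(),
        "intercept": model.intercept_,
        "vip": model.vip_.tolist(),
        "coef_halfwidth": None
        if model.coef_halfwidth_ is None
        else model.coef_halfwidth_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> PLSModel:
    with open(path) as fh:
        d = json.load(fh)
    return PLSModel(
        descriptor_names=d["descriptor_names"],
        response_name=d["response_name"],
        scope=d["scope"],
        n_components=d["n_components"],
        W=np.asarray(d["W"], dtype=float),
        P=np.asarray(d["P"], dtype=float),
        q=np.asarray(d["q"], dtype=float),
        T=np.empty((0, d["n_components"])),
        x_mean=np.asarray(d["x_mean"], dtype=float),
        x_sd=np.asarray(d["x_sd"], dtype=float),
        y_mean=float(d["y_mean"]),
        y_sd=float(d["y_sd"]),
        coef_=np.asarray(d["coef"], dtype=float),
        intercept_=float(d["intercept"]),
        vip_=np.asarray(d["vip"], dtype=float),
        coef_halfwidth_=None
        if d["coef_halfwidth"] is None
        else np.asarray(d["coef_halfwidth"], dtype=float),
    )
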