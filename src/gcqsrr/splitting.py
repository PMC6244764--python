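"""Training / test / external-validation set division.

Compounds are split by sorting PCA scores component by component and
assigning every 5th compound to the training set, every 8th to the test set
and every 9th to the external validation set; the pool shrinks and the
procedure repeats over the first four components, with any leftovers
distributed at random. PCB congeners are handled first: per chlorination
level all but two go straight to the external validation set, so the models
are not over-trained on the (large, homologous) PCB family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SET_NAMES = ("training", "test", "external_validation")

__all__ = ["PCAModel", "SplitAssignment", "run_pca", "systematic_split", "coverage_check"]


@dataclass
class PCAModel:
    """PCA of the (autoscaled) descriptor matrix.

    Scores are stored as a DataFrame indexed by compound id; loadings are a
    descriptors × components array with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).
    """

    loadings: np.ndarray
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series
    scale: pd.Series
    n_components: int

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project new rows onto the fitted components."""
        Z = (X[self.mean.index] - self.mean) / self.scale
        T = Z.to_numpy(dtype=float) @ self.loadings
        return pd.DataFrame(
            T, index=X.index, columns=[f"PC{i + 1}" for i in range(self.n_components)]
        )


def run_pca(X: pd.DataFrame, n_components: int = 5, scale: bool = True) -> PCAModel:
    """Principal components by SVD of the centered (and scaled) matrix.

    Constant columns are left centered but unscaled. If ``n_components``
    exceeds the matrix rank it is reduced with a warning.
    """
    Xv = X.astype(float)
    mean = Xv.mean()
    if scale:
        sd = Xv.std(ddof=1)
        sd = sd.where(sd > 0, 1.0)
    else:
        sd = pd.Series(1.0, index=Xv.columns)
    Z = ((Xv - mean) / sd).to_numpy(dtype=float)

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = s.max() * max(Z.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; reduced", stacklevel=2
        )
        n_components = rank

    loadings = Vt[:n_components].T  # descriptors x components
    # sign convention: largest-magnitude loading per component positive
    for a in range(n_components):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1.0
    T = Z @ loadings
    total_var = (s**2).sum()
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    scores = pd.DataFrame(
        T, index=Xv.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=evr,
        mean=mean,
        scale=sd,
        n_components=n_components,
    )


@dataclass
class SplitAssignment:
    """Compound → set map with per-compound provenance."""

    assignment: dict = field(default_factory=dict)  # id -> set name
    provenance: dict = field(default_factory=dict)  # id -> rule that placed it

    def ids(self, set_name: str) -> list:
        return [i for i, s in self.assignment.items() if s == set_name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": list(self.assignment),
                "set": [self.assignment[i] for i in self.assignment],
                "provenance": [self.provenance.get(i, "") for i in self.assignment],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SplitAssignment":
        bad = set(df["set"]) - set(SET_NAMES)
        if bad:
            raise ValueError(f"unknown set names: {sorted(bad)}")
        prov = df["provenance"] if "provenance" in df.columns else [""] * len(df)
        return cls(
            assignment=dict(zip(df["compound_id"], df["set"])),
            provenance=dict(zip(df["compound_id"], prov)),
        )


def systematic_split(
    compound_ids: list,
    scores: pd.DataFrame,
    seed: int,
    pcb_levels: dict | None = None,
    n_component_passes: int = 4,
) -> SplitAssignment:
    """Systematic PCA-score split with the PCB pre-assignment rule.

    1. Per PCB chlorination level, two congeners (seeded choice) stay in the
       general pool; the rest are assigned to external validation.
    2. For each of the first ``n_component_passes`` components the remaining
       pool is sorted by score (ascending, ties by id) and walked with
       1-based positions: multiples of 5 → training, else multiples of 8 →
       test, else multiples of 9 → external validation. Assigned compounds
       leave the pool before the next pass.
    3. Leftovers are assigned uniformly at random (seeded).
    """
    if len(compound_ids) == 0:
        raise ValueError("no compounds to split")
    rng = np.random.default_rng(seed)
    pcb_levels = pcb_levels or {}
    out = SplitAssignment()

    by_level: dict = {}
    for cid, level in pcb_levels.items():
        if cid not in set(compound_ids):
            continue
        if level is None:
            raise ValueError(f"PCB {cid!r} lacks a chlorination level")
        by_level.setdefault(int(level), []).append(cid)

    pool = list(compound_ids)
    for level in sorted(by_level):
        members = sorted(by_level[level])
        if len(members) <= 2:
            continue
        keep = set(rng.choice(members, size=2, replace=False))
        for cid in members:
            if cid not in keep:
                out.assignment[cid] = "external_validation"
                out.provenance[cid] = "pcb_rule"
    pool = [cid for cid in pool if cid not in out.assignment]

    for c in range(min(n_component_passes, scores.shape[1])):
        col = scores.columns[c]
        order = sorted(pool, key=lambda cid: (scores.at[cid, col], str(cid)))
        assigned = []
        for i, cid in enumerate(order, start=1):
            if i % 5 == 0:
                dest = "training"
            elif i % 8 == 0:
                dest = "test"
            elif i % 9 == 0:
                dest = "external_validation"
            else:
                continue
            out.assignment[cid] = dest
            out.provenance[cid] = f"component_{c + 1}"
            assigned.append(cid)
        pool = [cid for cid in pool if cid not in set(assigned)]

    for cid in pool:
        out.assignment[cid] = SET_NAMES[rng.integers(0, 3)]
        out.provenance[cid] = "random_remainder"
    return out


def coverage_check(
    assignment: SplitAssignment, scores: pd.DataFrame, components: int = 2,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Fraction of the test-set score range covered by the training range.

    Reported for the leading components; coverage below ``threshold`` is
    flagged (the test set then probes descriptor space the training set does
    not span).
    """
    train = assignment.ids("training")
    test = assignment.ids("test")
    if len(train) < 2 or len(test) < 2:
        raise ValueError("coverage check needs >=2 compounds in training and test")
    rows = []
    for c in range(min(components, scores.shape[1])):
        col = scores.columns[c]
        tr = scores.loc[train, col]
        te = scores.loc[test, col]
        span = te.max() - te.min()
        if span == 0:
            cov = 1.0
        else:
            overlap = min(tr.max(), te.max()) - max(tr.min(), te.min())
            cov = float(np.clip(overlap / span, 0.0, 1.0))
        rows.append({"component": col, "coverage": cov, "flagged": cov < threshold})
    report = pd.DataFrame(rows)
    for _, r in report[report["flagged"]].iterrows():
        log.warning("test-set coverage on %s is %.2f (<%.2f)", r["component"], r["coverage"], threshold)
    return report
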