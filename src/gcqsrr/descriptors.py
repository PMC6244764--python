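"""Descriptor-matrix construction for QSRR modelling.

The canonical input is a precomputed table of 2D physico-chemical
descriptors (one row per compound), optionally including the Abraham
solvation parameters E, S, A, B, L and the molecular weight. On top of the
base descriptors this module builds

* weight-normalized variants (descriptor / MW), compensating for the size
  dependence of properties such as lipophilicity;
* linearizing transforms (log, sqrt, reciprocal, square), appended only
  when they improve the Pearson correlation with the response by a margin;
* unit-variance autoscaling with training-set statistics that are reused
  verbatim on held-out and screening compounds.

A convenience path computes a small RDKit 2D descriptor set from structures
when no table is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ABRAHAM_NAMES = ("E", "S", "A", "B", "L")

__all__ = [
    "DescriptorMeta",
    "DescriptorTable",
    "ScalingParams",
    "TRANSFORM_CATALOG",
    "augment_weight_normalized",
    "apply_manual_transformations",
    "autoscale",
    "compute_rdkit_descriptors",
]


@dataclass(frozen=True)
class DescriptorMeta:
    source: str = "base"  # base | weight_normalized | transformed
    transform: str = "none"  # none | log10_shift | sqrt | reciprocal | square
    parent: str | None = None


class DescriptorTable:
    """Compounds × descriptors matrix with per-descriptor provenance.

    ``values`` is a float DataFrame indexed by compound id; ``meta`` maps each
    descriptor name to its :class:`DescriptorMeta`.
    """

    def __init__(self, values: pd.DataFrame, meta: dict[str, DescriptorMeta] | None = None):
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        self.values = values.astype(float)
        self.meta = dict(meta) if meta else {c: DescriptorMeta() for c in values.columns}
        for c in values.columns:
            self.meta.setdefault(c, DescriptorMeta())
        for m in self.meta.values():
            if m.parent is not None and m.parent not in values.columns:
                raise ValueError(f"transform parent {m.parent!r} missing from table")

    @property
    def compound_ids(self) -> list:
        return list(self.values.index)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "DescriptorTable":
        return DescriptorTable(self.values.copy(), dict(self.meta))

    def with_column(self, name: str, col: pd.Series, meta: DescriptorMeta) -> "DescriptorTable":
        if name in self.values.columns:
            raise ValueError(f"descriptor {name!r} already present")
        values = self.values.copy()
        values[name] = col.astype(float)
        new_meta = dict(self.meta)
        new_meta[name] = meta
        return DescriptorTable(values, new_meta)

    def __repr__(self) -> str:  # pragma: no cover
        n, k = self.values.shape
        return f"DescriptorTable({n} compounds x {k} descriptors)"


def augment_weight_normalized(
    table: DescriptorTable,
    which: list[str] | None = None,
    mw_column: str = "MW",
    suffix: str = "_per_MW",
) -> DescriptorTable:
    """Append weight-normalized copies (value / molecular weight).

    ``which`` defaults to every base descriptor except the MW column itself.
    """
    if mw_column not in table.values.columns:
        raise ValueError(
            f"molecular weight column {mw_column!r} required for weight normalization"
        )
    mw = table.values[mw_column]
    if (mw <= 0).any():
        raise ValueError("molecular weight must be strictly positive")
    if which is None:
        which = [
            c
            for c in table.names
            if c != mw_column and table.meta[c].source == "base"
        ]
    out = table
    for name in which:
        if name not in table.values.columns:
            raise ValueError(f"unknown descriptor {name!r}")
        out = out.with_column(
            name + suffix,
            table.values[name] / mw,
            DescriptorMeta(source="weight_normalized", parent=name),
        )
    return out


def _log10_shift(x: np.ndarray) -> np.ndarray:
    return np.log10(x - x.min() + 1.0)


def _sqrt_shift(x: np.ndarray) -> np.ndarray:
    return np.sqrt(x - x.min())


def _reciprocal(x: np.ndarray) -> np.ndarray:
    if (x <= 0).any():
        raise FloatingPointError("reciprocal requires strictly positive values")
    return 1.0 / x


def _square(x: np.ndarray) -> np.ndarray:
    return x**2


#: transform name -> callable; order fixes the (deterministic) evaluation order
TRANSFORM_CATALOG = {
    "log10_shift": _log10_shift,
    "sqrt": _sqrt_shift,
    "reciprocal": _reciprocal,
    "square": _square,
}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def apply_manual_transformations(
    table: DescriptorTable,
    response: pd.Series | np.ndarray,
    catalog: dict | None = None,
    margin: float = 0.05,
    rows: list | None = None,
) -> DescriptorTable:
    """Append linearizing transforms that beat the raw descriptor.

    For each descriptor and each catalog transform, the transformed column is
    appended iff |Pearson r(transform(x), y)| exceeds |r(x, y)| by at least
    ``margin``, judged on the training rows. Originals are always retained;
    transforms that are undefined on the data are skipped with a warning.
    """
    catalog = TRANSFORM_CATALOG if catalog is None else catalog
    y = np.asarray(response, dtype=float)
    fit = table.values.loc[rows] if rows is not None else table.values
    if len(fit) != len(y):
        raise ValueError("response not aligned with (training) rows")
    out = table
    base_names = [c for c in table.names]
    for name in base_names:
        x_fit = fit[name].to_numpy(dtype=float)
        r0 = abs(_pearson(x_fit, y))
        for tname, fn in catalog.items():
            try:
                with np.errstate(all="raise"):
                    xt_fit = fn(x_fit)
            except FloatingPointError:
                log.warning("transform %s undefined for descriptor %s; skipped", tname, name)
                continue
            if not np.all(np.isfinite(xt_fit)):
                log.warning("transform %s non-finite for descriptor %s; skipped", tname, name)
                continue
            if abs(_pearson(xt_fit, y)) - r0 >= margin:
                # transform the full column with the fit-row shift so held-out
                # rows are mapped consistently
                x_all = out.values[name].to_numpy(dtype=float)
                shift = x_fit.min()
                if tname == "log10_shift":
                    x_new = np.log10(np.maximum(x_all - shift + 1.0, 1e-12))
                elif tname == "sqrt":
                    x_new = np.sqrt(np.maximum(x_all - shift, 0.0))
                elif tname == "reciprocal":
                    x_new = 1.0 / x_all
                elif tname == "square":
                    x_new = x_all**2
                else:
                    x_new = fn(x_all)
                out = out.with_column(
                    f"{name}__{tname}",
                    pd.Series(x_new, index=out.values.index),
                    DescriptorMeta(source="transformed", transform=tname, parent=name),
                )
    return out


@dataclass
class ScalingParams:
    """Training-set centering/scaling statistics (sample SD, N−1)."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)
    imputed: dict[str, float] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.mean.index)

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        """Scale new rows with the stored training statistics."""
        X = values.reindex(columns=self.names).astype(float)
        for name, med in self.imputed.items():
            X[name] = X[name].fillna(med)
        return (X - self.mean) / self.sd

    def inverse(self, scaled: pd.DataFrame) -> pd.DataFrame:
        return scaled * self.sd + self.mean


def autoscale(
    table: DescriptorTable,
    fit_rows: list | None = None,
    max_missing_frac: float = 0.05,
) -> tuple[DescriptorTable, ScalingParams]:
    """Center and scale to unit variance using statistics from ``fit_rows``.

    Columns that are constant over the fit rows are dropped (recorded in the
    params); columns with more than ``max_missing_frac`` missing values over
    the fit rows are dropped, the rest median-imputed.
    """
    if fit_rows is None:
        fit_rows = table.compound_ids
    if len(fit_rows) == 0:
        raise ValueError("fit_rows must be nonempty")
    fit = table.values.loc[fit_rows]

    dropped, imputed = [], {}
    keep = []
    for name in table.names:
        col = fit[name]
        miss = col.isna().mean()
        if miss > max_missing_frac:
            dropped.append(name)
            continue
        if miss > 0:
            imputed[name] = float(col.median())
            col = col.fillna(imputed[name])
        if col.std(ddof=1) == 0 or not np.isfinite(col.std(ddof=1)):
            dropped.append(name)
            continue
        keep.append(name)

    fit_filled = fit[keep].copy()
    for name in keep:
        if name in imputed:
            fit_filled[name] = fit_filled[name].fillna(imputed[name])
    mean = fit_filled.mean()
    sd = fit_filled.std(ddof=1)
    params = ScalingParams(mean=mean, sd=sd, dropped=dropped, imputed=imputed)

    scaled_values = params.apply(table.values)
    meta = {c: table.meta[c] for c in keep}
    # parents of transformed columns may have been dropped; detach them
    meta = {
        c: (m if (m.parent is None or m.parent in keep) else DescriptorMeta(m.source, m.transform, None))
        for c, m in meta.items()
    }
    return DescriptorTable(scaled_values, meta), params


def compute_rdkit_descriptors(smiles: dict[str, str]) -> DescriptorTable:
    """Compute a small 2D descriptor set from SMILES with RDKit.

    Convenience path only; QSRR work normally starts from a curated
    descriptor table.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    rows, ids = [], []
    for cid, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            warnings.warn(f"unparseable SMILES for {cid}; skipped")
            continue
        rows.append(
            {
                "MW": Descriptors.MolWt(mol),
                "logP": Crippen.MolLogP(mol),
                "MR": Crippen.MolMR(mol),
                "TPSA": rdMolDescriptors.CalcTPSA(mol),
                "nRotB": rdMolDescriptors.CalcNumRotatableBonds(mol),
                "nHBD": rdMolDescriptors.CalcNumHBD(mol),
                "nHBA": rdMolDescriptors.CalcNumHBA(mol),
                "nAromRings": rdMolDescriptors.CalcNumAromaticRings(mol),
                "nHeavy": mol.GetNumHeavyAtoms(),
                "FractionCSP3": rdMolDescriptors.CalcFractionCSP3(mol),
            }
        )
        ids.append(cid)
    return DescriptorTable(pd.DataFrame(rows, index=ids))
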