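"""Retention-index calculation for GC×GC.

First-dimension linear retention indices (LRI) are computed against a
temperature-programmed n-alkane series: an alkane with n carbons is assigned
index 100·n and analytes are placed by linear interpolation of their
first-dimension retention time between the bracketing alkanes.

Second-dimension indices (PEG-²I) are anchored to a polyethylene-glycol
oligomer series, which forms a straight line in the (¹tR, ²tR) plane on a
non-polar × semi-polar column set. The index is the analyte's vertical
position between the n-alkane baseline (index 0) and the PEG line
(index 100), scaled by 100; values above 100 occur for analytes more
strongly retained in the second dimension than the PEGs.  The exact
three-step construction used with the original PEG index system is not
public; the normalized-vertical-position form implemented here is a
reconstruction that reproduces its anchor behaviour (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InvalidReferenceError",
    "ReferenceSeries",
    "IndexResult",
    "ReferenceLines",
    "compute_lri",
    "fit_reference_lines",
    "compute_peg_2i",
    "read_reference_series",
    "write_reference_series",
]


class InvalidReferenceError(ValueError):
    """Raised when a reference-standard series cannot support indexing."""


@dataclass(frozen=True)
class IndexResult:
    """A single retention-index value.

    ``extrapolated`` is True when the analyte eluted outside the span of the
    fitted reference standards, so the index is a linear extrapolation.
    """

    value: float
    extrapolated: bool
    dimension: str  # "first" or "second"


@dataclass
class ReferenceSeries:
    """n-Alkane and PEG reference standards.

    alkanes:   [(carbon_number, t1_s), ...] strictly increasing in both.
    pegs:      [(eo_units, t1_s, t2_s), ...] strictly increasing in t1.
    alkane_t2: optional [(t1_s, t2_s), ...] non-polar second-dimension
               baseline; when absent a flat baseline at the minimum observed
               PEG t2 is used.
    """

    alkanes: list[tuple[int, float]]
    pegs: list[tuple[int, float, float]] = field(default_factory=list)
    alkane_t2: list[tuple[float, float]] | None = None

    def validate_alkanes(self) -> None:
        if len(self.alkanes) < 2:
            raise InvalidReferenceError(
                "at least 2 alkane standards are required for LRI"
            )
        ns = [c for c, _ in self.alkanes]
        ts = [t for _, t in self.alkanes]
        if any(b <= a for a, b in zip(ns, ns[1:])) or any(
            b <= a for a, b in zip(ts, ts[1:])
        ):
            raise InvalidReferenceError(
                "alkane series must be strictly increasing in carbon number and t1"
            )

    def validate_pegs(self) -> None:
        if len(self.pegs) < 2:
            raise InvalidReferenceError("at least 2 PEG standards are required")
        ts = [t1 for _, t1, _ in self.pegs]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidReferenceError("PEG series must be strictly increasing in t1")


def compute_lri(t1: float, series: ReferenceSeries) -> IndexResult:
    """Linear retention index of an analyte with first-dimension time ``t1``.

    Piecewise linear between consecutive alkanes (C_n maps to exactly 100·n);
    linearly extrapolated, with ``extrapolated=True``, outside the alkane span.
    """
    series.validate_alkanes()
    if not t1 > 0:
        raise ValueError(f"t1 must be positive, got {t1}")
    ns = np.array([c for c, _ in series.alkanes], dtype=float)
    ts = np.array([t for _, t in series.alkanes], dtype=float)
    extrapolated = bool(t1 < ts[0] or t1 > ts[-1])
    # bracketing segment; clamp to terminal segments for extrapolation
    j = int(np.searchsorted(ts, t1, side="right")) - 1
    j = min(max(j, 0), len(ts) - 2)
    frac = (t1 - ts[j]) / (ts[j + 1] - ts[j])
    value = 100.0 * ns[j] + 100.0 * (ns[j + 1] - ns[j]) * frac
    return IndexResult(value=float(value), extrapolated=extrapolated, dimension="first")


@dataclass(frozen=True)
class ReferenceLines:
    """OLS reference lines in the (t1, t2) plane for the PEG index."""

    peg_slope: float
    peg_intercept: float
    base_slope: float
    base_intercept: float
    peg_t1_min: float
    peg_t1_max: float
    peg_rms: float
    base_rms: float

    def peg(self, t1: float | np.ndarray) -> float | np.ndarray:
        return self.peg_intercept + self.peg_slope * np.asarray(t1, dtype=float)

    def base(self, t1: float | np.ndarray) -> float | np.ndarray:
        return self.base_intercept + self.base_slope * np.asarray(t1, dtype=float)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(x) == 0:
        raise InvalidReferenceError("degenerate reference line: all t1 identical")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return float(slope), float(intercept), float(np.sqrt(np.mean(resid**2)))


def fit_reference_lines(series: ReferenceSeries) -> ReferenceLines:
    """Fit the PEG line and the non-polar baseline by ordinary least squares.

    When no alkane second-dimension times are available the baseline is flat
    (slope 0) at the minimum observed PEG t2.
    """
    series.validate_pegs()
    pt1 = np.array([t1 for _, t1, _ in series.pegs], dtype=float)
    pt2 = np.array([t2 for _, _, t2 in series.pegs], dtype=float)
    peg_slope, peg_intercept, peg_rms = _ols_line(pt1, pt2)

    if series.alkane_t2:
        if len(series.alkane_t2) < 2:
            raise InvalidReferenceError("baseline needs at least 2 alkane t2 points")
        at1 = np.array([t1 for t1, _ in series.alkane_t2], dtype=float)
        at2 = np.array([t2 for _, t2 in series.alkane_t2], dtype=float)
        base_slope, base_intercept, base_rms = _ols_line(at1, at2)
    else:
        base_slope, base_intercept, base_rms = 0.0, float(pt2.min()), 0.0

    return ReferenceLines(
        peg_slope=peg_slope,
        peg_intercept=peg_intercept,
        base_slope=base_slope,
        base_intercept=base_intercept,
        peg_t1_min=float(pt1.min()),
        peg_t1_max=float(pt1.max()),
        peg_rms=peg_rms,
        base_rms=base_rms,
    )


def compute_peg_2i(t1: float, t2: float, lines: ReferenceLines) -> IndexResult:
    """PEG-based second-dimension index of an analyte at (t1, t2).

    PEG-²I = 100 · (t2 − base(t1)) / (peg(t1) − base(t1)); the alkane
    baseline maps to 0 and the PEG line to 100 by construction. Values above
    100 are legitimate (strongly retained polar analytes). ``extrapolated``
    is set when t1 lies outside the PEG series span.
    """
    base = float(lines.base(t1))
    peg = float(lines.peg(t1))
    if peg <= base:
        raise InvalidReferenceError(
            f"degenerate geometry at t1={t1}: PEG line ({peg:.4g}) does not lie "
            f"above the baseline ({base:.4g})"
        )
    value = 100.0 * (t2 - base) / (peg - base)
    extrapolated = bool(t1 < lines.peg_t1_min or t1 > lines.peg_t1_max)
    return IndexResult(value=float(value), extrapolated=extrapolated, dimension="second")


def read_reference_series(path) -> ReferenceSeries:
    """Read a reference-series table (CSV: series, label, t1_s, t2_s).

    ``series`` is one of {alkane, peg, alkane2d}. Alkane labels like "C10"
    carry the carbon number, PEG labels like "PEG-6" the ethylene-oxide
    unit count.
    """
    df = pd.read_csv(path)
    required = {"series", "label", "t1_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference series file missing columns: {sorted(missing)}")

    def _num(label: str) -> int:
        digits = "".join(ch for ch in str(label) if ch.isdigit())
        if not digits:
            raise ValueError(f"cannot parse series label {label!r}")
        return int(digits)

    alkanes, pegs, alkane_t2 = [], [], []
    for _, row in df.iterrows():
        kind = str(row["series"]).strip().lower()
        if kind == "alkane":
            alkanes.append((_num(row["label"]), float(row["t1_s"])))
        elif kind == "peg":
            pegs.append((_num(row["label"]), float(row["t1_s"]), float(row["t2_s"])))
        elif kind == "alkane2d":
            alkane_t2.append((float(row["t1_s"]), float(row["t2_s"])))
        else:
            raise ValueError(f"unknown reference series kind {kind!r}")
    alkanes.sort()
    pegs.sort(key=lambda p: p[1])
    alkane_t2.sort()
    return ReferenceSeries(
        alkanes=alkanes, pegs=pegs, alkane_t2=alkane_t2 or None
    )


def write_reference_series(series: ReferenceSeries, path) -> None:
    rows = [
        {"series": "alkane", "label": f"C{c}", "t1_s": t1, "t2_s": ""}
        for c, t1 in series.alkanes
    ]
    rows += [
        {"series": "peg", "label": f"PEG-{k}", "t1_s": t1, "t2_s": t2}
        for k, t1, t2 in series.pegs
    ]
    if series.alkane_t2:
        rows += [
            {"series": "alkane2d", "label": "", "t1_s": t1, "t2_s": t2}
            for t1, t2 in series.alkane_t2
        ]
    pd.DataFrame(rows).to_csv(path, index=False)
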