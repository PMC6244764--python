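"""Retention-index calculations: LRI interpolation and the PEG-line index."""

import numpy as np
import pytest

from gcqsrr import indexing as ix
from gcqsrr import synthetic_data as sd

TWO_ALKANES = ix.ReferenceSeries(alkanes=[(10, 1200.0), (11, 1500.0)])


@pytest.mark.parametrize(
    "t1, expected, extrapolated",
    [
        (1200.0, 1000.0, False),  # co-elution with C10
        (1350.0, 1050.0, False),  # midpoint interpolation
        (1650.0, 1150.0, True),  # linear extrapolation beyond C11
    ],
)
def test_lri_interpolation(t1, expected, extrapolated):
    res = ix.compute_lri(t1, TWO_ALKANES)
    assert res.value == pytest.approx(expected)
    assert res.extrapolated is extrapolated
    assert res.dimension == "first"


def test_lri_alkane_anchors_exact():
    series = ix.ReferenceSeries(
        alkanes=[(n, 100.0 + 37.5 * n**1.02) for n in range(8, 31)]
    )
    for n, t1 in series.alkanes:
        assert ix.compute_lri(t1, series).value == pytest.approx(100.0 * n, abs=1e-9)


def test_lri_strictly_increasing_in_t1():
    series = ix.ReferenceSeries(alkanes=[(8, 400.0), (10, 700.0), (12, 1100.0)])
    t1s = np.linspace(300.0, 1300.0, 101)
    vals = [ix.compute_lri(t, series).value for t in t1s]
    assert np.all(np.diff(vals) > 0)


@pytest.mark.parametrize(
    "alkanes",
    [
        [(10, 1200.0)],  # too few
        [(10, 1200.0), (11, 1100.0)],  # t1 not increasing
        [(11, 1200.0), (10, 1500.0)],  # carbons not increasing
    ],
)
def test_lri_invalid_reference(alkanes):
    with pytest.raises(ix.InvalidReferenceError):
        ix.compute_lri(1000.0, ix.ReferenceSeries(alkanes=alkanes))


def test_fit_reference_lines_two_point_peg():
    series = ix.ReferenceSeries(
        alkanes=[(10, 1000.0), (20, 2000.0)],
        pegs=[(4, 1000.0, 3.0), (8, 2000.0, 4.0)],
        alkane_t2=[(1000.0, 1.0), (2000.0, 1.0)],
    )
    lines = ix.fit_reference_lines(series)
    assert lines.peg_slope == pytest.approx(0.001)
    assert lines.peg_intercept == pytest.approx(2.0)
    assert lines.base_slope == pytest.approx(0.0)
    assert lines.base_intercept == pytest.approx(1.0)
    assert lines.peg_rms == pytest.approx(0.0, abs=1e-12)


def test_fit_reference_lines_flat_baseline_default():
    series = ix.ReferenceSeries(
        alkanes=[(10, 1000.0), (20, 2000.0)],
        pegs=[(4, 1000.0, 3.0), (8, 2000.0, 4.0)],
    )
    lines = ix.fit_reference_lines(series)
    assert lines.base_slope == 0.0
    assert lines.base_intercept == pytest.approx(3.0)  # min observed PEG t2


def test_fit_reference_lines_underdetermined():
    series = ix.ReferenceSeries(
        alkanes=[(10, 1000.0), (20, 2000.0)], pegs=[(4, 1000.0, 3.0)]
    )
    with pytest.raises(ix.InvalidReferenceError):
        ix.fit_reference_lines(series)


@pytest.fixture
def lines():
    series = ix.ReferenceSeries(
        alkanes=[(10, 1000.0), (20, 2000.0)],
        pegs=[(4, 1000.0, 3.0), (8, 2000.0, 4.0)],
        alkane_t2=[(1000.0, 1.0), (2000.0, 1.2)],
    )
    return ix.fit_reference_lines(series)


def test_peg2i_anchors(lines):
    t1 = 1500.0
    base, peg = float(lines.base(t1)), float(lines.peg(t1))
    assert ix.compute_peg_2i(t1, base, lines).value == pytest.approx(0.0, abs=1e-12)
    assert ix.compute_peg_2i(t1, peg, lines).value == pytest.approx(100.0)
    mid = (base + peg) / 2
    assert ix.compute_peg_2i(t1, mid, lines).value == pytest.approx(50.0)


def test_peg2i_extrapolation_flag(lines):
    res = ix.compute_peg_2i(2500.0, 3.0, lines)
    assert res.extrapolated is True
    res_in = ix.compute_peg_2i(1500.0, 3.0, lines)
    assert res_in.extrapolated is False


def test_peg2i_monotone_in_t2(lines):
    vals = [ix.compute_peg_2i(1500.0, t2, lines).value for t2 in (1.5, 2.5, 4.0, 6.0)]
    assert np.all(np.diff(vals) > 0)


def test_peg2i_degenerate_geometry():
    series = ix.ReferenceSeries(
        alkanes=[(10, 1000.0), (20, 2000.0)],
        pegs=[(4, 1000.0, 1.0), (8, 2000.0, 1.5)],
        alkane_t2=[(1000.0, 3.0), (2000.0, 3.0)],  # baseline above PEG line
    )
    lines = ix.fit_reference_lines(series)
    with pytest.raises(ix.InvalidReferenceError):
        ix.compute_peg_2i(1500.0, 2.0, lines)


def test_peg2i_invariant_under_affine_t2_rescale(lines):
    """Index portability: a shared affine change of the ²t axis cancels."""
    series = ix.ReferenceSeries(
        alkanes=[(10, 1000.0), (20, 2000.0)],
        pegs=[(4, 1000.0, 3.0), (8, 2000.0, 4.0)],
        alkane_t2=[(1000.0, 1.0), (2000.0, 1.2)],
    )
    a, b = 1.7, 0.4  # arbitrary affine map of the second-dimension axis
    rescaled = ix.ReferenceSeries(
        alkanes=series.alkanes,
        pegs=[(k, t1, a * t2 + b) for k, t1, t2 in series.pegs],
        alkane_t2=[(t1, a * t2 + b) for t1, t2 in series.alkane_t2],
    )
    lines2 = ix.fit_reference_lines(rescaled)
    for t1, t2 in [(1200.0, 2.2), (1800.0, 3.9), (1000.0, 5.0)]:
        v1 = ix.compute_peg_2i(t1, t2, lines).value
        v2 = ix.compute_peg_2i(t1, a * t2 + b, lines2).value
        assert v2 == pytest.approx(v1, abs=1e-9)


def test_round_trip_through_synthetic_model(small_dataset):
    """Re-indexing a generated analyte recovers its true index exactly."""
    cfg, _, _, series, truth = small_dataset
    lines = ix.fit_reference_lines(series)
    for t in truth[::17]:
        res = ix.compute_peg_2i(t.t1_true, t.t2_true, lines)
        assert res.value == pytest.approx(t.peg2i_true, abs=1e-9)


def test_reference_series_round_trip(tmp_path, small_dataset):
    _, _, _, series, _ = small_dataset
    p = tmp_path / "refs.csv"
    ix.write_reference_series(series, p)
    back = ix.read_reference_series(p)
    assert back.alkanes == [(c, pytest.approx(t)) for c, t in series.alkanes]
    assert len(back.pegs) == len(series.pegs)
    assert back.pegs[0][0] == series.pegs[0][0]


# ---------------------------------------------------------------------------
# property-based invariants

from hypothesis import given, settings, strategies as st


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    t1s=st.lists(st.floats(100.0, 4000.0), min_size=2, max_size=8, unique=True),
    query=st.floats(50.0, 4500.0),
)
def test_lri_monotone_for_arbitrary_series(t1s, query):
    """For any valid alkane series, LRI is strictly increasing in t1."""
    times = sorted(t1s)
    series = ix.ReferenceSeries(alkanes=[(8 + i, t) for i, t in enumerate(times)])
    v1 = ix.compute_lri(query, series).value
    v2 = ix.compute_lri(query + 1.0, series).value
    assert v2 > v1


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    t2=st.floats(0.0, 10.0),
    scale=st.floats(0.1, 5.0),
    shift=st.floats(-1.0, 1.0),
)
def test_peg2i_affine_portability(t2, scale, shift):
    series = ix.ReferenceSeries(
        alkanes=[(10, 1000.0), (20, 2000.0)],
        pegs=[(4, 1000.0, 3.0), (8, 2000.0, 4.0)],
        alkane_t2=[(1000.0, 1.0), (2000.0, 1.2)],
    )
    lines = ix.fit_reference_lines(series)
    rescaled = ix.ReferenceSeries(
        alkanes=series.alkanes,
        pegs=[(k, a, scale * b + shift) for k, a, b in series.pegs],
        alkane_t2=[(a, scale * b + shift) for a, b in series.alkane_t2],
    )
    lines2 = ix.fit_reference_lines(rescaled)
    v1 = ix.compute_peg_2i(1400.0, t2, lines).value
    v2 = ix.compute_peg_2i(1400.0, scale * t2 + shift, lines2).value
    assert v2 == pytest.approx(v1, abs=1e-7)
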