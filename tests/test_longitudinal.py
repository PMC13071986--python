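import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonemorph import (
    MorphometryRecord,
    endpoint_differences,
    experimental_spread,
    relative_change,
    relative_difference,
)
from bonemorph.morphometry import WHOLE_SAMPLE


def _rec(day, tv=51.10, tb=3.05, mu_tb=0.873, region=WHOLE_SAMPLE):
    return MorphometryRecord(
        sample_id="gerbil", day=day, region=region, TV=tv, BV=tv * 0.5,
        Ct_BV=tv * 0.45, Tb_BV=tb, BV_TV=50.0, mu_B=1.162, mu_Ct=1.196,
        mu_Tb=mu_tb,
    )


@pytest.mark.parametrize(
    "first, last, expected",
    [
        (51.10, 50.75, -0.68),  # whole-sample TV under ethanol
        (20.42, 20.24, -0.88),  # proximal EM-zone TV under ethanol
        (1.288, 1.220, -5.28),  # diaphyseal mu.Ct from printed (rounded) values
    ],
)
def test_relative_difference_reproduces_printed_endpoints(first, last, expected):
    assert round(relative_difference(first, last), 2) == expected


def test_curve_baseline_is_exactly_zero():
    curve = relative_change([_rec(0), _rec(100, tv=52.0)], "TV")
    assert curve.points[0] == (0, 0.0)


def test_zero_or_missing_baseline_is_an_error():
    with pytest.raises(ValueError):
        relative_change([_rec(0, tv=51.1, tb=0.0), _rec(50)], "Tb.BV")
    with pytest.raises(ValueError):
        relative_change([_rec(35), _rec(70)], "TV")


def test_absent_values_propagate_as_absent():
    recs = [_rec(0), _rec(50, tb=None, mu_tb=None), _rec(100)]
    curve = relative_change(recs, "Tb.BV")
    assert curve.points[1][1] is None
    assert curve.points[2][1] == pytest.approx(0.0)


@settings(max_examples=40, derandomize=True)
@given(st.floats(min_value=1e-3, max_value=1e3),
       st.lists(st.floats(min_value=0.1, max_value=10.0), min_size=1, max_size=6))
def test_scale_invariance_of_relative_change(scale, factors):
    base = 7.3
    days = list(range(0, 10 * (len(factors) + 1), 10))
    values = [base] + [base * f for f in factors]
    recs = [_rec(d, tv=v) for d, v in zip(days, values)]
    scaled = [_rec(d, tv=v * scale) for d, v in zip(days, values)]
    c1 = relative_change(recs, "TV")
    c2 = relative_change(scaled, "TV")
    np.testing.assert_allclose([p for _, p in c1.points],
                               [p for _, p in c2.points], rtol=1e-9, atol=1e-9)


def test_sign_coherence_of_endpoints():
    up = endpoint_differences([_rec(0, tv=10.0), _rec(99, tv=10.5)],
                              parameters=["TV"])
    down = endpoint_differences([_rec(0, tv=10.0), _rec(99, tv=9.5)],
                                parameters=["TV"])
    assert up.frame.loc[0, "diff_pct"] > 0
    assert down.frame.loc[0, "diff_pct"] < 0


def test_constant_series_has_zero_differences():
    table = endpoint_differences([_rec(0), _rec(40), _rec(80)])
    diffs = table.frame["diff_pct"].dropna()
    assert np.allclose(diffs, 0.0)


def test_single_time_point_is_an_error():
    with pytest.raises(ValueError):
        endpoint_differences([_rec(0)])


def test_absent_cells_render_as_dash():
    recs = [_rec(0, tb=None, mu_tb=None, region="diaphysis"),
            _rec(90, tb=None, mu_tb=None, region="diaphysis")]
    table = endpoint_differences(recs).formatted()
    tb_row = table[table.parameter == "Tb.BV"].iloc[0]
    assert (tb_row["first"], tb_row["last"], tb_row["diff_pct"]) == ("-", "-", "-")


def test_table_self_consistency_at_printed_precision(rng):
    """Regenerating the difference column from its own printed first/last
    values stays within the input-rounding propagation bound — 0.05
    percentage points for well-conditioned rows (volumes in the tens printed
    to 2 decimals, attenuations near 1 printed to 3)."""
    for _ in range(200):
        volume_like = rng.uniform() < 0.5
        if volume_like:
            first, decimals = rng.uniform(5.0, 60.0), 2
        else:
            first, decimals = rng.uniform(0.8, 1.35), 3
        last = first * (1 + rng.uniform(-0.1, 0.1))
        stored = relative_difference(first, last)
        f_r, l_r = round(first, decimals), round(last, decimals)
        reprinted = relative_difference(f_r, l_r)
        half_ulp = 0.5 * 10.0**-decimals
        bound = 100.0 * half_ulp * (1.0 / f_r + l_r / f_r**2) + 1e-9
        assert abs(reprinted - stored) <= max(0.05, bound)


def test_formatted_table_reproduces_its_own_difference_column():
    """Parsing the printed first/last cells back and recomputing the percent
    difference agrees with the printed difference cell to printed precision."""
    recs = [_rec(0, tv=20.42, tb=2.57, mu_tb=0.860),
            _rec(1565, tv=20.24, tb=2.54, mu_tb=0.858)]
    printed = endpoint_differences(recs).formatted()
    for _, row in printed.iterrows():
        if row["first"] == "-":
            continue
        again = relative_difference(float(row["first"]), float(row["last"]))
        assert abs(again - float(row["diff_pct"])) <= 0.05


def test_experimental_spread_is_max_absolute_excursion():
    recs = [_rec(0), _rec(40, tv=51.30), _rec(80, tv=50.95)]
    curve = relative_change(recs, "TV")
    spread = experimental_spread([curve])
    assert spread == pytest.approx(100 * (51.30 - 51.10) / 51.10)
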