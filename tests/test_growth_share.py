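"""Growth/share statistics, quadrants, traffic lights and the control region."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupboard import (
    GrowthShareModel,
    SeriesMode,
    analyze_panel,
    assign_color,
    assign_mascot,
    classify_quadrant,
    control_region,
    growth,
    moving_sd_series,
    share,
)
from dupboard.synthetic import generate_panel

from conftest import hospital, make_panel


def pearson_by_hand(x, y):
    """Sigma-based Pearson formula, independent of numpy.corrcoef."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y)
    )
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


TWIN_A = [-1] * 11 + [1]
TWIN_B = [2] * 11 + [4]


class TestGrowth:
    @pytest.mark.parametrize("series", [TWIN_A, TWIN_B])
    def test_twin_datasets_give_048(self, series):
        assert round(growth(series), 2) == 0.48

    def test_perfect_linear_trend(self):
        assert growth(range(1, 13)) == pytest.approx(1.0)

    def test_constant_series_convention(self):
        assert growth([2.0] * 12) == 0.0

    def test_matches_sigma_formula_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=12)
            t = list(range(1, 13))
            assert growth(x) == pytest.approx(pearson_by_hand(t, list(x)), abs=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            growth([1.0, 2.0])


class TestShare:
    @pytest.mark.parametrize(
        "series,expected", [(TWIN_A, -0.83), (TWIN_B, 2.17), ([3.5] * 7, 3.5)]
    )
    def test_mean(self, series, expected):
        assert round(share(series), 2) == expected


QUADRANT_EXAMPLES = [
    # published worked examples: dataset, (growth, share) to 2 dp, quadrant
    ([2] * 10 + [3, 4], (0.63, 2.25), "I"),
    ([-1] * 10 + [1, 1], (0.65, -0.67), "II"),
    ([-1] * 10 + [-2, -3], (-0.63, -1.25), "III"),
    ([2] * 10 + [1, -1], (-0.60, 1.67), "IV"),
]


@pytest.mark.parametrize("series,gs,quadrant", QUADRANT_EXAMPLES)
def test_quadrant_worked_examples(series, gs, quadrant):
    g, s = growth(series), share(series)
    assert (round(g, 2), round(s, 2)) == gs
    assert classify_quadrant(g, s) == quadrant


class TestQuadrantMapping:
    @pytest.mark.parametrize(
        "g,s,quadrant",
        [(0.5, 0.5, "I"), (0.5, -0.5, "II"), (-0.5, -0.5, "III"), (-0.5, 0.5, "IV"),
         (0.0, 0.0, "III"), (0.0, 1.0, "IV"), (0.5, 0.0, "II"), (-0.5, 0.0, "III")],
    )
    def test_boundaries_go_to_non_red_side(self, g, s, quadrant):
        assert classify_quadrant(g, s) == quadrant

    def test_colors_and_mascots(self):
        assert assign_color("I") == "red"
        assert assign_color("II") == "yellow"
        assert assign_color("III") == "green"
        assert assign_color("IV") == "green"
        assert assign_mascot("I") == "star"
        assert assign_mascot("II") == "problem_child"
        assert assign_mascot("III") == "dog"
        assert assign_mascot("IV") == "cash_cow"

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=-1, max_value=1, allow_nan=False),
        st.floats(min_value=-10, max_value=10, allow_nan=False),
    )
    def test_assignment_total_and_deterministic(self, g, s):
        q = classify_quadrant(g, s)
        assert q in ("I", "II", "III", "IV")
        assert classify_quadrant(g, s) == q
        assert assign_color(q) in ("red", "yellow", "green")
        assert assign_mascot(q) in ("star", "problem_child", "cash_cow", "dog")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_quadrant(float("nan"), 0.0)


class TestAffineProperties:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=50),
        st.floats(min_value=-100, max_value=100),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_growth_affine_invariant_and_share_equivariant(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=12)
        assert growth(a * x + b) == pytest.approx(growth(x), abs=1e-9)
        assert share(a * x + b) == pytest.approx(a * share(x) + b, rel=1e-9, abs=1e-9)

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=12)
            assert growth(x[::-1]) == pytest.approx(-growth(x), abs=1e-12)


class TestMovingSD:
    def test_24_points_yield_12_sds_over_13_point_windows(self):
        x = np.random.default_rng(9).normal(size=24)
        out = moving_sd_series(x, 12)
        assert out.shape == (12,)
        for i in range(12):
            assert out[i] == pytest.approx(np.std(x[i:i + 13], ddof=1), abs=1e-12)
        assert (out >= 0).all()

    def test_constant_series_gives_zero_sds(self):
        assert moving_sd_series([5.0] * 24, 12) == pytest.approx(np.zeros(12))

    def test_three_points_window_two(self):
        out = moving_sd_series([1.0, 2.0, 3.0], 2)
        # each window is a 2-point unit step: sample SD = 1/sqrt(2)
        assert out == pytest.approx([2**-0.5, 2**-0.5], abs=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            moving_sd_series([1.0, 2.0], 12)


class TestControlRegion:
    def test_identical_points_all_in_control(self):
        _, half, inside = control_region([(0.5, 1.0)] * 4)
        assert half == (0.0, 0.0)
        assert inside.all()

    def test_extreme_outlier_flagged(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(50, 2)).tolist()
        mean = np.mean([p[0] for p in pts])
        sd = np.std([p[0] for p in pts], ddof=1)
        pts.append([mean + 10 * sd, 0.0])
        _, _, inside = control_region(pts)
        assert not inside[-1]

    def test_matches_independent_rectangle_check(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(200, 2))
        center, half, inside = control_region(pts)
        for p, flag in zip(pts, inside):
            expected = (abs(p[0] - center[0]) <= half[0] + 1e-12) and (
                abs(p[1] - center[1]) <= half[1] + 1e-12
            )
            assert flag == expected


class TestAnalyzePanel:
    def test_decreasing_rates_give_negative_growth(self):
        rows = [
            (hospital(1), np.linspace(1.0, 0.2, 25)),
            (hospital(2), np.linspace(0.9, 0.1, 25)),
        ]
        results = analyze_panel(make_panel(rows))
        assert all(r.growth < 0 for r in results)
        assert all(r.quadrant == "IV" for r in results)

    def test_constant_rate_is_quadrant_iv(self):
        rows = [(hospital(1), np.full(25, 0.5)), (hospital(2), np.full(25, 0.4))]
        results = analyze_panel(make_panel(rows))
        assert results[0].growth == 0.0
        assert results[0].quadrant == "IV"  # positive level, zero trend

    def test_raw_mode_uses_last_window(self):
        series = np.concatenate([np.full(13, 9.0), np.arange(1.0, 13.0)])
        rows = [(hospital(1), series), (hospital(2), series)]
        results = analyze_panel(make_panel(rows), SeriesMode("raw", 12))
        assert results[0].growth == pytest.approx(1.0)
        assert results[0].share == pytest.approx(np.mean(np.arange(1.0, 13.0)))

    def test_moving_sd_mode_reduces_last_24_quarters(self):
        rng = np.random.default_rng(12)
        series = rng.normal(2.0, 0.3, size=25)
        rows = [(hospital(1), np.abs(series)), (hospital(2), np.abs(series) + 0.1)]
        results = analyze_panel(make_panel(rows), SeriesMode("moving_sd", 12))
        msd = moving_sd_series(np.abs(series)[-24:], 12)
        assert results[0].growth == pytest.approx(growth(msd))
        assert results[0].share == pytest.approx(share(msd))

    def test_panel_shorter_than_span_rejected(self):
        rows = [(hospital(1), np.full(10, 0.5)), (hospital(2), np.full(10, 0.5))]
        with pytest.raises(ValueError):
            analyze_panel(make_panel(rows), SeriesMode("moving_sd", 12))

    def test_worsening_recovery_rate(self):
        panel, truth = generate_panel(
            n_per_type={"medical_center": 0, "regional": 0, "district": 200},
            profiles={"worsening": 1.0},
            missing_rate={"district": 0.0},
            noise_sd=0.05,
            slope=0.01,
            seed=0,
        )
        results = GrowthShareModel(panel).fit().results
        hits = sum(1 for r in results if r.quadrant == "I")
        assert hits / len(results) >= 0.95

    def test_model_summary_counts(self, tiny_panel):
        res = GrowthShareModel(tiny_panel).fit()
        assert len(res.results) == 3
        assert sum(res.color_counts().values()) == 3
        assert "Quadrants" in res.summary()
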