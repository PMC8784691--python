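"""Axial circular statistics and scalar group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rvbiomech import stats as rvstats
from rvbiomech.exceptions import ValidationError


class TestAxialCircularMean:
    def test_simple_average(self):
        assert rvstats.axial_circular_mean([10.0, 20.0]) == pytest.approx(15.0)

    def test_singleton_identity(self):
        for theta in (-89.0, 0.0, 45.0, 90.0):
            assert rvstats.axial_circular_mean([theta]) == pytest.approx(theta)

    def test_axial_wraparound(self):
        """-80 and +80 deg are 20 deg apart axially; their mean is the axis at 90."""
        m = rvstats.axial_circular_mean([-80.0, 80.0])
        assert abs(m) == pytest.approx(90.0)

    def test_matches_doubled_angle_resultant_oracle(self, rng):
        angles = rng.uniform(-60, 60, size=25)
        doubled = np.deg2rad(2 * angles)
        oracle = 0.5 * np.degrees(
            np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean())
        )
        assert rvstats.axial_circular_mean(angles) == pytest.approx(oracle, abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-89, 89), min_size=2, max_size=12))
    def test_invariant_to_adding_180_to_subset(self, angles):
        a = np.array(angles)
        try:
            base = rvstats.axial_circular_mean(a)
        except ValidationError:
            return  # balanced sample: mean undefined either way
        shifted = a.copy()
        shifted[:: 2] += 180.0
        assert rvstats.axial_circular_mean(shifted) == pytest.approx(base, abs=1e-6)

    def test_balanced_sample_undefined(self):
        with pytest.raises(ValidationError, match="undefined"):
            rvstats.axial_circular_mean([0.0, 90.0])


class TestWatsonWilliams:
    def test_identical_groups_not_significant(self):
        g = np.array([10, 12, 14, 11, 13], dtype=float)
        res = rvstats.watson_williams([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_separated_tight_groups_significant(self, rng):
        kappa = 20.0
        a = np.degrees(rng.vonmises(0.0, kappa, size=20)) / 2.0
        b = np.degrees(rng.vonmises(np.deg2rad(60.0), kappa, size=20)) / 2.0  # 30 deg axial shift
        res = rvstats.watson_williams([a, b])
        assert res.p_value < 0.05

    def test_matches_textbook_formula_on_fixture(self):
        """Independent evaluation of the F formula on a fixed 2x5 sample."""
        g1 = np.array([12.0, 17.0, 21.0, 25.0, 29.0])
        g2 = np.array([35.0, 39.0, 44.0, 48.0, 52.0])
        res = rvstats.watson_williams([g1, g2])

        def resultant(g):
            d = np.deg2rad(2.0 * g)
            return np.hypot(np.cos(d).sum(), np.sin(d).sum())

        R1, R2 = resultant(g1), resultant(g2)
        d_all = np.deg2rad(2.0 * np.concatenate([g1, g2]))
        R = np.hypot(np.cos(d_all).sum(), np.sin(d_all).sum())
        N, J = 10, 2
        rbar = (R1 + R2) / N
        kappa = (-0.4 + 1.39 * rbar + 0.43 / (1 - rbar)) if rbar < 0.85 else 1.0 / (
            rbar**3 - 4 * rbar**2 + 3 * rbar
        )
        F_expected = (1 + 3 / (8 * kappa)) * (
            (N - J) * (R1 + R2 - R) / ((J - 1) * (N - (R1 + R2)))
        )
        assert res.statistic == pytest.approx(F_expected, rel=1e-9)

    def test_invariant_to_common_rotation(self, rng):
        a = rng.uniform(-20, 20, 8)
        b = rng.uniform(10, 50, 8)
        base = rvstats.watson_williams([a, b])
        rot = rvstats.watson_williams([a + 25.0, b + 25.0])
        assert rot.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValidationError):
            rvstats.watson_williams([[10.0], [1.0, 2.0]])


class TestCompareGroups:
    def test_identical_samples_maximal_p(self, rng):
        a = rng.normal(0, 1, 15)
        res = rvstats.compare_groups(a, a)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_shifted_normals_use_t_test(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        res = rvstats.compare_groups(a, b)
        assert res.test == "t-test"
        assert res.p_value < 0.05

    def test_heavy_tailed_samples_use_mann_whitney(self, rng):
        a = rng.lognormal(0, 2.0, 40)
        b = rng.lognormal(0.2, 2.0, 40)
        res = rvstats.compare_groups(a, b)
        assert res.test == "mann-whitney"

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            rvstats.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_path_selection_deterministic(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        first = rvstats.compare_groups(a, b)
        second = rvstats.compare_groups(a, b)
        assert first.test == second.test and first.p_value == second.p_value


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,new,expected",
        [
            (66.2, 159.5, 141),  # myofiber stiffness
            (23.0, 26.8, 17),  # peak pressure
            (0.65, 0.90, 38),  # wall thickness
            (1063.8, 1611.7, 52),  # dP/dt max
        ],
    )
    def test_reported_group_means(self, ref, new, expected):
        assert rvstats.percent_change(ref, new) == expected

    def test_no_change_is_zero(self):
        assert rvstats.percent_change(7.3, 7.3) == 0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            rvstats.percent_change(0.0, 1.0)

    def test_half_rounds_away_from_zero(self):
        assert rvstats.percent_change(100.0, 116.5) == 17
        assert rvstats.percent_change(100.0, 83.5) == -17
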