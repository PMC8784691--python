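"""EFE decomposition: equibiaxial interpolation, stiffness, recruitment."""

import warnings

import numpy as np
import pandas as pd
import pytest

from rvbiomech import fiber_ensemble as fe
from rvbiomech import synthetic as syn
from rvbiomech.exceptions import ValidationError


def polynomial_tables():
    """Protocol-shaped samples of an analytic stress surface."""
    tables = []
    for rc, rl in syn.STANDARD_RATIOS:
        w = np.array([rc, rl], dtype=float) / max(rc, rl)
        t = np.linspace(0, 1, 30)
        E11, E22 = 0.15 * w[0] * t, 0.15 * w[1] * t
        tables.append(
            pd.DataFrame(
                {
                    "E11": E11, "E22": E22,
                    "S11": 50 * E11 + 200 * E11**2 + 30 * E11 * E22,
                    "S22": 40 * E22 + 150 * E22**2 + 30 * E11 * E22,
                }
            )
        )
    return tables


class TestInterpolation:
    def test_matches_analytic_surface_on_diagonal(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eq = fe.interpolate_equibiaxial(polynomial_tables())
        S11_true = 50 * eq.E + 200 * eq.E**2 + 30 * eq.E**2
        S22_true = 40 * eq.E + 150 * eq.E**2 + 30 * eq.E**2
        scale = max(S11_true.max(), 1.0)
        assert np.max(np.abs(eq.S11 - S11_true)) / scale < 5e-3
        assert np.max(np.abs(eq.S22 - S22_true)) / scale < 5e-3

    def test_passes_through_equibiaxial_protocol_data(self, noiseless_tables):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eq = fe.interpolate_equibiaxial(noiseless_tables)
        t11 = noiseless_tables[0]  # the 1:1 protocol
        on_grid = np.interp(t11["E11"], eq.E, eq.S11)
        inside = t11["E11"] < eq.E[-1]
        assert np.allclose(on_grid[inside], t11["S11"][inside], atol=5e-3)

    def test_fewer_than_three_protocols_rejected(self, noiseless_tables):
        with pytest.raises(ValidationError, match="3"):
            fe.interpolate_equibiaxial(noiseless_tables[:2])

    def test_one_sided_protocols_rejected(self, noiseless_tables):
        # 2:1, 4:1, 6:1 all lie on the circumferential side of the diagonal
        one_sided = [noiseless_tables[i] for i in (2, 4, 6)]
        with pytest.raises(ValidationError, match="diagonal"):
            fe.interpolate_equibiaxial(one_sided)


class TestEFECurve:
    def test_stress_sum(self):
        eq = fe.EquibiaxialResponse(
            E=np.linspace(0, 0.1, 11),
            S11=np.full(11, 10.0), S22=np.full(11, 10.0),
        )
        assert np.allclose(fe.efe_curve(eq).S, 20.0)

    def test_linear_curve_constant_stiffness(self):
        E = np.arange(0, 0.15, 0.0025)
        eq = fe.EquibiaxialResponse(E=E, S11=33.1 * E, S22=33.1 * E)
        assert np.allclose(fe.efe_curve(eq).TM, 66.2)

    def test_quadratic_stiffness_within_fd_error(self):
        E = np.arange(0.0, 0.15, 0.0025)
        a = 500.0
        eq = fe.EquibiaxialResponse(E=E, S11=0.5 * a * E**2, S22=0.5 * a * E**2)
        # S_EFE = a*E^2, so TM = 2aE; centered differences are exact on a
        # quadratic, one-sided ends carry O(dE) error
        TM = fe.efe_curve(eq).TM
        assert np.allclose(TM[1:-1], 2 * a * E[1:-1], rtol=1e-9)
        assert np.allclose(TM, 2 * a * E, atol=2 * a * 0.0025)

    def test_scaling_commutes(self, noiseless_tables):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = fe.efe_curve(fe.interpolate_equibiaxial(noiseless_tables))
            scaled_tables = [
                t.assign(S11=3.0 * t["S11"], S22=3.0 * t["S22"])
                for t in noiseless_tables
            ]
            scaled = fe.efe_curve(fe.interpolate_equibiaxial(scaled_tables))
        assert np.allclose(scaled.S, 3.0 * base.S, rtol=1e-8, atol=1e-8)
        assert np.allclose(scaled.TM, 3.0 * base.TM, rtol=1e-6, atol=1e-6)

    def test_efe_at_least_each_channel_when_nonnegative(self, noiseless_tables):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eq = fe.interpolate_equibiaxial(noiseless_tables)
        curve = fe.efe_curve(eq)
        assert np.all(curve.S >= np.maximum(eq.S11, eq.S22) - 1e-9)


class TestRecruitmentDetection:
    def test_piecewise_linear_break_found_within_one_grid_step(self):
        c = syn.gen_efe_curve(slope_pre=60, slope_post=600, recruitment_strain=0.10)
        rec = fe.detect_recruitment(c)
        assert rec is not None
        assert abs(rec.recruitment_strain - 0.10) <= 0.0025 + 1e-12
        assert rec.pre_recruitment_slope == pytest.approx(60.0, rel=1e-6)

    def test_globally_linear_curve_has_no_recruitment(self):
        E = np.arange(0, 0.15, 0.0025)
        curve = fe.EFECurve(E=E, S=66.2 * E, TM=np.gradient(66.2 * E, E))
        assert fe.detect_recruitment(curve) is None

    def test_reported_control_strain_setting_recovered(self):
        c = syn.gen_efe_curve(recruitment_strain=0.104, seed=1)
        rec = fe.detect_recruitment(c)
        assert abs(rec.recruitment_strain - 0.104) <= 0.0025 + 1e-12

    def test_monotone_in_threshold(self):
        c = syn.gen_efe_curve(
            slope_pre=60, slope_post=240, recruitment_strain=0.09,
            tm_noise_sd=2.0, seed=5,
        )
        idx = []
        for z in (2.0, 4.417, 8.0, 20.0):
            rec = fe.detect_recruitment(c, z_threshold=z)
            idx.append(rec.recruitment_index if rec else np.inf)
        assert all(a <= b for a, b in zip(idx, idx[1:]))

    @pytest.mark.parametrize("ratio", [3, 10, 30])
    def test_slope_and_strain_recovery_across_ratios(self, ratio):
        for seed in range(5):
            c = syn.gen_efe_curve(
                slope_pre=60.0, slope_post=60.0 * ratio,
                recruitment_strain=0.104, tm_noise_sd=1.2, seed=seed,
            )
            rec = fe.detect_recruitment(c)
            assert rec is not None
            assert abs(rec.recruitment_strain - 0.104) <= 0.0025 + 1e-12
            assert abs(rec.pre_recruitment_slope - 60.0) / 60.0 < 0.02

    def test_too_few_points_rejected(self):
        E = np.arange(0, 0.01, 0.0025)
        curve = fe.EFECurve(E=E, S=60 * E, TM=np.full_like(E, 60.0))
        with pytest.raises(ValidationError):
            fe.detect_recruitment(curve)


class TestMyofiberStiffness:
    def test_rule_of_mixtures_arithmetic(self):
        rec = fe.RecruitmentResult(0.1, 40, 63.0, 4.417, 40)
        assert fe.myofiber_stiffness(rec, 0.95).TM_myofiber == pytest.approx(66.3, abs=0.05)

    def test_phi_one_is_identity(self):
        rec = fe.RecruitmentResult(0.1, 40, 63.0, 4.417, 40)
        assert fe.myofiber_stiffness(rec, 1.0).TM_myofiber == 63.0

    def test_aging_consistency_fixture(self):
        rec = fe.RecruitmentResult(0.119, 47, 151.5, 4.417, 47)
        assert fe.myofiber_stiffness(rec, 0.95).TM_myofiber == pytest.approx(159.5, abs=0.1)

    def test_invalid_phi_rejected(self):
        rec = fe.RecruitmentResult(0.1, 40, 63.0, 4.417, 40)
        with pytest.raises(ValidationError):
            fe.myofiber_stiffness(rec, 0.0)
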