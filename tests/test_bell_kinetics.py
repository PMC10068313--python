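"""Bell model, fold-change calculus and Bell-Evans fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from forcekin.bell_kinetics import (BODY_TEMPERATURE, BellBond,
                                    BellEvansParams, ForceSensitivityRelation,
                                    TemperatureContext, bell_evans_force,
                                    fit_bell, fit_bell_evans,
                                    fit_xbeta_log_slope,
                                    fold_change_under_force, membrane_off_rate)
from forcekin.exceptions import FitInputError, InvalidParameterError

KBT = TemperatureContext(k_B=4.2797, T=1.0)  # kBT = 4.2797 pN nm exactly


class TestMembraneOffRate:
    def test_zero_force_sensitivity_is_force_independent(self):
        assert membrane_off_rate(BellBond(1.0, 0.0), 50.0) == 1.0

    def test_exponential_amplification(self):
        # 1/s bond, 0.4 nm sensitivity, 15 pN: exp(6/4.2797)
        k = membrane_off_rate(BellBond(1.0, 0.4), 15.0, KBT)
        assert k == pytest.approx(4.063186132803688, rel=1e-12)

    def test_zero_force_identity(self):
        for xb in (-0.5, 0.0, 0.7):
            assert membrane_off_rate(BellBond(0.29, xb), 0.0) == 0.29

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            membrane_off_rate(BellBond(1.0, 0.3), -1.0)
        with pytest.raises(InvalidParameterError):
            membrane_off_rate(BellBond(1.0, 0.3), math.nan)
        with pytest.raises(InvalidParameterError):
            BellBond(-0.1, 0.3)

    @given(k0=st.floats(1e-3, 1e3),
           xb=st.one_of(st.floats(0.01, 1.0), st.floats(-1.0, -0.01),
                        st.just(0.0)),
           f1=st.floats(0.0, 100.0), df=st.floats(0.1, 50.0))
    def test_monotonicity_tracks_sign_of_x_beta(self, k0, xb, f1, df):
        """Slip bonds (x_beta > 0) get faster under force, catch bonds slower."""
        bond = BellBond(k0, xb)
        a = membrane_off_rate(bond, f1)
        b = membrane_off_rate(bond, f1 + df)
        if xb > 0:
            assert b > a
        elif xb < 0:
            assert b < a
        else:
            assert b == a


class TestFoldChange:
    def test_positive_coupling_amplifies_100_fold_to_820(self):
        rel = ForceSensitivityRelation(slope=0.3, intercept=0.0)
        fold = fold_change_under_force(0.1, 10.0, rel, 15.0, KBT)
        assert fold == pytest.approx(820, rel=0.01)

    def test_negative_coupling_dampens_100_fold_to_12(self):
        rel = ForceSensitivityRelation(slope=-0.3, intercept=0.0)
        fold = fold_change_under_force(0.1, 10.0, rel, 15.0, KBT)
        assert fold == pytest.approx(12.2, rel=0.01)

    def test_no_force_preserves_ratio(self):
        rel = ForceSensitivityRelation(slope=0.3, intercept=0.1)
        assert fold_change_under_force(0.03, 3.0, rel, 0.0) == pytest.approx(100.0)

    @given(level=st.floats(1e-3, 1e2), ratio=st.floats(1.1, 1e3),
           slope=st.floats(-0.5, 0.5), force=st.floats(0.0, 60.0))
    def test_depends_only_on_rate_ratio(self, level, ratio, slope, force):
        """With x_beta linear in log10(k_off) the fold change is a function
        of the off-rate ratio alone, not of the absolute rates."""
        rel = ForceSensitivityRelation(slope=slope, intercept=0.2)
        a = fold_change_under_force(level, level * ratio, rel, force)
        b = fold_change_under_force(level * 7.3, level * 7.3 * ratio, rel, force)
        assert a == pytest.approx(b, rel=1e-9)


class TestFitBell:
    def test_noiseless_round_trip(self):
        kBT = BODY_TEMPERATURE.k_B_T
        F = np.array([0.0, 10.0, 20.0, 30.0])
        rates = 1.0 * np.exp(F * 0.4 / kBT)
        bond = fit_bell(F, rates)
        assert bond.k0_off == pytest.approx(1.0, rel=1e-9)
        assert bond.x_beta == pytest.approx(0.4, rel=1e-9)

    def test_constant_rates_give_zero_sensitivity(self):
        bond = fit_bell([5.0, 15.0, 40.0], [0.7, 0.7, 0.7])
        assert bond.x_beta == pytest.approx(0.0, abs=1e-12)

    def test_nonlinear_mode_agrees_on_noiseless_data(self):
        kBT = BODY_TEMPERATURE.k_B_T
        F = np.array([5.0, 15.0, 30.0, 45.0])
        rates = 0.3 * np.exp(F * 0.25 / kBT)
        a = fit_bell(F, rates)
        b = fit_bell(F, rates, method="nonlinear")
        assert b.k0_off == pytest.approx(a.k0_off, rel=1e-6)
        assert b.x_beta == pytest.approx(a.x_beta, rel=1e-6)

    def test_monte_carlo_estimates_are_unbiased(self):
        """200 replicate fits of 5%-lognormal-noise data: mean estimates
        land within 2 standard errors of the truth."""
        rng = np.random.default_rng(42)
        kBT = BODY_TEMPERATURE.k_B_T
        F = np.array([5.0, 15.0, 25.0, 40.0, 55.0])
        truth = BellBond(0.5, 0.3)
        k0s, xbs = [], []
        for _ in range(200):
            rates = np.array([membrane_off_rate(truth, f) for f in F])
            noisy = rates * np.exp(rng.normal(0.0, 0.05, F.size))
            b = fit_bell(F, noisy)
            k0s.append(b.k0_off)
            xbs.append(b.x_beta)
        for est, true in ((k0s, truth.k0_off), (xbs, truth.x_beta)):
            est = np.asarray(est)
            se = est.std(ddof=1) / math.sqrt(est.size)
            assert abs(est.mean() - true) < 2 * se + 1e-4 * abs(true)

    def test_rejects_bad_inputs(self):
        with pytest.raises(FitInputError):
            fit_bell([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(FitInputError):
            fit_bell([1.0, 2.0, 3.0], [1.0, -2.0, 3.0])
        with pytest.raises(FitInputError):
            fit_bell([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])  # not distinct


class TestBellEvans:
    PARAMS = BellEvansParams(k_off_tau=1e-5, x_beta=5.0, kappa=0.12)

    def test_unit_log_argument_gives_zero_force(self):
        p = self.PARAMS
        v_star = p.k_off_tau / (p.x_beta * p.kappa)  # log argument exactly 1
        with pytest.warns(UserWarning):
            assert bell_evans_force(v_star, p) == 0.0

    def test_most_probable_rupture_force_value(self):
        # (1/5) * ln(5*0.12*0.005/1e-5) = 0.2 ln 300
        f = bell_evans_force(0.005, self.PARAMS, k_B_T=1.0)
        assert f == pytest.approx(0.2 * math.log(300.0), rel=1e-12)

    def test_doubling_speed_adds_kT_over_xbeta_ln2(self):
        f1 = bell_evans_force(0.002, self.PARAMS)
        f2 = bell_evans_force(0.004, self.PARAMS)
        assert f2 - f1 == pytest.approx(math.log(2.0) / 5.0, rel=1e-9)

    def test_sub_threshold_speed_clamps_to_zero(self):
        with pytest.warns(UserWarning):
            assert bell_evans_force(1e-9, self.PARAMS) == 0.0

    def test_forward_then_invert_recovers_parameters(self):
        speeds = [0.0005, 0.001, 0.002, 0.005]
        forces = [bell_evans_force(v, self.PARAMS) for v in speeds]
        fit = fit_bell_evans(speeds, forces, kappa=0.12)
        assert fit.x_beta == pytest.approx(5.0, rel=1e-9)
        assert fit.k_off_tau == pytest.approx(1e-5, rel=1e-8)

    def test_flat_forces_flagged_non_identifiable(self):
        fit = fit_bell_evans([0.001, 0.002, 0.004], [1.0, 1.0, 1.0])
        assert not fit.identifiable
        assert math.isinf(fit.x_beta)

    def test_standard_error_coverage_near_nominal(self):
        """1-SE interval for x_beta covers the truth ~68% of the time
        under 5% Gaussian force noise (100 seeded replicates)."""
        rng = np.random.default_rng(3)
        speeds = np.array([0.0005, 0.001, 0.002, 0.005])
        clean = np.array([bell_evans_force(v, self.PARAMS) for v in speeds])
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            noisy = clean * (1.0 + rng.normal(0.0, 0.05, speeds.size))
            with np.errstate(all="ignore"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    fit = fit_bell_evans(speeds, noisy, kappa=0.12)
            if fit.identifiable and abs(fit.x_beta - 5.0) < fit.se_x_beta:
                hits += 1
        assert 0.58 <= hits / n_rep <= 0.78

    def test_two_point_closed_form_slope_oracle(self):
        """The fitted slope kT/x_beta matches the closed-form two-point
        difference quotient on noiseless data."""
        speeds = [0.001, 0.002, 0.004]
        forces = [bell_evans_force(v, self.PARAMS) for v in speeds]
        fit = fit_bell_evans(speeds, forces, kappa=0.12)
        slope_oracle = (forces[-1] - forces[0]) / math.log(speeds[-1] / speeds[0])
        assert 1.0 / fit.x_beta == pytest.approx(slope_oracle, rel=1e-9)


class TestXbetaLogSlope:
    def test_exact_recovery_from_noiseless_points(self):
        absc = [0.01, 0.1, 1.0, 10.0]
        pairs = [(a, -0.05 * math.log10(a) + 0.2) for a in absc]
        rel = fit_xbeta_log_slope(pairs)
        assert rel.slope == pytest.approx(-0.05, rel=1e-9)
        assert rel.intercept == pytest.approx(0.2, rel=1e-9)

    def test_constant_sensitivity_gives_zero_slope(self):
        rel = fit_xbeta_log_slope([(0.1, 0.3), (1.0, 0.3), (10.0, 0.3)])
        assert rel.slope == pytest.approx(0.0, abs=1e-12)

    def test_negative_slope_sign_recovered_reliably(self):
        """Five constructs on a true slope of -0.043: the sign is
        recovered in at least 95% of 200 seeded noisy replicates."""
        rng = np.random.default_rng(7)
        absc = np.array([1e-6, 1e-5, 1e-4, 1e-3, 1e-2])
        true = -0.043 * np.log10(absc) * 0 + (-0.043 * np.log10(absc) + 0.05)
        neg = 0
        for _ in range(200):
            noisy = true + rng.normal(0.0, 0.03, absc.size)
            rel = fit_xbeta_log_slope(list(zip(absc, noisy)))
            neg += rel.slope < 0
        assert neg >= 190

    def test_rejects_degenerate_input(self):
        with pytest.raises(FitInputError):
            fit_xbeta_log_slope([(1.0, 0.1)])
        with pytest.raises(FitInputError):
            fit_xbeta_log_slope([(1.0, 0.1), (1.0, 0.2)])


def test_bond_config_round_trip():
    bond = BellBond(0.29, 0.3)
    d = bond.to_dict()
    assert set(d) == {"k0_off", "x_beta_nm", "kB_pN_nm_per_K", "T_K"}
    back = BellBond.from_dict(d)
    assert back.k0_off == bond.k0_off and back.x_beta == bond.x_beta


def test_temperature_context_product_identity():
    tc = TemperatureContext()
    assert tc.k_B_T == tc.k_B * tc.T
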