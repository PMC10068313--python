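"""Arrest detection, survival curves, QC rules and the per-ligand pipeline."""

import math

import numpy as np
import pandas as pd
import pytest

from forcekin.arrest_survival import (SurvivalCurve, binding_linear_density,
                                      correct_nonspecific, detect_arrests,
                                      empirical_survival,
                                      fit_exponential_plateau,
                                      ligand_force_spectrum, off_rate_at_time,
                                      qc_min_events, specificity_filter,
                                      survival_at, xbeta_affinity_correlation)
from forcekin.bell_kinetics import BellBond
from forcekin.exceptions import (CorrectionError, FitInputError,
                                 InvalidParameterError)
from forcekin.synthetic import LFCSimConfig, simulate_arrest_table


class TestDetectArrests:
    def test_constant_velocity_track_has_no_arrests(self):
        x = np.cumsum(np.full(300, 2.0))  # 100 um/s at 50 fps
        assert len(detect_arrests(x, velocity_threshold=10.0)) == 0

    def test_single_stop_duration_and_velocity(self):
        x = np.cumsum(np.full(500, 2.0))
        x[100:151] = x[100]  # 50 zero-speed frames = 1.0 s
        ev = detect_arrests(x, velocity_threshold=10.0)
        assert len(ev) == 1
        assert ev["duration_s"].iloc[0] == pytest.approx(1.0)
        assert ev["velocity_um_s"].iloc[0] == pytest.approx(100.0)

    def test_planted_stops_recovered_within_one_frame(self, rng):
        fps, v = 50.0, 80.0
        stops = [(100, 0.3), (400, 1.2), (700, 4.0)]
        pieces, pos = [], 0.0
        frame = 0
        x = []
        for start, dur in stops + [(1200, 0.0)]:
            while frame < start:
                pos += v / fps
                x.append(pos + rng.normal(0, 0.02))
                frame += 1
            for _ in range(int(round(dur * fps))):
                x.append(pos + rng.normal(0, 0.02))
                frame += 1
        ev = detect_arrests(np.asarray(x), velocity_threshold=20.0, fps=fps)
        assert len(ev) == 3
        for (_, dur), got in zip(stops, ev["duration_s"]):
            assert abs(got - dur) <= 1.0 / fps + 1e-9

    def test_too_short_track_is_empty(self):
        assert len(detect_arrests([1.0], 5.0)) == 0


class TestBindingLinearDensity:
    def test_simple_ratio(self):
        df = pd.DataFrame({"n_arrests": [50], "total_distance_mm": [250.0]})
        res = binding_linear_density(df)
        assert res.values[0] == pytest.approx(0.2)
        assert res.geo_mean == pytest.approx(0.2)

    def test_geometric_mean_of_two_experiments(self):
        df = pd.DataFrame({"n_arrests": [10, 40],
                           "total_distance_mm": [100.0, 100.0]})
        res = binding_linear_density(df)
        assert res.geo_mean == pytest.approx(0.2)  # sqrt(0.1*0.4)

    def test_monte_carlo_geo_mean_within_2_geo_sem(self, rng):
        true = 0.5
        hit = 0
        for _ in range(20):
            vals = true * np.exp(rng.normal(0.0, 0.3, 8))
            df = pd.DataFrame({"n_arrests": vals * 100,
                               "total_distance_mm": [100.0] * 8})
            res = binding_linear_density(df)
            lo = res.geo_mean / res.geo_sem_factor**2
            hi = res.geo_mean * res.geo_sem_factor**2
            hit += lo <= true <= hi
        assert hit >= 17  # ~95% nominal coverage of the 2-SEM interval

    def test_zero_distance_rejected(self):
        df = pd.DataFrame({"n_arrests": [5], "total_distance_mm": [0.0]})
        with pytest.raises(InvalidParameterError):
            binding_linear_density(df)


class TestSpecificityFilter:
    @staticmethod
    def _pairs(folds, label="[2,10)"):
        return pd.DataFrame({"bin_label": [label] * len(folds),
                             "experiment_id": range(len(folds)),
                             "bld_sample": folds,
                             "bld_control": [1.0] * len(folds)})

    def test_clear_specific_bin_retained(self):
        kept, table = specificity_filter(self._pairs([2.5, 3.0, 3.6]))
        assert kept == ["[2,10)"]
        assert table["lower_bound"].iloc[0] > 1.0

    def test_marginal_bin_excluded(self):
        kept, table = specificity_filter(self._pairs([0.6, 1.2, 2.4, 0.8]))
        assert kept == []

    def test_null_data_mostly_excluded(self, rng):
        """With sample indistinguishable from control, most bins are
        excluded: a bin survives the lower-error-bound rule only when
        the noise pushes its geometric mean a full SEM above 1, a
        ~16% one-sided event under the null."""
        excluded = 0
        for b in range(60):
            folds = np.exp(rng.normal(0.0, 0.3, 6))
            kept, _ = specificity_filter(self._pairs(folds, label=f"bin{b}"))
            excluded += not kept
        assert excluded >= 42  # >= 70%; expectation ~84%


class TestEmpiricalSurvival:
    def test_step_function_by_construction(self):
        c = empirical_survival([0.5, 1.5, 2.5, 3.5])
        assert np.allclose(c.times, [0.5, 1.5, 2.5, 3.5])
        assert np.allclose(c.survival, [1.0, 0.75, 0.5, 0.25])
        assert survival_at(c, 0.2) == 1.0
        assert survival_at(c, 5.0) == 0.0

    def test_tied_durations_single_step(self):
        c = empirical_survival([2.0, 2.0, 2.0])
        assert np.allclose(c.times, [2.0])
        assert np.allclose(c.survival, [1.0])
        assert survival_at(c, 2.1) == 0.0

    def test_non_increasing_and_bounded(self, rng):
        d = rng.exponential(0.7, 500)
        c = empirical_survival(d)
        assert np.all(np.diff(c.survival) <= 0)
        assert c.survival.min() >= 0 and c.survival.max() <= 1

    def test_dkw_agreement_with_true_exponential(self, rng):
        d = rng.exponential(0.5, 10_000)
        c = empirical_survival(d)
        sup = np.abs(c.survival - np.exp(-2.0 * c.times)).max()
        assert sup < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            empirical_survival([])


class TestCorrectNonspecific:
    def test_zero_control_weight_is_identity(self):
        s = empirical_survival([0.2, 0.6, 1.4])
        ctrl = empirical_survival([0.1])
        out = correct_nonspecific(s, ctrl, w_sample=5.0, w_control=0.0)
        assert np.allclose(out.survival, s.survival)

    def test_population_mixture_inversion(self, rng):
        """An 80/20 mixture of specific (rate 1) and control-like arrests
        corrects back to the pure exponential."""
        spec = rng.exponential(1.0, 8000)
        ns = rng.exponential(1.0 / 3.0, 2000)
        sample = empirical_survival(np.concatenate([spec, ns]))
        control = empirical_survival(rng.exponential(1.0 / 3.0, 4000))
        out = correct_nonspecific(sample, control, w_sample=10.0, w_control=2.0)
        for t in (0.5, 1.0, 2.0):
            assert survival_at(out, t) == pytest.approx(math.exp(-t), abs=0.03)

    def test_fully_nonspecific_bin_refused(self):
        s = empirical_survival([0.2, 0.6])
        c = empirical_survival([0.3, 0.5])
        with pytest.raises(CorrectionError):
            correct_nonspecific(s, c, w_sample=1.0, w_control=1.0)


class TestQCMinEvents:
    @staticmethod
    def _curve(durations):
        return empirical_survival(durations)

    def test_threshold_boundary(self):
        base = list(np.linspace(1.1, 1.9, 14))
        assert not qc_min_events(self._curve(base + [0.5]))
        assert qc_min_events(self._curve(base + [1.5]))

    def test_interval_is_half_open(self):
        # exactly 1.0 s does not count; exactly 2.0 s counts
        d14 = list(np.linspace(1.1, 1.9, 14))
        assert not qc_min_events(self._curve(d14 + [1.0]))
        assert qc_min_events(self._curve(d14 + [2.0]))


class TestOffRateAtTime:
    def test_ln2_at_half_survival(self):
        c = SurvivalCurve(times=np.array([1.0]), survival=np.array([0.5]),
                          n_events=100)
        assert off_rate_at_time(c, 1.0).value == pytest.approx(math.log(2.0))

    def test_two_second_estimator(self):
        c = SurvivalCurve(times=np.array([2.0]), survival=np.array([0.1]),
                          n_events=100)
        assert off_rate_at_time(c, 2.0).value == pytest.approx(1.1513, rel=1e-4)

    def test_subsequent_event_rule(self):
        # no event at exactly 1 s; first at 1.04 s with survival 0.4
        c = SurvivalCurve(times=np.array([0.5, 1.04, 2.0]),
                          survival=np.array([0.9, 0.4, 0.1]), n_events=50)
        assert off_rate_at_time(c, 1.0).value == pytest.approx(
            -math.log(0.4) / 1.0)

    def test_exhausted_survival_rejected(self):
        c = SurvivalCurve(times=np.array([0.5]), survival=np.array([1.0]),
                          n_events=10)
        with pytest.raises(FitInputError):
            off_rate_at_time(c, 1.0)  # no event at or after 1 s
        c2 = SurvivalCurve(times=np.array([0.5, 1.2]),
                           survival=np.array([0.5, 0.0]), n_events=10)
        with pytest.raises(FitInputError):
            off_rate_at_time(c2, 1.0)


class TestExponentialPlateau:
    def test_noiseless_recovery(self):
        t = np.linspace(0.02, 5.0, 50)
        s = 0.8 * np.exp(-0.8 * t) + 0.2
        curve = SurvivalCurve(times=t, survival=s, n_events=500)
        est = fit_exponential_plateau(curve)
        assert est.value == pytest.approx(0.8, rel=1e-6)
        assert est.amplitude == pytest.approx(1.0, rel=1e-5)
        assert est.plateau == pytest.approx(0.2, rel=1e-5)

    def test_pure_exponential_matches_log_linear_oracle(self):
        t = np.linspace(0.05, 4.0, 40)
        s = np.exp(-1.3 * t)
        curve = SurvivalCurve(times=t, survival=s, n_events=500)
        est = fit_exponential_plateau(curve, fix_plateau=0.0)
        slope_oracle = -np.polyfit(t, np.log(s), 1)[0]
        assert est.value == pytest.approx(slope_oracle, rel=1e-6)

    def test_flat_curve_flagged(self):
        t = np.linspace(0.1, 5.0, 30)
        curve = SurvivalCurve(times=t, survival=np.ones_like(t), n_events=50)
        est = fit_exponential_plateau(curve)
        assert not est.ok


class TestLigandForceSpectrum:
    def test_catch_bond_sign_recovered(self):
        cfg = LFCSimConfig(true_bond=BellBond(0.8, -0.2), n_beads=80,
                           plateau_fraction=0.05)
        sim = simulate_arrest_table(cfg, seed=21)
        res = ligand_force_spectrum(sim.events, sim.controls,
                                    summaries=sim.summaries)
        bond = res.bells["exp_fit"]
        assert bond is not None
        assert bond.x_beta < 0

    def test_force_independent_bond_estimated_near_zero(self):
        """A bond with x_beta = 0 comes out with negligible fitted
        force sensitivity (well below the 0.1-0.4 nm signal scale), and
        the survival-at-1-s estimator's interval covers zero."""
        cfg = LFCSimConfig(true_bond=BellBond(0.5, 1e-9), n_beads=80,
                           plateau_fraction=0.05)
        sim = simulate_arrest_table(cfg, seed=22)
        res = ligand_force_spectrum(sim.events, sim.controls,
                                    summaries=sim.summaries)
        exp_bond = res.bells["exp_fit"]
        assert exp_bond is not None
        assert abs(exp_bond.x_beta) < 0.02
        at1 = res.bells["at_1s"]
        assert at1 is not None
        assert abs(at1.x_beta) < 3 * at1.se_x_beta + 0.02

    def test_reports_all_three_estimators(self, lfc_recovery):
        _, _, res = lfc_recovery
        for m in ("at_1s", "at_2s", "exp_fit"):
            assert f"koff_{m}" in res.table.columns


def test_xbeta_affinity_correlation_two_ligand_line():
    fits = [(BellBond(0.3, 0.30), 5.0), (BellBond(1.0, 0.24), 50.0)]
    rel = xbeta_affinity_correlation(fits)
    assert rel.slope == pytest.approx(-0.06, rel=1e-9)
    assert rel.argument_kind == "K_D"
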