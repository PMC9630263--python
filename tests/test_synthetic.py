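import dataclasses

import numpy as np
import pytest

from divekin import (
    G,
    VARIABLE_NAMES,
    Rule,
    SimParams,
    default_params,
    default_session_config,
    simulate_dive,
    simulate_outcome_table,
    simulate_session,
)
from divekin.pipeline import ProcessConfig, process_trial
from divekin.synthetic import _DiveModel


class TestSimParams:
    def test_old_rule_forbids_frontal_step(self):
        with pytest.raises(ValueError, match="frontal_step"):
            SimParams(rule=Rule.OLD, frontal_step_m=0.2)

    def test_negative_apex_rejected(self):
        with pytest.raises(ValueError, match="flight_apex"):
            SimParams(flight_apex_height_m=-0.1)

    def test_zero_apex_rejected(self):
        with pytest.raises(ValueError, match="flight_apex"):
            SimParams(flight_apex_height_m=0.0)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            SimParams(kin_rate_hz=0)

    def test_impulse_too_short_rejected(self):
        # violent push-off: force must go negative -> non-physical
        p = default_params("old", "right", impulse_duration_s=0.05,
                          countermovement_depth_m=0.4)
        with pytest.raises(ValueError, match="non-physical"):
            _DiveModel(p)


class TestContinuousModel:
    def test_projectile_apex_height(self, clean_new_rule):
        # airborne peak height gain = v0z^2 / (2 g), projectile closed form
        params, _, truth = clean_new_rule
        v0z = truth.takeoff_velocity[2]
        model = _DiveModel(params)
        z_takeoff = model.position(np.array([truth.t_takeoff]))[0, 2]
        z_apex = model.position(np.array([truth.t_apex]))[0, 2]
        assert z_apex - z_takeoff == pytest.approx(v0z**2 / (2 * G), rel=1e-12)

    def test_force_zero_after_takeoff(self, clean_new_rule):
        params, _, truth = clean_new_rule
        model = _DiveModel(params)
        t = np.linspace(truth.t_takeoff, model.t_end, 50)
        assert np.all(model.force(t) == 0.0)

    def test_flight_acceleration_is_gravity(self, clean_new_rule):
        params, _, truth = clean_new_rule
        model = _DiveModel(params)
        t = np.linspace(truth.t_takeoff + 1e-6, model.t_end, 20)
        acc = model._eval(t, "acc")
        np.testing.assert_allclose(acc[:, :2], 0.0, atol=1e-9)
        np.testing.assert_allclose(acc[:, 2], -G, rtol=1e-12)

    def test_c1_continuity_at_phase_boundaries(self, clean_new_rule):
        params, _, _ = clean_new_rule
        model = _DiveModel(params)
        eps = 1e-9
        for piece in model.pieces[1:]:
            t = piece.t0
            before = model.position(np.array([t - eps]))[0]
            after = model.position(np.array([t + eps]))[0]
            np.testing.assert_allclose(before, after, atol=1e-6)
            vb = model.velocity(np.array([t - eps]))[0]
            va = model.velocity(np.array([t + eps]))[0]
            np.testing.assert_allclose(vb, va, atol=1e-6)

    def test_newtonian_consistency_trapezoid(self, clean_new_rule):
        # integral of (Fz - mg) over contact = m * vz_takeoff, O(dt^2)
        params, rec, truth = clean_new_rule
        m = params.body_mass_kg
        fz = rec.grf.values[:, 2]
        t = rec.grf.t
        on_ground = t <= truth.t_takeoff
        imp = np.trapezoid(fz[on_ground] - m * G, t[on_ground])
        # force is zero at takeoff, so the extra -mg tail of the last
        # partial interval is the only O(dt) term; tolerance reflects it
        expected = m * truth.takeoff_velocity[2]
        assert imp == pytest.approx(expected, rel=5e-3)

    def test_mass_scaling(self):
        p1 = default_params("new", "right")
        p2 = dataclasses.replace(p1, body_mass_kg=2 * p1.body_mass_kg)
        t1 = _DiveModel(p1).ground_truth()
        t2 = _DiveModel(p2).ground_truth()
        # weight-normalized ground truth unchanged
        np.testing.assert_allclose(t1.variables.as_array(),
                                   t2.variables.as_array(), rtol=1e-9)
        # absolute forces double
        f1 = _DiveModel(p1).force(np.array([1.1]))
        f2 = _DiveModel(p2).force(np.array([1.1]))
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-12)

    def test_frontal_step_strictly_increases_apd(self):
        t_old = _DiveModel(default_params("old", "right")).ground_truth()
        t_new = _DiveModel(default_params("new", "right")).ground_truth()
        assert t_new.variables.APD > t_old.variables.APD
        assert t_old.variables.APD == pytest.approx(0.25)

    def test_old_rule_apd_has_no_frontal_step_contribution(self, clean_old_rule):
        params, _, truth = clean_old_rule
        assert params.frontal_step_m == 0.0
        assert truth.variables.APD == pytest.approx(params.ap_drift_m)

    def test_truth_invariants(self, clean_new_rule):
        _, _, truth = clean_new_rule
        v = truth.variables
        assert v.RD >= max(v.VD, v.MLD, v.APD)
        assert v.RD <= v.VD + v.MLD + v.APD
        assert v.PV >= v.AV
        assert v.RPF >= max(v.VPF, v.MLPF, v.APPF)
        assert v.RI >= v.VI

    def test_left_side_mirrors_x(self):
        pr = default_params("new", "right")
        pl = default_params("new", "left")
        mr, ml = _DiveModel(pr), _DiveModel(pl)
        t = np.linspace(0, mr.t_end, 100)
        np.testing.assert_allclose(ml.position(t)[:, 0],
                                   -mr.position(t)[:, 0], atol=1e-12)
        # outcomes identical (absolute-value reporting)
        np.testing.assert_allclose(ml.ground_truth().variables.as_array(),
                                   mr.ground_truth().variables.as_array(),
                                   rtol=1e-9)


class TestSimulateDive:
    def test_clean_pipeline_recovers_rd_to_1e6(self, clean_new_rule,
                                               clean_outcomes):
        # default events are sample-grid aligned: discretization-free
        _, _, truth = clean_new_rule
        assert clean_outcomes["RD"] == pytest.approx(truth.variables.RD,
                                                     rel=1e-6)

    def test_clean_pipeline_recovers_all_variables(self, clean_new_rule,
                                                   clean_outcomes):
        _, _, truth = clean_new_rule
        tv = truth.variables.as_dict()
        for k in VARIABLE_NAMES:
            assert clean_outcomes[k] == pytest.approx(tv[k], rel=5e-3), k

    def test_two_clocks(self, clean_new_rule):
        _, rec, _ = clean_new_rule
        assert rec.cm.rate == 400.0
        assert rec.grf.rate == 2000.0
        assert len(rec.grf) > len(rec.cm)

    def test_noise_is_reproducible(self):
        p = default_params("old", "left", noise_sd_pos_m=0.002,
                          noise_sd_force_n=5.0, seed=7)
        r1, _ = simulate_dive(p)
        r2, _ = simulate_dive(p)
        np.testing.assert_array_equal(r1.cm.values, r2.cm.values)
        np.testing.assert_array_equal(r1.grf.values, r2.grf.values)

    def test_truth_independent_of_noise(self):
        p0 = default_params("new", "right")
        pn = dataclasses.replace(p0, noise_sd_pos_m=0.01,
                                 noise_sd_force_n=20.0, seed=3)
        _, t0 = simulate_dive(p0)
        _, tn = simulate_dive(pn)
        np.testing.assert_allclose(t0.variables.as_array(),
                                   tn.variables.as_array(), rtol=1e-12)


class TestSimulateSession:
    def test_default_session_counts(self):
        cfg = default_session_config()
        trials = simulate_session(cfg, seed=1)
        assert len(trials) == 120
        from collections import Counter
        cells = Counter((t.rule.value, t.side.value) for t in trials)
        assert all(v == 30 for v in cells.values()) and len(cells) == 4

    def test_single_subject_cells(self):
        cfg = default_session_config(n_subjects=1)
        trials = simulate_session(cfg, seed=1)
        assert len(trials) == 20
        from collections import Counter
        cells = Counter((t.rule.value, t.side.value) for t in trials)
        assert all(v == 5 for v in cells.values())

    def test_determinism(self):
        cfg = default_session_config(n_subjects=2)
        t1 = simulate_session(cfg, seed=5)
        t2 = simulate_session(cfg, seed=5)
        assert [t.trial_id for t in t1] == [t.trial_id for t in t2]
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.cm.values, b.cm.values)
            np.testing.assert_array_equal(a.grf.values, b.grf.values)

    def test_seed_changes_order(self):
        cfg = default_session_config(n_subjects=1)
        o1 = [t.rule.value for t in simulate_session(cfg, seed=1)]
        o2 = [t.rule.value for t in simulate_session(cfg, seed=2)]
        assert o1 != o2

    def test_empty_roster_rejected(self):
        from divekin.synthetic import SessionConfig
        with pytest.raises(ValueError, match="subject"):
            simulate_session(SessionConfig(subjects=[]), seed=0)

    def test_discard_count(self):
        cfg = default_session_config(n_subjects=2, discard_count=4)
        trials = simulate_session(cfg, seed=1)
        assert sum(t.quality.value == "discarded" for t in trials) == 4


class TestOutcomeTable:
    def test_shape_and_null(self):
        cfg = default_session_config(frontal_step_m=0.0)
        df = simulate_outcome_table(cfg, seed=0)
        assert len(df) == 120
        assert set(VARIABLE_NAMES) <= set(df.columns)
        # null: OR and NR rows drawn from identical distributions
        assert df.groupby("rule")["APD"].mean().values == pytest.approx(
            [0.25, 0.25], rel=0.2)

    def test_rule_effect_visible(self):
        cfg = default_session_config()  # frontal_step_m = 0.25
        df = simulate_outcome_table(cfg, seed=0)
        assert (df.loc[df.rule == "new", "APD"].mean()
                > 1.5 * df.loc[df.rule == "old", "APD"].mean())

    def test_determinism(self):
        cfg = default_session_config()
        d1 = simulate_outcome_table(cfg, seed=9)
        d2 = simulate_outcome_table(cfg, seed=9)
        assert d1.equals(d2)
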