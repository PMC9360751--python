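import dataclasses
import math

import numpy as np
import pytest

from csfdecay.domain import ValidationError
from csfdecay.synthetic import (
    GeneratorConfig,
    TrajectoryConfig,
    _within_projection_slope,
    calibrate_fall,
    daily_drainage_volumes,
    default_config,
    disable_effects,
    generate_cohort,
    mean_trajectory,
    reference_schedule,
)


class TestReferenceSchedule:
    def test_cohort_shape(self):
        sched = reference_schedule()
        assert sched.n_patients == 33
        assert sched.total_visits == 177
        counts = sched.visits_per_patient
        assert float(np.median(counts)) == 6.0
        assert min(counts) == 3 and max(counts) == 6

    def test_time_point_median_days(self):
        assert reference_schedule().time_point_median_days() == {
            1: 3.0, 2: 6.0, 3: 10.0, 4: 13.0, 5: 17.0, 6: 20.5,
        }

    def test_every_patient_meets_inclusion(self):
        for days in reference_schedule().days_by_patient:
            assert len(days) >= 3
            assert days[-1] - days[0] > 7
            assert all(b > a for a, b in zip(days, days[1:]))


class TestMeanTrajectory:
    def test_decay_at_day_zero_is_baseline(self, config):
        assert mean_trajectory("rbc", 0.0, config) == pytest.approx(
            config.trajectories["rbc"].y_ref
        )

    def test_decay_daily_ratio_matches_lambda(self, config):
        # lam ~= 0.330 -> each day retains ~71.9% of the previous day
        lam = config.trajectories["rbc"].lam
        ratio = mean_trajectory("rbc", 5.0, config) / mean_trajectory("rbc", 4.0, config)
        assert ratio == pytest.approx(math.exp(-lam))
        assert ratio == pytest.approx(0.719, abs=1e-3)

    @pytest.mark.parametrize("analyte", ["wbc", "tp"])
    def test_peak_value_at_peak_day(self, config, analyte):
        t_peak = config.trajectories[analyte].t_peak
        grid = np.linspace(0.5, 22, 4000)
        vals = mean_trajectory(analyte, grid, config)
        assert mean_trajectory(analyte, t_peak, config) == pytest.approx(
            config.trajectories[analyte].y_ref
        )
        assert abs(grid[np.argmax(vals)] - t_peak) < 0.02

    def test_unknown_analyte_rejected(self, config):
        with pytest.raises(ValidationError):
            mean_trajectory("glucose", 3.0, config)

    def test_calibrated_fall_hits_target_projection(self, config):
        sched = reference_schedule()
        for analyte in ("wbc", "tp"):
            traj = config.trajectories[analyte]
            slope = _within_projection_slope(sched.days_by_patient, traj.log_mean)
            assert slope == pytest.approx(-traj.target_lambda, abs=1e-10)

    def test_uncalibrated_peaked_trajectory_refuses_to_evaluate(self):
        traj = TrajectoryConfig(kind="peaked", y_ref=1.0, t_peak=6, rise=0.2,
                                target_lambda=0.2)
        with pytest.raises(ValidationError):
            traj.log_mean(3.0)
        assert calibrate_fall(traj).fall > 0


class TestGenerateCohort:
    def test_default_cohort_shape(self, reference_cohort):
        assert len(reference_cohort) == 33
        assert reference_cohort.n_samples == 177

    def test_equal_seeds_equal_cohorts(self, config):
        a = generate_cohort(config, seed=7).samples_frame()
        b = generate_cohort(config, seed=7).samples_frame()
        assert a.equals(b)
        c = generate_cohort(config, seed=8).samples_frame()
        assert not a.equals(c)

    def test_noiseless_limit_equals_mean_trajectory(self, config):
        quiet = dataclasses.replace(config, sigma=0.0, tau=0.0, complications={})
        cohort = generate_cohort(quiet, seed=0)
        for p in cohort:
            for s in p.samples:
                assert s.rbc_csf == pytest.approx(
                    mean_trajectory("rbc", s.day, config), rel=1e-12
                )
                assert s.wbc_csf == pytest.approx(
                    mean_trajectory("wbc", s.day, config), rel=1e-12
                )

    def test_group_effects_are_exactly_multiplicative(self, config):
        # seed-matched cohorts with and without effects differ only by the
        # configured multipliers, patient by patient, sample by sample
        withfx = generate_cohort(config, seed=11)
        nullfx = generate_cohort(disable_effects(config), seed=11)
        mult_rbc = {
            pid: (3.0 if p.rebleeding.present else 1.0) * (2.0 if p.dci.present else 1.0)
            for pid, p in ((p.patient_id, p) for p in withfx)
        }
        assert any(m != 1.0 for m in mult_rbc.values())
        for pa, pb in zip(withfx, nullfx):
            assert pa.patient_id == pb.patient_id
            assert pa.dci.present == pb.dci.present
            for sa, sb in zip(pa.samples, pb.samples):
                assert sa.rbc_csf == pytest.approx(
                    mult_rbc[pa.patient_id] * sb.rbc_csf, rel=1e-12
                )

    def test_drainage_median_converges_to_config(self, config):
        rng = np.random.default_rng(5)
        draws = daily_drainage_volumes(config, rng, 200_000)
        assert float(np.median(draws)) == pytest.approx(config.drainage_median, abs=3.0)

    def test_cumulative_drainage_is_nondecreasing(self, reference_cohort):
        for p in reference_cohort:
            drains = [s.cum_drainage for s in p.samples]
            assert all(b >= a for a, b in zip(drains, drains[1:]))

    def test_stochastic_schedule_respects_protocol(self, config):
        cfg = dataclasses.replace(config, schedule="stochastic", n_patients=40)
        cohort = generate_cohort(cfg, seed=3)
        assert len(cohort) == 40
        for p in cohort:
            days = [s.day for s in p.samples]
            assert len(days) >= 3
            assert days[-1] - days[0] > 7
            assert days[-1] <= cfg.horizon_days

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(sigma=-1)
        with pytest.raises(ValidationError):
            GeneratorConfig(schedule="weekly")
        with pytest.raises(ValidationError):
            TrajectoryConfig(kind="peaked", y_ref=1.0, t_peak=None, rise=0.1)

    def test_labels_match_reported_prevalence_direction(self, config):
        # across many seeds the label rates approach the configured ones
        counts = {"rebleeding": 0, "ventriculitis": 0, "dci": 0}
        n = 0
        for seed in range(30):
            for p in generate_cohort(config, seed=seed):
                n += 1
                for o in counts:
                    counts[o] += p.label(o)
        for o, prev in (("rebleeding", 0.18), ("ventriculitis", 0.15), ("dci", 0.36)):
            assert counts[o] / n == pytest.approx(prev, abs=0.03)
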