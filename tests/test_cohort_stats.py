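import dataclasses
import math

import numpy as np
import pytest

from conftest import make_patient
from csfdecay.cohort_stats import (
    compare_groups,
    outcome_association,
    peak_day,
    summarize_time_points,
)
from csfdecay.domain import Cohort, ValidationError
from csfdecay.synthetic import default_config, disable_effects, generate_cohort


class TestSummaries:
    def test_flat_cohort_every_median_is_v(self, flat_cohort):
        table = summarize_time_points(flat_cohort)
        for stat in ("rbc", "wbc", "tp"):
            sub = table.table[(table.table.statistic == stat) & (table.table.n > 0)]
            assert (sub["median"] == 100.0).all()
            assert (sub["q1"] == 100.0).all() and (sub["q3"] == 100.0).all()

    def test_reference_cohort_bin_median_days(self, reference_cohort):
        assert summarize_time_points(reference_cohort).median_days() == {
            1: 3.0, 2: 6.0, 3: 10.0, 4: 13.0, 5: 17.0, 6: 20.5,
        }

    def test_single_sample_cohort_has_one_populated_bin(self):
        cohort = Cohort([make_patient("A", [3], [10])])
        table = summarize_time_points(cohort).table
        rbc = table[table.statistic == "rbc"]
        assert (rbc.n > 0).sum() == 1
        assert (rbc.n == 0).sum() == 5

    def test_order_and_duplicate_invariance(self, reference_cohort):
        base = summarize_time_points(reference_cohort).table
        reversed_cohort = Cohort(list(reference_cohort)[::-1])
        again = summarize_time_points(reversed_cohort).table
        merged = base.merge(again, on=["time_point", "statistic"], suffixes=("_a", "_b"))
        assert np.allclose(merged.median_a, merged.median_b, equal_nan=True)

    def test_samples_beyond_day_22_excluded(self):
        p = make_patient("A", [3, 10, 25], [5, 5, 99])
        table = summarize_time_points(Cohort([p])).table
        assert table[table.statistic == "rbc"].n.sum() == 2  # day 25 dropped


class TestPeakDay:
    def test_decreasing_trajectories_peak_at_first_day(self):
        cohort = Cohort(
            [
                make_patient("A", [2, 6, 10], [30, 20, 10]),
                make_patient("B", [3, 7, 11], [9, 8, 7]),
            ]
        )
        assert peak_day(cohort, "rbc") == pytest.approx(2.5)

    def test_tie_broken_to_earliest_day(self):
        cohort = Cohort([make_patient("A", [2, 6, 10], [5, 5, 1])])
        assert peak_day(cohort, "wbc") == 2.0

    def test_reference_cohort_wbc_and_tp_peaks(self, reference_cohort):
        assert abs(peak_day(reference_cohort, "wbc") - 6) <= 1.5
        assert abs(peak_day(reference_cohort, "tp") - 13) <= 1.5


class TestGroupContrasts:
    def test_two_group_contrast_matches_difference_of_means(self):
        # one time point, identity scale: the contrast is the group-mean gap
        with_group = [make_patient(f"W{i}", [3], [v], outcome="dci") for i, v in enumerate([12, 14])]
        without = [make_patient(f"N{i}", [3], [v]) for i, v in enumerate([7, 9, 11])]
        gc = compare_groups(Cohort(with_group + without), "dci", "wbc", transform="identity")
        row = gc.contrasts[gc.contrasts.time_point == 1].iloc[0]
        assert row.estimable
        assert row.estimate == pytest.approx(np.mean([12, 14]) - np.mean([7, 9, 11]))

    def test_log_scale_contrasts_shift_invariant(self, reference_cohort):
        # multiplying every value by a constant leaves log-scale contrasts unchanged
        base = compare_groups(reference_cohort, "dci", "wbc").contrasts
        scaled_patients = []
        for p in reference_cohort:
            q = dataclasses.replace(
                p,
                samples=[dataclasses.replace(s, wbc_csf=s.wbc_csf * 7.5) for s in p.samples],
            )
            scaled_patients.append(q)
        scaled = compare_groups(Cohort(scaled_patients), "dci", "wbc").contrasts
        assert np.allclose(base.estimate, scaled.estimate, equal_nan=True)

    def test_absent_group_reported_not_estimable(self):
        with_group = [make_patient("W0", [3], [12], outcome="dci")]
        without = [make_patient("N0", [3, 6], [7, 7]), make_patient("N1", [6], [9])]
        gc = compare_groups(Cohort(with_group + without), "dci", "wbc", transform="identity")
        rows = gc.contrasts.set_index("time_point")
        assert rows.loc[1, "estimable"]
        assert not rows.loc[2, "estimable"]  # no DCI patient at time point 2

    def test_dci_effect_on_wbc_detected_at_first_time_point(self, config):
        # pooled over seeded cohorts the configured DCI effect yields a
        # positive early-WBC contrast
        estimates = []
        for seed in range(8):
            cohort = generate_cohort(config, seed=seed)
            gc = compare_groups(cohort, "dci", "wbc")
            row = gc.contrasts[gc.contrasts.time_point == 1]
            if row.iloc[0].estimable:
                estimates.append(row.iloc[0].estimate)
        assert np.mean(estimates) > 0.5  # log scale; truth is log(2.5) ~ 0.92

    def test_null_contrasts_center_on_zero(self, config):
        null_cfg = disable_effects(config)
        estimates = []
        for seed in range(10):
            gc = compare_groups(generate_cohort(null_cfg, seed=seed), "dci", "wbc")
            est = gc.contrasts[gc.contrasts.estimable].estimate
            estimates.extend(est.tolist())
        assert abs(np.mean(estimates)) < 0.25


class TestOutcomeAssociation:
    def test_singleton_clusters_reduce_to_heteroskedastic_sandwich(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(5, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(x - 5)))).astype(int)
        patients = [
            make_patient(f"P{i}", [3], [math.exp(v)], outcome="dci" if yi else None)
            for i, (v, yi) in enumerate(zip(x, y))
        ]
        res = outcome_association(Cohort(patients), "dci", "wbc")  # log(wbc) == x
        X = sm.add_constant(x)
        hc0 = sm.Logit(y, X).fit(disp=0, cov_type="HC0")
        expected_se = hc0.bse[1] * math.sqrt(n / (n - 1))
        assert res.n_clusters == n
        assert res.se == pytest.approx(expected_se, rel=1e-6)

    def test_separation_flagged_not_reported(self):
        patients = [
            make_patient(f"P{i}", [3], [100.0 if i < 5 else 1.0],
                         outcome="dci" if i < 5 else None)
            for i in range(10)
        ]
        res = outcome_association(Cohort(patients), "dci", "wbc")
        assert not res.converged
        assert math.isnan(res.estimate)

    def test_strong_effect_detected(self, config):
        # configured ventriculitis effect on WBC: significant in most cohorts
        hits, total = 0, 0
        for seed in range(12):
            cohort = generate_cohort(config, seed=seed)
            labels = [p.label("ventriculitis") for p in cohort]
            if not (any(labels) and not all(labels)):
                continue
            res = outcome_association(cohort, "ventriculitis", "wbc")
            if res.converged:
                total += 1
                hits += res.p_value < 0.05
        assert total >= 8
        assert hits / total > 0.5

    def test_constant_outcome_rejected(self, flat_cohort):
        with pytest.raises(ValidationError):
            outcome_association(flat_cohort, "dci", "wbc")
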