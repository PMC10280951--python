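"""Knockoff importance: metrics, splitting, grouped study mechanics."""

import numpy as np
import pandas as pd
import pytest

import knockvimp as kv


class TestSplit:
    def test_eighty_twenty_sizes(self):
        y = np.r_[np.ones(10, dtype=int), np.zeros(90, dtype=int)]
        train, test = kv.split_train_test(y, 0.2, seed=1)
        assert len(test) == 20 and len(train) == 80
        assert np.array_equal(np.sort(np.r_[train, test]), np.arange(100))

    def test_stratified_allocation_proportional(self):
        y = np.r_[np.ones(10, dtype=int), np.zeros(90, dtype=int)]
        _, test = kv.split_train_test(y, 0.2, seed=2)
        assert y[test].sum() == 2

    def test_same_seed_identical_split(self):
        y = np.r_[np.ones(30, dtype=int), np.zeros(70, dtype=int)]
        a = kv.split_train_test(y, 0.25, seed=3)
        b = kv.split_train_test(y, 0.25, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_tiny_class_rejected(self):
        y = np.r_[np.ones(1, dtype=int), np.zeros(99, dtype=int)]
        with pytest.raises(ValueError, match="class 1"):
            kv.split_train_test(y, 0.2, seed=0)


class TestSensitivitySpecificity:
    def test_perfect_predictions(self):
        t = np.array([1, 0, 1, 0])
        assert kv.sensitivity(t, t) == 1.0
        assert kv.specificity(t, t) == 1.0

    def test_all_ones_predictions(self):
        t = np.array([1, 0, 1, 0])
        p = np.ones(4, dtype=int)
        assert kv.sensitivity(t, p) == 1.0
        assert kv.specificity(t, p) == 0.0

    def test_hand_counted_two_by_two_table(self):
        t = np.array([1, 1, 0, 0])
        p = np.array([1, 0, 0, 1])
        assert kv.sensitivity(t, p) == 0.5
        assert kv.specificity(t, p) == 0.5

    def test_undefined_metrics_raise(self):
        with pytest.raises(ValueError, match="no positive"):
            kv.sensitivity(np.zeros(4, dtype=int), np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="no negative"):
            kv.specificity(np.ones(4, dtype=int), np.ones(4, dtype=int))


@pytest.fixture(scope="module")
def study_inputs(bias_small):
    ds, scheme = bias_small
    sampler = kv.GaussianKnockoffSampler().fit(ds.features)
    ko = sampler.sample(ds.features, seed=99)
    return ds, scheme, sampler, ko


class TestGroupVimp:
    def test_misaligned_knockoffs_rejected(self, study_inputs):
        ds, _, _, ko = study_inputs
        train, test = kv.split_train_test(ds.outcome, 0.2, seed=1)
        with pytest.raises(ValueError, match="shape"):
            kv.knockoff_vimp_group(
                ds.features, ds.outcome, ko[:, :3], ["X1"], ds.feature_names,
                train, test, threshold=0.3,
            )

    def test_threshold_out_of_range_rejected(self, study_inputs):
        ds, _, _, ko = study_inputs
        train, test = kv.split_train_test(ds.outcome, 0.2, seed=1)
        with pytest.raises(ValueError, match="threshold"):
            kv.knockoff_vimp_group(
                ds.features, ds.outcome, ko, ["X1"], ds.feature_names,
                train, test, threshold=1.5,
            )

    def test_accuracy_decomposes_into_prevalence_weighted_rates(self, study_inputs):
        ds, _, _, ko = study_inputs
        train, test = kv.split_train_test(ds.outcome, 0.2, seed=4)
        res = kv.knockoff_vimp_group(
            ds.features, ds.outcome, ko, ["X1", "X2"], ds.feature_names,
            train, test, forest_params={"n_trees": 30}, threshold=0.3, seed=2,
        )
        pi = ds.outcome[test].mean()
        recon = pi * res.vimp_sens + (1 - pi) * res.vimp_spec
        assert abs(res.vimp_acc - recon) < 1e-12

    def test_aggregate_equals_mean_participant_delta(self, study_inputs):
        ds, _, _, ko = study_inputs
        train, test = kv.split_train_test(ds.outcome, 0.2, seed=4)
        res = kv.knockoff_vimp_group(
            ds.features, ds.outcome, ko, ["X3"], ds.feature_names,
            train, test, forest_params={"n_trees": 30}, threshold=0.3, seed=2,
        )
        assert abs(res.vimp_acc - res.participant_deltas.mean()) < 1e-12

    def test_deterministic_given_seed(self, study_inputs):
        ds, _, _, ko = study_inputs
        train, test = kv.split_train_test(ds.outcome, 0.2, seed=4)
        kwargs = dict(
            forest_params={"n_trees": 20}, threshold=0.3, seed=8,
            level="roles", group_name="causal",
        )
        a = kv.knockoff_vimp_group(
            ds.features, ds.outcome, ko, ["X1", "X2"], ds.feature_names,
            train, test, **kwargs,
        )
        b = kv.knockoff_vimp_group(
            ds.features, ds.outcome, ko, ["X1", "X2"], ds.feature_names,
            train, test, **kwargs,
        )
        assert (a.vimp_sens, a.vimp_spec, a.vimp_acc) == (
            b.vimp_sens, b.vimp_spec, b.vimp_acc
        )


class TestRunStudy:
    def test_one_row_per_group_per_level(self, study_inputs):
        ds, scheme, _, ko = study_inputs
        table = kv.run_study(
            ds.features, ds.outcome, scheme, ds.feature_names,
            knockoffs=ko, forest_params={"n_trees": 20}, threshold=0.3, seed=1,
        )
        assert len(table) == scheme.n_groups

    def test_same_base_seed_identical_tables(self, study_inputs):
        ds, scheme, sampler, _ = study_inputs
        kwargs = dict(
            sampler=sampler, forest_params={"n_trees": 20},
            threshold="auto", seed=5,
        )
        a = kv.run_study(ds.features, ds.outcome, scheme, ds.feature_names, **kwargs)
        b = kv.run_study(ds.features, ds.outcome, scheme, ds.feature_names, **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_replicate_mode_reports_mean_and_sd(self, study_inputs):
        ds, scheme, sampler, _ = study_inputs
        table = kv.run_study(
            ds.features, ds.outcome, scheme, ds.feature_names,
            sampler=sampler, forest_params={"n_trees": 15},
            threshold=0.3, seed=2, replicates=3,
        )
        assert "vimp_sens_sd" in table.columns
        assert len(table) == scheme.n_groups
        assert (table["vimp_sens_sd"] >= 0).all()

    def test_per_group_failure_recorded_others_run(self, study_inputs, monkeypatch):
        ds, _, _, ko = study_inputs
        import knockvimp.knockoff_importance as ki

        real = ki.knockoff_vimp_group

        def flaky(*args, **kwargs):
            if kwargs.get("group_name") == "bad":
                raise ValueError("synthetic failure for this group")
            return real(*args, **kwargs)

        monkeypatch.setattr(ki, "knockoff_vimp_group", flaky)
        scheme = kv.GroupingScheme(levels={"l1": {"ok": ["X1"], "bad": ["X2"]}})
        table = ki.run_study(
            ds.features, ds.outcome, scheme, ds.feature_names,
            knockoffs=ko, forest_params={"n_trees": 10}, threshold=0.3, seed=3,
        )
        bad = table[table["group"] == "bad"].iloc[0]
        ok = table[table["group"] == "ok"].iloc[0]
        assert "synthetic failure" in bad["error"] and np.isnan(bad["vimp_acc"])
        assert ok["error"] == "" and np.isfinite(ok["vimp_acc"])

    def test_fig_filter_keeps_only_doubly_positive_rows(self):
        table = pd.DataFrame({
            "group": ["a", "b", "c"],
            "vimp_sens": [0.05, 0.02, -0.01],
            "vimp_spec": [0.01, -0.01, 0.02],
        })
        out = kv.fig_filter(table)
        assert list(out["group"]) == ["a"]


class TestNullAndSignalBehaviour:
    def test_null_singleton_group_centered_on_zero(self):
        # a pure-noise feature's knockoff VIMP distribution straddles zero
        vals_sens, vals_spec = [], []
        for seed in range(15):
            ds, _ = kv.make_bias_scenario(
                n=500, rho=0.0, betas=(1.0, 1.0), prevalence=0.3,
                n_noise=2, seed=300 + seed,
            )
            sampler = kv.GaussianKnockoffSampler().fit(ds.features)
            ko = sampler.sample(ds.features, seed=seed)
            train, test = kv.split_train_test(ds.outcome, 0.2, seed=seed)
            res = kv.knockoff_vimp_group(
                ds.features, ds.outcome, ko, ["X4"], ds.feature_names,
                train, test, forest_params={"n_trees": 60},
                threshold=0.3, seed=seed,
            )
            vals_sens.append(res.vimp_sens)
            vals_spec.append(res.vimp_spec)
        for vals in (np.asarray(vals_sens), np.asarray(vals_spec)):
            hw = 2.15 * vals.std(ddof=1) / np.sqrt(len(vals))  # t_14, 95%
            assert abs(vals.mean()) <= hw + 1e-12

    def test_causal_group_beats_noise_group(self):
        # signal dominance at a moderate effect size and sample size
        wins = 0
        for seed in range(6):
            ds, _ = kv.make_bias_scenario(
                n=2000, rho=0.0, betas=(1.5, 1.5), prevalence=0.3,
                n_noise=3, seed=400 + seed,
            )
            sampler = kv.GaussianKnockoffSampler().fit(ds.features)
            ko = sampler.sample(ds.features, seed=seed)
            train, test = kv.split_train_test(ds.outcome, 0.2, seed=seed)
            common = dict(
                forest_params={"n_trees": 80}, threshold=0.3, seed=seed,
            )
            causal = kv.knockoff_vimp_group(
                ds.features, ds.outcome, ko, ["X1", "X2"], ds.feature_names,
                train, test, **common,
            )
            noise = kv.knockoff_vimp_group(
                ds.features, ds.outcome, ko, ["X4", "X5"], ds.feature_names,
                train, test, **common,
            )
            wins += causal.vimp_acc > noise.vimp_acc
        assert wins >= 5
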