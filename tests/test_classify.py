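"""QDA phenotype classifier and Monte-Carlo split-evaluation harness."""

import numpy as np
import pandas as pd
import pytest

from leafpol.classify import (
    CLASS_ORDER,
    PhenotypeQDA,
    QDAResults,
    monte_carlo_evaluation,
    run_split,
)
from leafpol.errors import FitError, ParameterError
from leafpol.synthetic import (
    ClassCloud,
    FeatureCloudSpec,
    default_feature_spec,
    generate_feature_dataset,
    generate_study_sized_dataset,
)


def scaled(df: pd.DataFrame) -> pd.DataFrame:
    """R_Qav rescaled to order 1 (QDA is scale-equivariant; sklearn's rank
    checks are not, so oracle comparisons run on the rescaled copy)."""
    out = df.copy()
    out["R_Qav"] = out["R_Qav"] * 1e4
    return out


class TestFit:
    def test_recovers_point_mass_means(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 0.01, (50, 2))
        b = rng.normal([1, 1], 0.01, (50, 2))
        df = pd.DataFrame(
            np.vstack([a, b]), columns=["R_Qav", "DIFF_R"]
        ).assign(label=["glossy"] * 50 + ["hairy"] * 50)
        res = PhenotypeQDA.from_dataframe(df).fit()
        assert np.allclose(res.means["glossy"], [0, 0], atol=0.01)
        assert np.allclose(res.means["hairy"], [1, 1], atol=0.01)

    def test_fit_is_deterministic(self, balanced_features):
        r1 = PhenotypeQDA.from_dataframe(balanced_features).fit()
        r2 = PhenotypeQDA.from_dataframe(balanced_features).fit()
        for c in r1.classes:
            assert np.array_equal(r1.means[c], r2.means[c])
            assert np.array_equal(r1.covariances[c], r2.covariances[c])

    def test_small_class_errors_with_name(self, balanced_features):
        df = pd.concat(
            [
                balanced_features[balanced_features.label != "hairy"],
                balanced_features[balanced_features.label == "hairy"].head(2),
            ],
            ignore_index=True,
        )
        with pytest.raises(FitError, match="hairy"):
            PhenotypeQDA.from_dataframe(df).fit()

    def test_equal_priors_regardless_of_counts(self):
        df = generate_study_sized_dataset(0)  # unbalanced 104/110/39/96
        res = PhenotypeQDA.from_dataframe(df).fit()
        assert all(p == pytest.approx(0.25) for p in res.priors.values())

    def test_parameter_recovery_on_untruncated_clouds(self):
        """Fitted means/covariances approach generator truth at n=1e4."""
        spec = FeatureCloudSpec(
            classes={
                "glossy": ClassCloud(
                    mean=(6.0, 9.0), cov=((2.0, 0.6), (0.6, 4.0)),
                    rqav_bounds=None, diffr_bounds=None,
                ),
                "glabrous": ClassCloud(
                    mean=(2.0, 6.0), cov=((1.0, -0.3), (-0.3, 2.0)),
                    rqav_bounds=None, diffr_bounds=None,
                ),
            },
            n_per_class=10_000,
        )
        df = generate_feature_dataset(spec, seed=1)
        res = PhenotypeQDA.from_dataframe(df).fit()
        for label, cloud in spec.classes.items():
            true_mean = np.asarray(cloud.mean)
            true_cov = np.asarray(cloud.cov)
            assert np.all(
                np.abs(res.means[label] - true_mean) / np.abs(true_mean) < 0.05
            )
            rel = np.linalg.norm(res.covariances[label] - true_cov) / (
                np.linalg.norm(true_cov)
            )
            assert rel < 0.05


class TestPredict:
    def test_class_mean_maps_to_class(self):
        means = {c: np.array([i, -i], float) for i, c in enumerate(CLASS_ORDER)}
        covs = {c: np.eye(2) for c in CLASS_ORDER}
        res = QDAResults.from_parameters(means, covs)
        for c in CLASS_ORDER:
            assert res.predict(means[c][None])[0] == c

    def test_identity_covariance_equals_nearest_mean_rule(self):
        rng = np.random.default_rng(3)
        means = {c: rng.normal(0, 3, 2) for c in CLASS_ORDER}
        res = QDAResults.from_parameters(
            means, {c: np.eye(2) for c in CLASS_ORDER}
        )
        pts = rng.normal(0, 3, (100, 2))
        mean_mat = np.stack([means[c] for c in res.classes])
        d = ((pts[:, None, :] - mean_mat[None]) ** 2).sum(axis=2)
        nearest = np.array([res.classes[i] for i in d.argmin(axis=1)])
        assert np.array_equal(res.predict(pts), nearest)

    def test_pooled_covariance_matches_lda_oracle_on_grid(self, balanced_features):
        """With pooled covariance the quadratic rule degenerates to LDA."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        df = scaled(balanced_features)
        res = PhenotypeQDA.from_dataframe(df).fit(pooled_covariance=True)
        X = df[["R_Qav", "DIFF_R"]].to_numpy()
        lda = LinearDiscriminantAnalysis(priors=[0.25] * 4).fit(
            X, df["label"].to_numpy()
        )
        g0 = np.linspace(X[:, 0].min(), X[:, 0].max(), 50) + 1e-7
        g1 = np.linspace(X[:, 1].min(), X[:, 1].max(), 50) + 1e-7
        grid = np.array(np.meshgrid(g0, g1)).reshape(2, -1).T
        assert np.array_equal(res.predict(grid), lda.predict(grid))

    def test_full_qda_matches_sklearn_oracle(self, balanced_features):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        df = scaled(balanced_features)
        X = df[["R_Qav", "DIFF_R"]].to_numpy()
        res = PhenotypeQDA.from_dataframe(df).fit()
        sk = QuadraticDiscriminantAnalysis(priors=[0.25] * 4).fit(
            X, df["label"].to_numpy()
        )
        rng = np.random.default_rng(5)
        pts = np.column_stack(
            [rng.uniform(0, 20, 400), rng.uniform(0, 15, 400)]
        )
        assert (res.predict(pts) == sk.predict(pts)).mean() == 1.0

    def test_glossy_only_region(self, balanced_features):
        res = PhenotypeQDA.from_dataframe(balanced_features).fit()
        assert res.predict([[12e-4, 9.0]])[0] == "glossy"

    def test_duplicating_a_class_leaves_predictions_stable(self, balanced_features):
        """Equal priors: class frequency does not sway the decision rule."""
        df = balanced_features
        dup = pd.concat(
            [df, df[df.label == "glaucous"]], ignore_index=True
        )
        r1 = PhenotypeQDA.from_dataframe(df).fit()
        r2 = PhenotypeQDA.from_dataframe(dup).fit()
        rng = np.random.default_rng(6)
        pts = np.column_stack(
            [rng.uniform(0, 10e-4, 500), rng.uniform(1, 14, 500)]
        )
        # only the (n-1) vs (2n-1) covariance normalization differs
        assert (r1.predict(pts) == r2.predict(pts)).mean() >= 0.99

    def test_non_finite_input_rejected(self, balanced_features):
        res = PhenotypeQDA.from_dataframe(balanced_features).fit()
        with pytest.raises(ParameterError):
            res.predict([[np.nan, 1.0]])

    def test_json_round_trip(self, balanced_features, tmp_path):
        res = PhenotypeQDA.from_dataframe(balanced_features).fit()
        res.to_json(tmp_path / "model.json")
        back = QDAResults.from_json(tmp_path / "model.json")
        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.uniform(0, 1e-3, 50), rng.uniform(1, 12, 50)])
        assert np.array_equal(res.predict(pts), back.predict(pts))

    def test_summary_mentions_all_classes(self, balanced_features):
        text = PhenotypeQDA.from_dataframe(balanced_features).fit().summary()
        for c in CLASS_ORDER:
            assert c in text


class TestRunSplit:
    def test_study_sizes(self):
        labels = generate_study_sized_dataset(1)["label"].to_numpy()
        train, test = run_split(labels, 150, seed=0)
        assert train.size == 150 and test.size == 199

    def test_same_seed_same_partition(self):
        labels = np.repeat(list(CLASS_ORDER), 20)
        a = run_split(labels, 30, seed=5)
        b = run_split(labels, 30, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_partition_laws(self):
        labels = np.repeat(list(CLASS_ORDER), 25)
        train, test = run_split(labels, 37, seed=2)
        union = np.sort(np.concatenate([train, test]))
        assert np.array_equal(union, np.arange(100))
        assert np.intersect1d(train, test).size == 0

    def test_every_class_in_train(self):
        labels = np.array(["glossy"] * 95 + ["hairy"] * 5)
        for seed in range(20):
            train, _ = run_split(labels, 10, seed=seed)
            assert set(labels[train]) == {"glossy", "hairy"}

    def test_bad_n_train(self):
        with pytest.raises(ParameterError):
            run_split(np.array(["a", "b", "c"]), 3, seed=0)


class TestMonteCarlo:
    def test_separated_classes_score_perfectly(self):
        rng = np.random.default_rng(0)
        frames = []
        for i, c in enumerate(CLASS_ORDER):
            pts = rng.normal([10 * i, 10 * i], 0.1, (30, 2))
            frames.append(
                pd.DataFrame(pts, columns=["R_Qav", "DIFF_R"]).assign(label=c)
            )
        df = pd.concat(frames, ignore_index=True)
        mc = monte_carlo_evaluation(df, n_train=60, n_runs=50, seed=1)
        assert mc.mean_rate == 1.0 and mc.sd_rate == 0.0

    def test_shuffled_labels_score_at_chance(self):
        """Null: ~25% mean rate on 4 balanced classes with shuffled labels.

        Each fixed label permutation has its own (slightly learnable) chance
        level, so runs on one dataset are not independent draws of the null;
        the mean is taken over independent shuffled datasets (500 runs in
        total) and the standard error across those replicates.
        """
        dataset_means = []
        for ds in range(10):
            rng = np.random.default_rng(1000 + ds)
            df = pd.DataFrame(
                rng.normal(0, 1, (200, 2)), columns=["R_Qav", "DIFF_R"]
            ).assign(label=rng.permutation(np.repeat(list(CLASS_ORDER), 50)))
            mc = monte_carlo_evaluation(df, n_train=100, n_runs=50, seed=3)
            dataset_means.append(mc.mean_rate)
        grand = np.mean(dataset_means)
        se = np.std(dataset_means, ddof=1) / np.sqrt(len(dataset_means))
        assert abs(grand - 0.25) <= 3 * se

    def test_deterministic_under_seed(self, balanced_features):
        a = monte_carlo_evaluation(balanced_features, 150, 100, seed=9)
        b = monte_carlo_evaluation(balanced_features, 150, 100, seed=9)
        assert np.array_equal(a.rates, b.rates)
        assert np.array_equal(a.confusions, b.confusions)
        pd.testing.assert_frame_equal(a.class_rates, b.class_rates)

    def test_confusion_rows_sum_to_test_counts(self, balanced_features):
        mc = monte_carlo_evaluation(balanced_features, 150, 20, seed=4)
        y = balanced_features["label"].to_numpy()
        streams = np.random.SeedSequence(4).spawn(20)
        for run, stream in enumerate(streams):
            rng = np.random.default_rng(stream)
            _, test = run_split(y, 150, rng)
            counts = pd.Series(y[test]).value_counts()
            for i, c in enumerate(mc.classes):
                assert mc.confusions[run, i].sum() == counts.get(c, 0)
            # overall rate = trace / total
            conf = mc.confusions[run]
            assert mc.rates[run] == pytest.approx(np.trace(conf) / conf.sum())

    def test_aggregate_mean_stable_in_run_count(self):
        df = generate_feature_dataset(default_feature_spec(40), seed=2)
        big = monte_carlo_evaluation(df, 80, 2000, seed=5)
        small = monte_carlo_evaluation(df, 80, 500, seed=6)
        tol = 3 * big.sd_rate / np.sqrt(500)
        assert abs(big.mean_rate - small.mean_rate) < max(tol, 0.01)

    def test_summary_reports_percentages(self, balanced_features):
        mc = monte_carlo_evaluation(balanced_features, 150, 50, seed=7)
        text = mc.summary()
        assert "%" in text and "runs" in text
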