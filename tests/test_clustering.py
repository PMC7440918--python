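"""Preprocessing, BIC model-order selection and mixture subtyping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

import vtasst as v
from vtasst.clustering import _gmm_n_params, _ppca_n_params


class TestPreprocess:
    def test_minmax_scaling(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [0.0, 1.0, 2.0]})
        scaled, _ = v.preprocess(df, log1p_features=(), log_features=())
        assert list(scaled["a"]) == [0.0, 0.5, 1.0]
        assert scaled.to_numpy().min() == 0.0 and scaled.to_numpy().max() == 1.0

    def test_five_iqr_outlier_rule(self):
        # feature with median 10 and IQR 2: a value of 21 deviates by 11 > 10
        base = np.array([8.0, 9.0, 10.0, 11.0, 12.0] * 5)
        df = pd.DataFrame({"x": np.concatenate([base, [21.0]]),
                           "y": np.zeros(26) + np.arange(26) * 0.01})
        scaled, report = v.preprocess(df, log1p_features=(), log_features=())
        assert report.outlier_cell_ids == [25]
        assert 25 not in scaled.index

    def test_engineered_ten_outliers_reported(self):
        """A cohort engineered with exactly 10 rule-violating cells reports
        exactly those 10 as outliers."""
        rng = np.random.default_rng(0)
        clean = pd.DataFrame(
            rng.normal(0.0, 1.0, (400, 6)),
            columns=[f"f{i}" for i in range(6)],
            index=[f"c{i}" for i in range(400)],
        )
        spiked = clean.copy()
        victims = [f"c{i}" for i in range(0, 100, 10)]
        for j, cid in enumerate(victims):
            spiked.loc[cid, f"f{j % 6}"] = 60.0  # far beyond 5 IQR
        _, report = v.preprocess(spiked, log1p_features=(), log_features=())
        assert sorted(report.outlier_cell_ids) == sorted(victims)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            scaled, report = v.preprocess(df, log1p_features=(), log_features=())
        assert "c" not in scaled.columns and report.dropped_columns == ["c"]

    def test_idempotent_on_own_output(self, cohort):
        # with medians/IQRs frozen from the full (transformed) table, the
        # retained cells contain no remaining rule violations
        df = cohort.values.copy()
        for col in v.DEFAULT_LOG1P_FEATURES:
            df[col] = np.log1p(df[col])
        for col in v.DEFAULT_LOG_FEATURES:
            df[col] = np.log(df[col])
        med = df.median()
        iqr = df.quantile(0.75) - df.quantile(0.25)
        _, report = v.preprocess(cohort)
        kept = df.drop(index=report.outlier_cell_ids)
        assert not ((kept - med).abs() > 5 * iqr).any(axis=1).any()

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            v.preprocess(df)


class TestSelectPcaOrder:
    def test_rank_one_data_selects_one_component(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 1)) @ rng.normal(size=(1, 9))
        X += 0.01 * rng.normal(size=X.shape)
        n_pcs, curve = v.select_pca_order(X, seed=0)
        assert n_pcs == 1
        assert curve.size == 9

    def test_two_factor_model_selects_two(self):
        """Data simulated from a 2-factor model selects 2 PCs in >= 9/10
        seeds (generator-truth oracle)."""
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(300, 2)) @ rng.normal(size=(2, 10))
            X += 0.3 * rng.normal(size=X.shape)
            hits += v.select_pca_order(X, seed=s)[0] == 2
        assert hits >= 9

    def test_deterministic_given_seed(self, cohort):
        scaled, _ = v.preprocess(cohort)
        a = v.select_pca_order(scaled, seed=5)
        b = v.select_pca_order(scaled, seed=5)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])


class TestFitGmm:
    def test_single_gaussian_selects_one_component(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2))
        k, _, _ = v.fit_gmm(X, seed=0)
        assert k == 1

    def test_three_separated_gaussians_recovered_exactly(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        truth = np.repeat([0, 1, 2], 80)
        X = centers[truth] + rng.normal(0.0, 1.0, (240, 2))
        k, _, gm = v.fit_gmm(X, seed=0)
        assert k == 3
        assert adjusted_rand_score(truth, gm.predict(X)) == 1.0

    def test_bic_selection_matches_bruteforce_enumeration(self):
        """Both selection loops equal an independent exhaustive enumeration
        over the same candidate set."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (60, 4)), rng.normal(4, 1, (60, 4))])
        seed, folds = 7, 5

        # brute-force PCA-order oracle
        best = (np.inf, None)
        for k in range(1, 5):
            vals = []
            for tr, te in KFold(folds, shuffle=True, random_state=seed).split(X):
                p = PCA(n_components=k, svd_solver="full").fit(X[tr])
                ll = p.score(X[te]) * len(te)
                vals.append(-2 * ll + _ppca_n_params(4, k) * np.log(len(te)))
            m = np.mean(vals)
            if m < best[0]:
                best = (m, k)
        n_pcs, _ = v.select_pca_order(X, kmax=4, folds=folds, seed=seed)
        assert n_pcs == best[1]

        # brute-force GMM-K oracle
        best = (np.inf, None)
        for k in range(1, 5):
            vals = []
            for tr, te in KFold(folds, shuffle=True, random_state=seed).split(X):
                gm = GaussianMixture(
                    k, covariance_type="full", n_init=10, reg_covar=1e-6,
                    random_state=seed,
                ).fit(X[tr])
                ll = gm.score(X[te]) * len(te)
                vals.append(-2 * ll + _gmm_n_params(4, k) * np.log(len(te)))
            m = np.mean(vals)
            if m < best[0]:
                best = (m, k)
        k_sel, _, _ = v.fit_gmm(X, krange=range(1, 5), folds=folds, seed=seed)
        assert k_sel == best[1]


@pytest.fixture(scope="module")
def fitted(cohort):
    model, report = v.cluster_cells(cohort, seed=0)
    return model, report


class TestEndToEnd:
    def test_weights_sum_and_loadings_orthonormal(self, fitted):
        model, _ = fitted
        assert model.weights.sum() == pytest.approx(1.0)
        eye = model.loadings.T @ model.loadings
        assert np.allclose(eye, np.eye(model.n_pcs), atol=1e-8)
        assert set(model.labels.unique()) <= set(range(1, model.n_components + 1))

    def test_labels_invariant_to_feature_and_cell_permutation(self, cohort, fitted):
        model, _ = fitted
        rng = np.random.default_rng(0)
        df = cohort.values
        shuffled = df.iloc[rng.permutation(len(df)), rng.permutation(df.shape[1])]
        model2, _ = v.cluster_cells(
            v.FeatureMatrix(values=shuffled), seed=0, n_pcs=model.n_pcs
        )
        common = model.labels.index.intersection(model2.labels.index)
        assert adjusted_rand_score(model.labels[common], model2.labels[common]) == 1.0

    def test_mixture_weights_recover_cohort_proportions(self, fitted):
        model, _ = fitted
        target = np.sort(np.array([215, 92, 85]) / 392.0)[::-1]
        got = np.sort(model.weights)[::-1]
        assert np.all(np.abs(got - target) < 0.05)

    def test_naming_matches_generator_subtypes(self, cohort, fitted):
        model, _ = fitted
        names = v.name_clusters(model, cohort)
        named = model.labels.map(names)
        truth = cohort.true_labels.loc[named.index]
        agreement = (named == truth).mean()
        assert agreement > 0.95

    def test_roundtrip_serialization(self, fitted, tmp_path):
        model, _ = fitted
        model.save(tmp_path / "model.json")
        back = v.ClusterModel.load(tmp_path / "model.json")
        assert back.n_pcs == model.n_pcs
        assert np.allclose(back.means, model.means)
        assert (back.labels.to_numpy() == model.labels.to_numpy()).all()

    def test_frozen_assignment_of_new_cells(self, cohort, fitted):
        model, report = fitted
        names = v.name_clusters(model, cohort)
        adult = v.synth_feature_table(seed=99)
        labels = v.assign_new_cells(model, report, adult)
        named = labels.map(names)
        truth = adult.true_labels
        assert (named == truth).mean() >= 0.90

    def test_new_cell_at_component_mean_joins_that_component(self, cohort, fitted):
        model, report = fitted
        # invert the frozen transform at a component mean in PC space
        scaled_point = model.pca_mean + model.loadings @ model.means[0]
        row = scaled_point * report.feature_range + report.feature_min
        df = pd.DataFrame([row], columns=report.feature_min.index, index=["probe"])
        for col, kind in report.log_transformed.items():
            df[col] = np.expm1(df[col]) if kind == "log1p" else np.exp(df[col])
        labels = v.assign_new_cells(model, report, df)
        assert labels["probe"] == 1

    def test_feature_mismatch_is_schema_error(self, fitted):
        model, report = fitted
        with pytest.raises(ValueError, match="missing features"):
            v.assign_new_cells(model, report, pd.DataFrame({"rmp": [1.0]}))

    def test_generic_names_when_k_is_not_three(self, cohort):
        model, _ = v.cluster_cells(cohort, seed=0, n_pcs=2, krange_gmm=[2])
        names = v.name_clusters(model, cohort)
        assert set(names.values()) == {"cluster_1", "cluster_2"}


def test_joint_refit_keeps_three_clusters(cohort):
    """Pooling a second (adult) synthetic cohort and re-clustering yields
    the same three subtypes."""
    model, report = v.cluster_cells(cohort, seed=1)
    adult = v.synth_feature_table(
        specs=[
            type(s)(s.name, 31, s.features, s.template)
            for s in v.default_cohort()
        ],
        seed=123,
    )
    adult.values.index = [f"adult_{i}" for i in range(len(adult.values))]
    joint = v.assign_new_cells(
        model, report, adult, mode="joint", original_features=cohort
    )
    assert joint.nunique() == 3
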