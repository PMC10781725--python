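import numpy as np
import pytest

from psymeta import (
    PredictionConfig,
    SimulationConfig,
    generate_expression_study,
    loso_cv,
    make_ground_truth,
    standardize_per_gene,
    top_features,
)


def quick_cfg(model="elastic_net", seed=0):
    # trimmed grids keep the nested search fast; layout unchanged
    return PredictionConfig(
        model=model,
        alpha_grid=[0.0, 0.5, 1.0],
        lambda_grid=[1e-3, 1e-2, 1e-1],
        ntree_grid=[100],
        mtry_grid=["sqrt"],
        inner_folds=3,
        seed=seed,
    )


def separable_scenario(effect=4.0, seed=3, n_studies=5, n_genes=30, n_deg=10):
    cfg = SimulationConfig(
        n_genes=n_genes, n_studies_a=n_studies, n_studies_b=n_studies,
        n_shared_deg=n_deg, n_private_deg_a=0, n_private_deg_b=0,
        samples_per_arm=8, effect_size=effect, noise_sd=1.0, seed=seed,
    )
    truth = make_ground_truth(cfg)
    studies = [generate_expression_study(cfg, "B", i, truth)[0] for i in range(n_studies)]
    return cfg, truth, studies


class TestStandardize:
    def test_three_value_arithmetic(self):
        _, truth, studies = separable_scenario(n_studies=3)
        sub = studies[0]
        gene = truth.genes[0]
        X, y, sids, names = standardize_per_gene([sub], [gene])
        vals = sub.values.loc[gene].to_numpy()
        expected = (vals - vals.mean()) / vals.std(ddof=1)
        np.testing.assert_allclose(X[:, 0], expected, atol=1e-12)

    def test_per_study_moments_exact(self):
        _, truth, studies = separable_scenario()
        genes = truth.shared_genes
        X, y, sids, _ = standardize_per_gene(studies, genes)
        for sid in np.unique(sids):
            block = X[sids == sid]
            np.testing.assert_allclose(block.mean(axis=0), 0, atol=1e-10)
            np.testing.assert_allclose(block.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_standardization_is_idempotent(self):
        _, truth, studies = separable_scenario(n_studies=3)
        genes = truth.shared_genes[:3]
        X1, *_ = standardize_per_gene(studies, genes)
        std_studies = []
        for s in studies:
            s2 = s
            vals = s.values.loc[genes]
            z = vals.sub(vals.mean(axis=1), axis=0).div(vals.std(axis=1, ddof=1), axis=0)
            s2 = type(s)(study_id=s.study_id, values=z, groups=s.groups, transform="normalized")
            std_studies.append(s2)
        X2, *_ = standardize_per_gene(std_studies, genes)
        np.testing.assert_allclose(X1, X2, atol=1e-10)

    def test_missing_gene_rejected(self):
        _, truth, studies = separable_scenario(n_studies=3)
        with pytest.raises(ValueError, match="missing"):
            standardize_per_gene(studies, ["NOT_A_GENE"])

    def test_zero_variance_gene_becomes_zero_column(self):
        _, truth, studies = separable_scenario(n_studies=3)
        s = studies[0]
        s.values.iloc[0, :] = 5.0
        X, *_ = standardize_per_gene([s], [truth.genes[0]])
        np.testing.assert_array_equal(X[:, 0], 0.0)


class TestLosoCV:
    @pytest.mark.parametrize("model", ["elastic_net", "random_forest"])
    def test_separable_scenario_perfect_accuracy(self, model):
        _, truth, studies = separable_scenario(effect=4.0)
        X, y, sids, names = standardize_per_gene(studies, truth.shared_genes)
        report = loso_cv(X, y, sids, quick_cfg(model), feature_names=names)
        assert len(report.accuracies) == 5
        assert report.mean_accuracy == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        _, truth, studies = separable_scenario(effect=4.0)
        X, y, sids, _ = standardize_per_gene(studies, truth.shared_genes)
        rng = np.random.default_rng(12)
        y_perm = y.copy()
        for sid in np.unique(sids):
            idx = np.where(sids == sid)[0]
            y_perm[idx] = rng.permutation(y_perm[idx])
        report = loso_cv(X, y_perm, sids, quick_cfg())
        assert report.mean_accuracy == pytest.approx(0.5, abs=0.1)

    def test_deterministic_given_seed(self):
        _, truth, studies = separable_scenario(effect=1.0)
        X, y, sids, _ = standardize_per_gene(studies, truth.shared_genes)
        r1 = loso_cv(X, y, sids, quick_cfg(seed=5))
        r2 = loso_cv(X, y, sids, quick_cfg(seed=5))
        assert r1.accuracies == r2.accuracies
        np.testing.assert_array_equal(r1.feature_scores, r2.feature_scores)

    def test_no_leakage_held_out_perturbation_cannot_change_training(self):
        # per-study standardization: corrupting one study's raw values must
        # leave every other study's standardized block bit-identical
        _, truth, studies = separable_scenario(n_studies=3)
        genes = truth.shared_genes
        X_ref, _, sids, _ = standardize_per_gene(studies, genes)
        studies[0].values.iloc[:, :] = studies[0].values.to_numpy() * 100 + 7
        X_new, _, sids2, _ = standardize_per_gene(studies, genes)
        held_out = studies[0].study_id
        np.testing.assert_array_equal(X_ref[sids != held_out], X_new[sids2 != held_out])

    def test_too_few_studies_rejected(self):
        _, truth, studies = separable_scenario(n_studies=3)
        X, y, sids, _ = standardize_per_gene(studies[:2], truth.shared_genes)
        with pytest.raises(ValueError, match=">= 3"):
            loso_cv(X, y, sids, quick_cfg())


class TestTopFeatures:
    def test_planted_genes_dominate_rankings(self):
        cfg, truth, studies = separable_scenario(effect=4.0, n_genes=40, n_deg=3)
        feature_genes = truth.shared_genes + [g for g in truth.genes if g not in set(truth.shared_genes)][:17]
        X, y, sids, names = standardize_per_gene(studies, feature_genes)
        for model in ("elastic_net", "random_forest"):
            report = loso_cv(X, y, sids, quick_cfg(model), feature_names=names)
            top = top_features(report, 10)
            assert set(truth.shared_genes) <= set(top)

    def test_k_zero_gives_empty_list(self):
        _, truth, studies = separable_scenario(n_studies=3)
        X, y, sids, names = standardize_per_gene(studies, truth.shared_genes)
        report = loso_cv(X, y, sids, quick_cfg())
        assert top_features(report, 0) == []


class TestConfigValidation:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            PredictionConfig(model="svm")
        with pytest.raises(ValueError):
            PredictionConfig(alpha_grid=[1.5])
        with pytest.raises(ValueError):
            PredictionConfig(lambda_grid=[0.0])
        with pytest.raises(ValueError):
            PredictionConfig(ntree_grid=[10])
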