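"""Standardization, correlation PCA, LDA and the assembled predictor."""

import numpy as np
import pytest

from trailstrat import (
    CoverageError,
    DegenerateError,
    ExpressionPanel,
    PredictorResults,
    ResponsePredictor,
    ResponseTable,
    RunConfig,
    apply_standardization,
    fit_lda,
    fit_pca,
    project,
    standardize,
    train_predictor,
    variance_explained,
)


class TestStandardize:
    def test_simple_column(self):
        panel = ExpressionPanel(("a", "b", "c"), ("x", "y"), [[1, 10], [2, 20], [3, 30]])
        z, params = standardize(panel)
        np.testing.assert_allclose(z[:, 0], [-1, 0, 1], atol=1e-12)
        assert params.means[0] == 2 and params.sds[0] == 1

    def test_constant_column_rejected(self):
        panel = ExpressionPanel(("a", "b", "c"), ("x", "y"), [[5, 1], [5, 2], [5, 3]])
        with pytest.raises(DegenerateError, match="x"):
            standardize(panel)

    def test_columns_have_zero_mean_unit_sd(self, random_panel):
        z, _ = standardize(random_panel(12, 7, seed=2))
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_apply_uses_training_parameters_only(self, random_panel):
        panel = random_panel(8, 4, seed=3)
        z, params = standardize(panel)
        # the training means map to the origin
        np.testing.assert_allclose(
            apply_standardization(params.means, params), 0, atol=1e-12
        )
        # re-applying to a training row reproduces its z-row
        np.testing.assert_allclose(
            apply_standardization(panel.values[2], params), z[2], atol=1e-12
        )

    def test_missing_protein_is_coverage_error(self, random_panel):
        _, params = standardize(random_panel(5, 3, seed=1))
        with pytest.raises(CoverageError, match="prot2"):
            apply_standardization({"prot0": 1.0, "prot1": 2.0}, params)


def _oracle_pca(z):
    """Brute force: eigendecomposition of the explicitly formed correlation matrix."""
    n = z.shape[0]
    corr = z.T @ z / (n - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    return np.clip(w[order], 0, None), v[:, order]


class TestPCA:
    def test_rank_one_correlation(self):
        x = np.array([-1.0, 0.0, 1.0])
        z = np.column_stack([x, 2 * x]) / x.std(ddof=1) / np.array([1, 2])
        model = fit_pca(z)
        np.testing.assert_allclose(model.eigenvalues, [2, 0], atol=1e-12)
        assert model.n_retained == 1

    def test_trace_identity(self, random_panel):
        for seed in range(5):
            z, _ = standardize(random_panel(9, 6, seed=seed))
            model = fit_pca(z)
            assert model.eigenvalues.sum() == pytest.approx(6, abs=1e-8)

    def test_matches_dense_eigensolver_oracle(self, random_panel):
        z, _ = standardize(random_panel(8, 5, seed=42))
        model = fit_pca(z)
        w, v = _oracle_pca(z)
        np.testing.assert_allclose(model.eigenvalues, w, atol=1e-8)
        for j in range(5):
            if w[j] < 1e-8:
                continue
            a, b = model.loadings[:, j], v[:, j]
            sign = np.sign(a @ b)
            np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_kaiser_rule_and_cap(self, random_panel):
        z, _ = standardize(random_panel(30, 10, seed=5))
        model = fit_pca(z, RunConfig(n_pcs_max=2))
        assert model.n_retained == 2
        free = fit_pca(z, RunConfig(n_pcs_max=10))
        assert free.n_retained == int(np.sum(free.eigenvalues > 1))

    def test_no_component_clears_threshold_falls_back_to_one(self, random_panel):
        z, _ = standardize(random_panel(50, 3, seed=6))
        with pytest.warns(UserWarning, match="Kaiser"):
            model = fit_pca(z, RunConfig(kaiser_threshold=100.0))
        assert model.n_retained == 1

    def test_sign_convention(self, random_panel):
        z, _ = standardize(random_panel(10, 6, seed=8))
        model = fit_pca(z)
        for j in range(model.loadings.shape[1]):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_variance_explained_fractions(self):
        from trailstrat.predictor import PCAModel

        model = PCAModel(("a", "b", "c", "d"), np.eye(4), [2.0, 1.0, 1.0, 0.0], 2)
        table = variance_explained(model)
        np.testing.assert_allclose(table["fraction"], [0.5, 0.25, 0.25, 0.0])
        np.testing.assert_allclose(table["cumulative"], [0.5, 0.75, 1.0, 1.0])

    def test_projection_matches_loop_oracle(self, random_panel):
        z, _ = standardize(random_panel(7, 4, seed=9))
        model = fit_pca(z)
        vec = np.array([0.3, -1.2, 0.0, 2.0])
        coords = project(vec, model)
        oracle = [sum(vec[i] * model.loadings[i, j] for i in range(4))
                  for j in range(model.n_retained)]
        np.testing.assert_allclose(coords, oracle, atol=1e-12)
        np.testing.assert_allclose(project(np.zeros(4), model), 0, atol=1e-15)


def _labels(ids, n_syn):
    return ResponseTable(tuple(ids), ("synergistic",) * n_syn + ("low",) * (len(ids) - n_syn))


class TestLDA:
    def test_one_dimensional_midpoint_rule(self):
        """Equal priors, symmetric 1-D classes: boundary exactly at the midpoint."""
        scores = np.array([[-1.2], [-0.8], [0.8], [1.2]])
        labels = ResponseTable(("a", "b", "c", "d"), ("low", "low", "synergistic", "synergistic"))
        model = fit_lda(scores, labels, RunConfig(lda_priors="equal"))
        assert model.discriminant(np.array([0.0])) == pytest.approx(0.0, abs=1e-12)
        assert model.posterior_synergistic(np.array([0.5])) > 0.5

    def test_label_swap_mirrors_discriminant(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(10, 2))
        ids = tuple(f"s{i}" for i in range(10))
        fwd = fit_lda(scores, _labels(ids, 5), RunConfig(lda_priors="equal"))
        swapped = ResponseTable(ids, tuple("low" if l == "synergistic" else "synergistic"
                                           for l in _labels(ids, 5).labels))
        bwd = fit_lda(scores, swapped, RunConfig(lda_priors="equal"))
        np.testing.assert_allclose(fwd.weights, -bwd.weights, atol=1e-10)
        np.testing.assert_allclose(fwd.offset, -bwd.offset, atol=1e-10)

    def test_separable_clusters_train_perfectly(self):
        rng = np.random.default_rng(11)
        scores = np.vstack([rng.normal(5, 0.2, (8, 2)), rng.normal(-5, 0.2, (8, 2))])
        ids = tuple(f"s{i}" for i in range(16))
        labels = _labels(ids, 8)
        model = fit_lda(scores, labels)
        post = model.posterior_synergistic(scores)
        assert np.all(post[:8] > 0.5) and np.all(post[8:] < 0.5)

    def test_singular_covariance_gets_ridge(self):
        scores = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        labels = _labels(("a", "b", "c", "d"), 2)
        with pytest.warns(UserWarning, match="ridge"):
            model = fit_lda(scores, labels)
        assert model.ridge > 0
        assert np.all(np.isfinite(model.weights))

    def test_single_class_rejected(self):
        scores = np.zeros((3, 1))
        labels = ResponseTable(("a", "b", "c"), ("low", "low", "low"))
        with pytest.raises(DegenerateError):
            fit_lda(scores, labels)

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check: posteriors match sklearn's LDA."""
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(21)
        scores = np.vstack([rng.normal(1.0, 1.0, (12, 3)), rng.normal(-1.0, 1.0, (8, 3))])
        ids = tuple(f"s{i}" for i in range(20))
        labels = _labels(ids, 12)
        ours = fit_lda(scores, labels, RunConfig(lda_priors="empirical"))
        ref = sklearn_lda.LinearDiscriminantAnalysis(solver="svd")
        ref.fit(scores, [1] * 12 + [0] * 8)
        np.testing.assert_allclose(
            ours.posterior_synergistic(scores), ref.predict_proba(scores)[:, 1], atol=1e-8
        )


class TestPredictor:
    def test_composition_consistency(self, default_panel):
        """Training scores equal project(apply_standardization(row)) per row."""
        panel, labels = default_panel
        results = train_predictor(panel, labels)
        ordered = panel.subset(results.proteins)
        for i, sid in enumerate(ordered.sample_ids):
            np.testing.assert_allclose(
                results.transform(ordered.values[i]), results.training_scores[i], atol=1e-12
            )

    def test_sample_at_synergistic_mean_classified_synergistic(self, strong_panel):
        panel, labels = strong_panel
        results = train_predictor(panel, labels)
        mask = np.array([l == "synergistic" for l in labels.aligned_to(panel).labels])
        mean_profile = panel.subset(results.proteins).values[mask].mean(axis=0)
        pred = results.predict(mean_profile)
        assert pred.label == "synergistic" and pred.posterior > 0.5

    def test_strongly_separated_panel_trains_perfectly(self, strong_panel):
        panel, labels = strong_panel
        assert train_predictor(panel, labels).training_accuracy() == 1.0

    def test_tie_resolved_by_policy(self, default_panel):
        panel, labels = default_panel
        low_tie = train_predictor(panel, labels, RunConfig(tie_policy="low"))
        assert low_tie._label_from_posterior(0.5) == "low"
        syn_tie = train_predictor(panel, labels, RunConfig(tie_policy="synergistic"))
        assert syn_tie._label_from_posterior(0.5) == "synergistic"

    def test_prediction_invariant_to_column_order(self, default_panel):
        panel, labels = default_panel
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_proteins)
        shuffled = ExpressionPanel(
            panel.sample_ids,
            tuple(panel.protein_ids[j] for j in perm),
            panel.values[:, perm],
        )
        a = train_predictor(panel, labels)
        b = train_predictor(shuffled, labels)
        assert a.to_json() == b.to_json()

    def test_serialization_round_trip(self, default_panel):
        panel, labels = default_panel
        results = train_predictor(panel, labels)
        clone = PredictorResults.from_json(results.to_json())
        assert clone.to_json() == results.to_json()
        rng = np.random.default_rng(5)
        for _ in range(20):
            profile = rng.lognormal(2, 1, size=len(results.proteins))
            a = results.predict(profile)
            b = clone.predict(profile)
            assert a.label == b.label and a.posterior == b.posterior

    def test_save_load(self, tmp_path, default_panel):
        panel, labels = default_panel
        results = train_predictor(panel, labels)
        results.save(tmp_path / "model.json")
        loaded = PredictorResults.load(tmp_path / "model.json")
        assert loaded.to_json() == results.to_json()

    def test_null_panel_training_accuracy_near_chance(self):
        """With zero class effect, separation hovers near the majority rate."""
        from trailstrat import PanelSpec, gen_panel

        accs = []
        for seed in range(30):
            panel, labels = gen_panel(PanelSpec(effect_size=0.0, seed=seed))
            accs.append(train_predictor(panel, labels).training_accuracy())
        # in-sample separation of 16 noise samples in 6 PCs is optimistic but
        # must stay clearly below perfect on average
        assert 0.6 < np.mean(accs) < 1.0

    def test_summary_mentions_key_facts(self, default_panel):
        panel, labels = default_panel
        text = train_predictor(panel, labels).summary()
        assert "retained" in text and "training separation accuracy" in text

    def test_missing_protein_coverage_error(self, default_panel):
        panel, labels = default_panel
        results = train_predictor(panel, labels)
        with pytest.raises(CoverageError):
            results.predict({"XIAP": 1.0})
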