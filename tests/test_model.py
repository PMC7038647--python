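"""Attention model: operation-level oracles, gradients, training behaviour."""

import dataclasses

import numpy as np
import pytest

import deeptriage as dt
from deeptriage.model import (
    EmbeddingMatrix,
    ModelConfig,
    TriageModel,
    _init_params,
    attention_scores,
    build_embedding,
    embed_sample,
    forward,
    loss_and_grads,
    predict_proba,
    represent_sample,
)


def _bare_model(d=8, m=4, p=3, alpha_hidden=3, y_hidden=3, seed=0, emb_seed=1) -> TriageModel:
    """Untrained model with random parameters, identity input scaling."""
    cfg = ModelConfig(m=m, p=p, alpha_hidden=alpha_hidden, y_hidden=y_hidden,
                      dropout_rate=0.0, input_scaling="none", seed=seed)
    rng = np.random.default_rng(seed)
    return TriageModel(
        embedding=build_embedding(d, m, emb_seed),
        params=_init_params(d, cfg, rng),
        bn_mean=rng.normal(size=y_hidden) * 0.1,
        bn_var=np.abs(rng.normal(size=y_hidden)) + 0.5,
        config=cfg,
    )


class TestEmbedding:
    def test_seeded_determinism_and_shape(self):
        a = build_embedding(5, 3, seed=11)
        b = build_embedding(5, 3, seed=11)
        np.testing.assert_array_equal(a.E, b.E)
        assert a.E.shape == (5, 3)
        assert not np.allclose(a.E, build_embedding(5, 3, seed=12).E)

    def test_moments_match_configured_distribution(self):
        # entries are N(0, 1/m): check mean and variance within 3 SE
        d, m = 10000, 8
        E = build_embedding(d, m, seed=0).E
        n = d * m
        se_mean = (1 / np.sqrt(m)) / np.sqrt(n)
        assert abs(E.mean()) < 3 * se_mean
        var = E.var()
        se_var = (1 / m) * np.sqrt(2 / n)
        assert abs(var - 1 / m) < 3 * se_var

    def test_invalid_dims_error(self):
        with pytest.raises(ValueError):
            build_embedding(0, 3, 0)
        with pytest.raises(ValueError):
            build_embedding(3, -1, 0)


class TestEmbedSample:
    def test_zero_value_gives_zero_row(self):
        E = build_embedding(4, 3, 0)
        x = np.array([1.0, 0.0, 2.0, 3.0])
        out = embed_sample(x, E)
        np.testing.assert_array_equal(out[1], np.zeros(3))

    def test_multiplicative_interaction(self):
        E = EmbeddingMatrix(E=np.array([[0.5, -1.0]]), seed=0, distribution="fixed")
        out = embed_sample(np.array([2.0]), E)
        np.testing.assert_allclose(out, [[1.0, -2.0]])

    def test_linearity(self):
        E = build_embedding(6, 4, 2)
        x = np.random.default_rng(0).random(6)
        np.testing.assert_allclose(embed_sample(2 * x, E), 2 * embed_sample(x, E), rtol=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="rows"):
            embed_sample(np.ones(3), build_embedding(4, 2, 0))


class TestAttentionScores:
    def test_singleton_softmax_is_one(self):
        model = _bare_model(d=1)
        att = attention_scores(embed_sample(np.array([2.0]), model.embedding), model)
        np.testing.assert_allclose(att.beta, [1.0])

    def test_identical_rows_give_uniform_beta(self):
        model = _bare_model(d=5)
        embedded = np.tile(np.random.default_rng(1).random(model.config.m), (5, 1))
        att = attention_scores(embedded, model)
        np.testing.assert_allclose(att.beta, np.full(5, 0.2), rtol=1e-12)

    def test_softmax_analytic_values(self):
        from deeptriage.model import _softmax

        np.testing.assert_allclose(_softmax(np.log([1.0, 3.0])), [0.25, 0.75], rtol=1e-12)

    def test_non_finite_embedded_errors(self):
        model = _bare_model()
        bad = np.full((8, 4), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            attention_scores(bad, model)


class TestRepresentSample:
    def test_one_hot_beta_selects_single_feature(self):
        model = _bare_model()
        emb = embed_sample(np.random.default_rng(2).random(8), model.embedding)
        beta = np.zeros(8)
        beta[3] = 1.0
        out = represent_sample(emb, beta, model)
        expected = np.tanh(emb[3] @ model.params["Wx"] + model.params["bx"])
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_bruteforce_weighted_sum(self):
        model = _bare_model(d=7)
        rng = np.random.default_rng(3)
        emb = embed_sample(rng.random(7), model.embedding)
        beta = rng.dirichlet(np.ones(7))
        out = represent_sample(emb, beta, model)
        acc = np.zeros(model.config.p)
        for i in range(7):
            acc += beta[i] * np.tanh(emb[i] @ model.params["Wx"] + model.params["bx"])
        np.testing.assert_allclose(out, acc, atol=1e-6)

    def test_boundedness(self):
        model = _bare_model(d=30)
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.random(30) * 100
            emb = embed_sample(x, model.embedding)
            beta = attention_scores(emb, model).beta
            out = represent_sample(emb, beta, model)
            assert np.all(np.abs(out) < 1.0)


class TestPredictProba:
    def test_output_in_open_unit_interval(self):
        model = _bare_model()
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = predict_proba(rng.normal(size=model.config.p), model)
            assert 0.0 < p < 1.0

    def test_zeroed_head_gives_half(self):
        model = _bare_model()
        model.params["wy2"][:] = 0.0
        model.params["by2"][:] = 0.0
        assert predict_proba(np.random.default_rng(6).normal(size=3), model) == pytest.approx(0.5)

    def test_closed_form_sigmoid_of_logit(self):
        model = _bare_model()
        x_bar = np.random.default_rng(7).normal(size=model.config.p)
        P = model.params
        z = x_bar @ P["Wy1"] + P["by1"]
        zn = (z - model.bn_mean) / np.sqrt(model.bn_var + 1e-5)
        h = np.maximum(P["gamma"] * zn + P["delta"], 0.0)
        logit = h @ P["wy2"] + P["by2"][0]
        assert predict_proba(x_bar, model) == pytest.approx(1 / (1 + np.exp(-logit)), abs=1e-6)

    def test_non_finite_input_errors(self):
        with pytest.raises(ValueError, match="non-finite"):
            predict_proba(np.array([np.inf, 0.0, 0.0]), _bare_model())


class TestForward:
    def test_composition_equals_sequential_ops(self):
        model = _bare_model()
        x = np.random.default_rng(8).random(8)
        prob, att = forward(x, model, scale=False)
        emb = embed_sample(x, model.embedding)
        att2 = attention_scores(emb, model)
        np.testing.assert_allclose(att.beta, att2.beta, rtol=1e-12)
        assert prob == pytest.approx(
            predict_proba(represent_sample(emb, att2.beta, model), model), abs=1e-12
        )

    def test_feature_permutation_equivariance(self):
        model = _bare_model(d=12)
        rng = np.random.default_rng(9)
        x = rng.random(12)
        perm = rng.permutation(12)
        prob, att = forward(x, model, scale=False)
        perm_model = dataclasses.replace(
            model,
            embedding=EmbeddingMatrix(model.embedding.E[perm], model.embedding.seed, "permuted"),
        )
        prob_p, att_p = forward(x[perm], perm_model, scale=False)
        np.testing.assert_allclose(att_p.beta, att.beta[perm], atol=1e-6)
        assert prob_p == pytest.approx(prob, abs=1e-6)

    def test_batch_of_one_matches_batch_of_many(self):
        from deeptriage.model import _forward_batch

        model = _bare_model(d=10)
        rng = np.random.default_rng(10)
        X = rng.random((5, 10))
        out_batch = _forward_batch(X, model.params, model.embedding.E, training=False,
                                   bn_mean=model.bn_mean, bn_var=model.bn_var)
        for j in range(5):
            prob, att = forward(X[j], model, scale=False)
            assert prob == pytest.approx(out_batch["prob"][j], abs=1e-6)
            np.testing.assert_allclose(att.beta, out_batch["beta"][j], atol=1e-6)

    def test_zero_expression_gives_constant_alpha(self):
        # x_ji = 0 embeds to the zero vector, so alpha_ji = f_alpha(0)
        model = _bare_model(d=6)
        P = model.params
        f_alpha_zero = np.tanh(np.zeros(model.config.m) @ P["Wa1"] + P["ba1"]) @ P["wa2"] + P["ba2"][0]
        rng = np.random.default_rng(11)
        for _ in range(3):
            x = rng.random(6)
            x[2] = 0.0
            _, att = forward(x, model, scale=False)
            assert att.alpha[2] == pytest.approx(f_alpha_zero, abs=1e-12)


class TestGradients:
    def test_analytic_matches_central_differences(self):
        # d=20, m=4, p=2 instance; every parameter checked
        d, n = 20, 6
        cfg = ModelConfig(m=4, p=2, alpha_hidden=3, y_hidden=3, dropout_rate=0.0)
        rng = np.random.default_rng(0)
        params = _init_params(d, cfg, rng)
        E = build_embedding(d, cfg.m, 3).E
        X = rng.random((n, d))
        y = rng.integers(0, 2, n).astype(float)
        _, grads = loss_and_grads(params, E, X, y)
        h = 1e-5
        for k, v in params.items():
            it = np.nditer(v, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = v[idx]
                v[idx] = orig + h
                lp, _ = loss_and_grads(params, E, X, y)
                v[idx] = orig - h
                lm, _ = loss_and_grads(params, E, X, y)
                v[idx] = orig
                num = (lp - lm) / (2 * h)
                ana = grads[k][idx]
                assert abs(num - ana) <= 1e-4 * max(1e-6, abs(num), abs(ana)), (
                    f"gradient mismatch for {k}{idx}: analytic={ana}, numeric={num}"
                )


def _small_separable(n_per_class=40, d=30, seed=0):
    cfg = dt.SyntheticConfig(
        n_per_class=n_per_class, n_features=d, n_planted=5, effect_size=2.5,
        subgroup_fraction=0.0, gradient_features=0, seed=seed,
    )
    cohort = dt.generate_cohort(cfg, with_gene_sets=False)
    return cohort.counts, cohort.labels


_SMALL_CFG = dict(m=16, p=8, alpha_hidden=8, y_hidden=4, epochs=30, batch_size=16)


class TestFit:
    def test_loss_decreases_over_first_epochs(self):
        counts, y = _small_separable()
        model = dt.fit(counts, y, ModelConfig(seed=1, **_SMALL_CFG))
        log = model.training_log
        # separable data: clear downward trend over the first five epochs
        assert log[4] < log[0]
        assert min(log[:5]) == min(log[:5])  # log recorded per epoch
        assert len(log) == 30

    def test_same_seed_identical_parameters(self):
        counts, y = _small_separable()
        cfg = ModelConfig(seed=2, **{**_SMALL_CFG, "epochs": 5})
        m1 = dt.fit(counts, y, cfg)
        m2 = dt.fit(counts, y, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])
        np.testing.assert_array_equal(m1.bn_mean, m2.bn_mean)
        assert m1.training_log == m2.training_log

    def test_label_flip_auc_symmetry(self):
        from sklearn.metrics import roc_auc_score

        counts, y = _small_separable()
        cfg = ModelConfig(seed=3, **{**_SMALL_CFG, "m": 32, "epochs": 60})
        auc = roc_auc_score(y, dt.predict(dt.fit(counts, y, cfg), counts))
        auc_flip = roc_auc_score(1 - y, dt.predict(dt.fit(counts, 1 - y, cfg), counts))
        assert auc > 0.9 and auc_flip > 0.9
        assert abs(auc - auc_flip) < 0.1

    def test_single_class_labels_error(self):
        counts, y = _small_separable()
        with pytest.raises(ValueError, match="class"):
            dt.fit(counts, np.ones_like(y), ModelConfig(**_SMALL_CFG))

    def test_non_binary_labels_error(self):
        counts, y = _small_separable()
        bad = y.astype(float).copy()
        bad[0] = 2.0
        with pytest.raises(ValueError, match="binary"):
            dt.fit(counts, bad, ModelConfig(**_SMALL_CFG))


class TestScoreImportance:
    def test_rows_sum_to_one_and_positive(self):
        counts, y = _small_separable()
        model = dt.fit(counts, y, ModelConfig(seed=4, **{**_SMALL_CFG, "epochs": 10}))
        imp = dt.score_importance(model, counts)
        assert imp.B.shape == (counts.n_samples, counts.n_features)
        np.testing.assert_allclose(imp.B.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(imp.B > 0)

    def test_feature_mismatch_lists_discrepancy(self):
        counts, y = _small_separable()
        model = dt.fit(counts, y, ModelConfig(seed=4, **{**_SMALL_CFG, "epochs": 3}))
        other = dt.ExpressionMatrix(
            counts.sample_ids, [f"other{i}" for i in range(counts.n_features)], counts.values
        )
        with pytest.raises(ValueError, match="feature mismatch"):
            dt.score_importance(model, other)


class TestSerialisation:
    def test_round_trip_reproduces_outputs(self, tmp_path):
        counts, y = _small_separable()
        model = dt.fit(counts, y, ModelConfig(seed=5, **{**_SMALL_CFG, "epochs": 5}))
        path = tmp_path / "model.npz"
        dt.save_model(model, path)
        loaded = dt.load_model(path)
        np.testing.assert_array_equal(dt.predict(model, counts), dt.predict(loaded, counts))
        np.testing.assert_array_equal(
            dt.score_importance(model, counts).B, dt.score_importance(loaded, counts).B
        )
        assert loaded.config == model.config
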