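"""Model contracts: attention pooling, Noisy-OR, instances, training."""

import numpy as np
import pytest

from geotx import nn
from geotx.nn import Tensor
from geotx.evaluate import MetricReport, average_precision_stepwise, evaluate
from geotx.models import (
    ModelConfig,
    attention_pool,
    build_model,
    cross_validate,
    make_instances,
    noisy_or,
    permutation_importance,
    train,
)


def _rand_params(d, hidden, seed=0):
    rng = np.random.default_rng(seed)
    return {"V": rng.normal(size=(d, hidden)),
            "U": rng.normal(size=(d, hidden)),
            "w": rng.normal(size=(hidden, 1))}


class TestAttentionPool:
    def test_identical_members_uniform_weights(self):
        h = np.tile(np.arange(6.0), (4, 1))
        pooled, w = attention_pool(h, _rand_params(6, 3))
        assert np.allclose(w, 0.25)
        assert np.allclose(pooled, h[0])
        assert w.sum() == pytest.approx(1.0)

    def test_singleton_bag(self):
        h = np.random.default_rng(1).normal(size=(1, 5))
        _, w = attention_pool(h, _rand_params(5, 3))
        assert w.tolist() == [1.0]

    def test_layer_matches_formula_oracle(self):
        rng = np.random.default_rng(2)
        layer = nn.GatedAttention(8, 5, np.random.default_rng(3))
        h = rng.normal(size=(6, 8))
        pooled_t, w_t = layer(Tensor(h))
        params = {"V": layer.V.data, "U": layer.U.data, "w": layer.w.data}
        # independent evaluation of the gated-attention formula
        query = np.tanh(h @ params["V"]) / (1 + np.exp(-(h @ params["U"])))
        scores = (query @ params["w"]).reshape(-1)
        weights = np.exp(scores - scores.max())
        weights /= weights.sum()
        pooled = weights @ h
        assert np.allclose(pooled_t.data.reshape(-1), pooled)
        assert np.allclose(w_t.data.reshape(-1), weights)
        pooled_f, w_f = attention_pool(h, params)
        assert np.allclose(pooled_f, pooled) and np.allclose(w_f, weights)

    def test_masked_member_has_no_influence(self):
        rng = np.random.default_rng(4)
        h = rng.normal(size=(5, 7))
        params = _rand_params(7, 4, seed=5)
        pooled_full, w_full = attention_pool(
            h, params, mask=[True, True, True, True, False]
        )
        pooled_drop, _ = attention_pool(h[:4], params)
        assert w_full[4] == 0.0
        assert np.max(np.abs(pooled_full - pooled_drop)) < 1e-6


class TestNoisyOr:
    @pytest.mark.parametrize("probs,expected", [
        ([0, 0, 0], 0.0),
        ([1.0, 0.2], 1.0),
        ([0.5, 0.5], 0.75),
    ])
    def test_closed_forms(self, probs, expected):
        assert noisy_or(probs) == pytest.approx(expected)

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(6)
            assert noisy_or(p) == pytest.approx(noisy_or(rng.permutation(p)))
            bumped = p.copy()
            j = rng.integers(6)
            bumped[j] = min(bumped[j] + 0.1, 1.0)
            assert noisy_or(bumped) >= noisy_or(p) - 1e-12

    def test_mask_excludes_padding(self):
        assert noisy_or([0.5, 0.9], mask=[True, False]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            noisy_or([])
        with pytest.raises(ValueError):
            noisy_or([0.5], mask=[False])

    def test_twenty_reads_at_partial_stoichiometry(self):
        # a perfect read classifier at stoichiometry 0.3 with 20 reads
        assert noisy_or([0.3] * 20) == pytest.approx(1 - 0.7**20)


class TestMakeInstances:
    @pytest.mark.parametrize("L,n", [(50, 1), (100, 6), (120, 8)])
    def test_instance_counts(self, L, n):
        seqs = make_instances("A" * L)
        assert len(seqs) == n
        assert all(len(s) == 50 for s in seqs)

    def test_short_sequence_advises_padding(self):
        with pytest.raises(ValueError, match="pad"):
            make_instances("A" * 49)

    def test_works_on_arrays(self):
        X = np.zeros((100, 4))
        inst = make_instances(X)
        assert len(inst) == 6 and inst[0].shape == (50, 4)


class TestBuildModel:
    def test_geo_cnn_outputs_probability(self):
        m = build_model("geo_cnn", ModelConfig(seed=0))
        p = m.predict({"geo": np.random.default_rng(0).random((3, 35, 7))})
        assert p.shape == (3,) and np.all((p >= 0) & (p <= 1))

    def test_i_gepse_attention_normalized(self):
        m = build_model("i_gepse", ModelConfig(seed=0))
        rng = np.random.default_rng(1)
        bag = {"geo": rng.random((3, 35, 7)), "seq": rng.random((101, 4)),
               "mask": np.ones(3, bool)}
        probs, attn = m.predict({"bags": [bag]}, return_attention=True)
        assert len(attn[0]) == 3
        assert attn[0].sum() == pytest.approx(1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("mystery")

    def test_untrained_model_is_chance_level(self):
        rng = np.random.default_rng(0)
        X = rng.random((1200, 35, 7))
        y = rng.integers(0, 2, 1200)
        aucs = []
        for seed in (0, 1, 2):
            m = build_model("geo_cnn", ModelConfig(seed=seed))
            aucs.append(evaluate(m.predict({"geo": X}), y).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_ti_gepse_contract(self):
        m = build_model("ti_gepse", ModelConfig(seed=0))
        rng = np.random.default_rng(2)
        bag = {"geo": rng.random((2, 35, 7)),
               "instances": rng.random((6, 50, 4)),
               "mask": np.ones(2, bool)}
        probs = m.predict({"bags": [bag]})
        assert 0 <= probs[0] <= 1

    def test_read_gepse_noisy_or_consistency(self):
        m = build_model("read_gepse", ModelConfig(seed=0))
        rng = np.random.default_rng(3)
        bag = {"geo": rng.random((5, 35, 7)), "mask": np.ones(5, bool)}
        p_site, read_probs = m.forward_bag(bag)
        assert p_site.data.item() == pytest.approx(noisy_or(read_probs))
        # masking a read can only lower the site probability
        bag2 = dict(bag, mask=np.array([1, 1, 1, 0, 0], bool))
        p2, rp2 = m.forward_bag(bag2)
        assert p2.data.item() == pytest.approx(noisy_or(rp2, bag2["mask"]))


def _separable_toy(n=160, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0.0, 1.0], n // 2)
    X = np.zeros((n, 35, 7))
    X[y == 1, :, 0] = 1.0
    X += 0.01 * rng.random(X.shape)
    return {"geo": X, "y": y}


class TestTraining:
    def test_separable_toy_reaches_perfect_auc(self):
        data = _separable_toy()
        cfg = ModelConfig(seed=0, epochs=8)
        m = build_model("geo_cnn", cfg)
        res = train(m, data, cfg)
        assert res.loss_history[-1] < res.loss_history[0]
        assert evaluate(m.predict(data), data["y"]).auc == 1.0

    def test_same_seed_reproduces_loss_history(self):
        data = _separable_toy()
        cfg = ModelConfig(seed=3, epochs=3)
        h1 = train(build_model("geo_cnn", cfg), data, cfg).loss_history
        h2 = train(build_model("geo_cnn", cfg), data, cfg).loss_history
        assert h1 == h2

    def test_cross_validate_reports_and_refusals(self):
        data = _separable_toy(n=90)
        cfg = ModelConfig(seed=0, epochs=3)
        result = cross_validate(lambda: build_model("geo_cnn", cfg), data,
                                folds=3)
        assert len(result["folds"]) == 3
        assert set(result["summary"]) == {"accuracy", "f1", "mcc", "auc", "ap"}
        bad = {"geo": data["geo"], "y": np.zeros(90)}
        with pytest.raises(ValueError):
            cross_validate(lambda: build_model("geo_cnn", cfg), bad, folds=3)

    def test_fold_average_on_independent_set(self):
        data = _separable_toy(n=90)
        indep = _separable_toy(n=30, seed=9)
        cfg = ModelConfig(seed=0, epochs=3)
        result = cross_validate(lambda: build_model("geo_cnn", cfg), data,
                                folds=3, independent=indep)
        assert result["independent_scores"].shape == (30,)
        assert result["independent_report"].auc == 1.0


class TestBagTraining:
    def _bag(self, rng, positive, kind):
        k = int(rng.integers(1, 4))
        geo = rng.random((k, 35, 7)) * 0.1
        if positive:
            geo[:, :, 0] += 1.0  # planted witness signal in the exon column
        bag = {"geo": geo, "mask": np.ones(k, bool)}
        if kind == "i_gepse":
            bag["seq"] = rng.random((101, 4))
        if kind == "ti_gepse":
            bag["instances"] = rng.random((4, 50, 4))
        return bag

    @pytest.mark.parametrize("kind", ["i_gepse", "ti_gepse", "read_gepse"])
    def test_bag_models_learn_a_separable_signal(self, kind):
        rng = np.random.default_rng(0)
        bags = [self._bag(rng, i % 2 == 1, kind) for i in range(60)]
        y = np.array([i % 2 for i in range(60)], dtype=np.float64)
        cfg = ModelConfig(seed=0, epochs_variable=3)
        m = build_model(kind, cfg)
        res = train(m, {"bags": bags, "y": y}, cfg)
        assert res.loss_history[-1] < res.loss_history[0]
        auc = evaluate(m.predict({"bags": bags}), y).auc
        assert auc > 0.9


class TestEvaluate:
    def test_perfect_ranking(self):
        r = evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0 and r.ap == 1.0 and r.accuracy == 1.0

    def test_four_point_worked_auc(self):
        # pairs: (0.9 vs 0.8) ok, (0.9 vs 0.1) ok, (0.3 vs 0.8) wrong,
        # (0.3 vs 0.1) ok -> 3/4
        assert evaluate([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]).auc == 0.75

    def test_shuffled_labels_are_chance(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert abs(evaluate(scores, labels).auc - 0.5) < 0.02

    def test_single_class_reports_missing(self):
        r = evaluate([0.2, 0.8], [1, 1])
        assert np.isnan(r.auc) and np.isnan(r.ap)

    def test_stepwise_ap_matches_library(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.integers(0, 2, 200)
            s = rng.random(200)
            assert average_precision_stepwise(y, s) == pytest.approx(
                average_precision_score(y, s)
            )

    def test_aggregate_mean_sd(self):
        r1 = evaluate([0.9, 0.1], [1, 0])
        r2 = evaluate([0.4, 0.6], [1, 0])
        agg = MetricReport.aggregate([r1, r2])
        assert agg["auc"] == (0.5, 0.5)


def test_permutation_importance_finds_informative_feature():
    rng = np.random.default_rng(0)
    X = rng.random((400, 5))
    y = (X[:, 2] > 0.5).astype(int)
    drops = permutation_importance(lambda A: A[:, 2], X, y, seed=1)
    assert np.argmax(drops) == 2
    assert drops[2] > 0.3
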