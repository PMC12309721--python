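"""Network construction, training mechanics, guarded inference, serialization."""

import json

import numpy as np
import pytest

import puritynet as pn
from puritynet import mlp


def small_features(n=6):
    return pn.FeatureSet([f"g{i:04d}" for i in range(n)])


class TestArchitecture:
    def test_parameter_count_published_panel(self):
        # 5829 -> 32 -> 16 -> 1 with biases
        assert mlp.parameter_count([5829, 32, 16, 1]) == 5829 * 32 + 32 + 32 * 16 + 16 + 16 + 1

    def test_init_dimensions_and_determinism(self):
        fs = small_features(10)
        cfg = pn.ModelConfig(seed=0)
        m1 = pn.init_model(fs, cfg, np.random.default_rng(7))
        m2 = pn.init_model(fs, cfg, np.random.default_rng(7))
        assert [l.W.shape for l in m1.layers] == [(10, 32), (32, 16), (16, 1)]
        for a, b in zip(m1.layers, m2.layers):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.b, b.b)

    def test_zero_weights_forward_zero(self):
        fs = small_features(4)
        model = pn.init_model(fs, pn.ModelConfig(), np.random.default_rng(0))
        for l in model.layers:
            l.W[:] = 0.0
            l.b[:] = 0.0
        preds = model.forward(np.zeros((3, 4)))
        np.testing.assert_array_equal(preds, 0.0)

    def test_config_invariants(self):
        with pytest.raises(pn.ValidationError):
            pn.ModelConfig(hidden_sizes=[])
        with pytest.raises(pn.ValidationError):
            pn.ModelConfig(input_dropout=1.0)
        with pytest.raises(pn.ValidationError):
            pn.ModelConfig(window=30, patience=10)


class TestGradientsAndAdam:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        layers = mlp.init_layers([5, 4, 3, 1], rng)
        X = rng.normal(size=(9, 5))
        y = rng.uniform(size=9)
        _, cache = mlp.forward(layers, X)
        grads = mlp.backward_l1(layers, cache, y)
        eps = 1e-7
        for li in range(len(layers)):
            W = layers[li].W
            for ix in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]:
                orig = W[ix]
                W[ix] = orig + eps
                up = mlp.l1_loss(y, mlp.forward(layers, X)[0])
                W[ix] = orig - eps
                down = mlp.l1_loss(y, mlp.forward(layers, X)[0])
                W[ix] = orig
                fd = (up - down) / (2 * eps)
                assert grads[li].W[ix] == pytest.approx(fd, abs=1e-6)

    def test_adam_single_step_reference(self):
        # one Adam step on a single scalar weight with known gradient:
        # m=(1-b1)g, v=(1-b2)g^2, step = lr * g/|g| (bias-corrected), minus decay term
        layer = mlp.Linear(np.array([[2.0]]), np.array([0.0]))
        grad = mlp.Linear(np.array([[0.5]]), np.array([0.0]))
        opt = mlp.Adam(lr=1e-3, weight_decay=0.0)
        opt.step([layer], [grad])
        g = 0.5
        mhat = (1 - 0.9) * g / (1 - 0.9)
        vhat = (1 - 0.999) * g * g / (1 - 0.999)
        expected = 2.0 - 1e-3 * mhat / (np.sqrt(vhat) + 1e-8)
        assert layer.W[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_weight_decay_pulls_toward_zero(self):
        layer = mlp.Linear(np.array([[1.0]]), np.array([0.0]))
        grad = mlp.Linear(np.array([[0.0]]), np.array([0.0]))
        opt = mlp.Adam(lr=1e-2, weight_decay=1e-1)
        opt.step([layer], [grad])
        assert layer.W[0, 0] < 1.0


class TestDropout:
    def test_eval_mode_is_deterministic_identity(self):
        rng = np.random.default_rng(1)
        layers = mlp.init_layers([8, 4, 1], rng)
        X = rng.normal(size=(5, 8))
        p1, _ = mlp.forward(layers, X, input_dropout=0.4, training=False)
        p2, _ = mlp.forward(layers, X, input_dropout=0.4, training=False)
        np.testing.assert_array_equal(p1, p2)

    def test_training_mode_masks_inputs(self):
        rng = np.random.default_rng(2)
        layers = mlp.init_layers([50, 4, 1], rng)
        X = np.ones((4, 50))
        _, cache = mlp.forward(
            layers, X, input_dropout=0.4, training=True, rng=np.random.default_rng(0)
        )
        dropped = cache["inputs"][0]
        frac_zero = np.mean(dropped == 0.0)
        assert 0.2 < frac_zero < 0.6
        surviving = dropped[dropped > 0]
        np.testing.assert_allclose(surviving, 1 / 0.6)


class TestTraining:
    def test_short_training_runs_and_logs(self, corpus, selected_features, gene_lengths):
        sim = pn.SimulationConfig(seed=3, cells_min=50, cells_max=200)
        cfg = pn.ModelConfig(seed=4, max_batches=40, window=5, patience=5)
        model, log = pn.train(corpus, selected_features, gene_lengths, sim, cfg)
        assert len(log.losses) <= 40
        assert log.best_window_mean == pytest.approx(min(log.window_means))
        assert log.stop_reason
        assert model.training_log is log

    def test_best_snapshot_is_returned(self, corpus, selected_features, gene_lengths):
        """The returned weights come from the batch with the lowest sliding
        mean, not from the last batch."""
        sim = pn.SimulationConfig(seed=3, cells_min=50, cells_max=200)
        cfg = pn.ModelConfig(seed=4, max_batches=60, window=5, patience=5)
        model, log = pn.train(corpus, selected_features, gene_lengths, sim, cfg)
        assert log.best_window_mean <= min(log.window_means) + 1e-15

    def test_same_seeds_identical_models(self, corpus, selected_features, gene_lengths, tmp_path):
        out = []
        for rep in range(2):
            sim = pn.SimulationConfig(seed=5, cells_min=50, cells_max=200)
            cfg = pn.ModelConfig(seed=6, max_batches=30, window=5, patience=5)
            model, _ = pn.train(corpus, selected_features, gene_lengths, sim, cfg)
            path = tmp_path / f"m{rep}.json"
            pn.save_model(model, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]


class TestPredictGuards:
    @pytest.fixture()
    def model(self):
        fs = small_features(100)
        model = pn.init_model(fs, pn.ModelConfig(seed=0), np.random.default_rng(3))
        return model

    def _matrix(self, fs_genes, n_cols=2, drop=0):
        genes = fs_genes[drop:] if drop else list(fs_genes)
        rng = np.random.default_rng(0)
        return pn.CountMatrix(
            genes,
            [f"s{j}" for j in range(n_cols)],
            rng.poisson(30.0, size=(len(genes), n_cols)) + 1.0,
        )

    @pytest.fixture()
    def lengths(self, model):
        return pn.GeneLengths({g: 1000.0 for g in model.feature_set.gene_ids})

    def test_predictions_clipped_to_unit_interval(self, model, lengths):
        # force a huge positive output bias, then a huge negative one
        m = self._matrix(model.feature_set.gene_ids)
        model.layers[-1].b[:] = 100.0
        preds, _ = pn.predict(model, m, lengths)
        np.testing.assert_array_equal(preds, 1.0)
        model.layers[-1].b[:] = -100.0
        preds, _ = pn.predict(model, m, lengths)
        np.testing.assert_array_equal(preds, 0.0)

    def test_two_percent_missing_warns(self, model, lengths):
        m = self._matrix(model.feature_set.gene_ids, drop=2)  # 2% of 100
        with pytest.warns(UserWarning, match="underestimated"):
            preds, notes = pn.predict(model, m, lengths)
        assert len(preds) == 2
        assert notes

    def test_one_percent_missing_silent(self, model, lengths, recwarn):
        m = self._matrix(model.feature_set.gene_ids, drop=1)
        preds, notes = pn.predict(model, m, lengths)
        assert not notes

    def test_twenty_five_percent_missing_refuses(self, model, lengths):
        m = self._matrix(model.feature_set.gene_ids, drop=25)
        with pytest.raises(pn.MissingGeneError, match="refus"):
            pn.predict(model, m, lengths)

    def test_repeated_predict_identical(self, model, lengths):
        m = self._matrix(model.feature_set.gene_ids)
        p1, _ = pn.predict(model, m, lengths)
        p2, _ = pn.predict(model, m, lengths)
        np.testing.assert_array_equal(p1, p2)


class TestSerialization:
    @pytest.fixture()
    def model(self):
        fs = small_features(12)
        return pn.init_model(fs, pn.ModelConfig(seed=1), np.random.default_rng(9))

    def test_round_trip_identical_predictions(self, model, tmp_path):
        path = tmp_path / "model.json"
        pn.save_model(model, path)
        back = pn.load_model(path)
        X = np.random.default_rng(0).uniform(0, 5, size=(7, 12))
        np.testing.assert_array_equal(model.forward(X), back.forward(X))
        assert back.feature_set.gene_ids == model.feature_set.gene_ids

    def test_truncated_file_rejected(self, model, tmp_path):
        path = tmp_path / "model.json"
        pn.save_model(model, path)
        path.write_bytes(path.read_bytes()[:50])
        with pytest.raises(pn.ValidationError, match="not a valid"):
            pn.load_model(path)

    def test_missing_feature_set_rejected(self, model, tmp_path):
        path = tmp_path / "model.json"
        pn.save_model(model, path)
        obj = json.loads(path.read_text())
        del obj["feature_set"]
        path.write_text(json.dumps(obj))
        with pytest.raises(pn.ValidationError, match="feature_set"):
            pn.load_model(path)

    def test_version_mismatch_rejected(self, model, tmp_path):
        path = tmp_path / "model.json"
        pn.save_model(model, path)
        obj = json.loads(path.read_text())
        obj["format_version"] = 99
        path.write_text(json.dumps(obj))
        with pytest.raises(pn.ValidationError, match="version"):
            pn.load_model(path)


class TestParameterRecovery:
    """Pipeline-level learning checks that are slower than unit tests."""

    def test_recovers_purity_with_dropout_matched_to_input_dimension(
        self, corpus, selected_features, gene_lengths, heldout_pseudobulks
    ):
        """With input dropout disabled — the appropriate regularization for a
        ~130-gene panel, where a 0.4 dropout rate injects ~6x more relative
        input noise than on the published 5829-gene panel — the network
        recovers held-out purity accurately at the published learning rate."""
        model, _ = pn.train(
            corpus,
            selected_features,
            gene_lengths,
            pn.SimulationConfig(seed=1),
            pn.ModelConfig(seed=2, input_dropout=0.0, max_batches=6000),
        )
        cm, labels = heldout_pseudobulks
        report, preds = pn.evaluate(model, cm, labels, gene_lengths, "holdout")
        assert report.mae <= 0.07
        assert report.ccc >= 0.95
        slope = np.polyfit(labels, preds, 1)[0]
        assert 0.85 <= slope <= 1.15  # no scale compression

    def test_heldout_error_decreases_with_signal_strength(self):
        """Across three marker fold-change levels, held-out MAE falls as the
        malignant/nonmalignant expression contrast grows."""
        maes = []
        for fc in (1.5, 4.0, 10.0):
            cfg = pn.FixtureConfig(fold_change=fc)
            c = pn.generate_corpus(cfg)
            pb, _ = pn.pseudobulk_per_sample(c)
            bulk, _ = pn.generate_bulk_cohort(cfg, 50)
            fs, _ = pn.select_features(bulk, pb)
            glen = pn.generate_gene_lengths(cfg)
            model, _ = pn.train(
                c, fs, glen, pn.SimulationConfig(seed=1), pn.ModelConfig(seed=2)
            )
            hold_cfg = pn.FixtureConfig(**{**cfg.__dict__, "n_samples": 2})
            rng = np.random.default_rng(999)
            hold = pn.generate_corpus(hold_cfg, rng=rng, sample_prefix="H")
            cols, ys, ids = [], [], []
            for j in range(100):
                pbk = pn.simulate_pseudobulk(
                    hold, hold.sample_ids[j % 2],
                    float(rng.uniform(0, 1)), int(rng.integers(200, 4001)), rng,
                )
                cols.append(pbk.counts)
                ys.append(pbk.purity)
                ids.append(f"h{j}")
            cm = pn.CountMatrix(cfg.gene_ids, ids, np.array(cols).T)
            report, _ = pn.evaluate(model, cm, np.array(ys), glen)
            maes.append(report.mae)
        assert maes[0] > maes[1] > maes[2]
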