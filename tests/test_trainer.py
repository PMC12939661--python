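"""LODO protocol, NumPy CNN backprop, training schedule, diagnostics."""

import numpy as np
import pytest

from crossmex.manifests import LABELS, RunConfig, SampleRecord
from crossmex.metrics import compute_metrics
from crossmex.trainer import (BackboneSpec, SimpleCNN, TrainState, evaluate,
                              extract_features, feature_diagnostics,
                              load_inputs, make_lodo_splits, split_records,
                              train)


def _au_rec(i, dataset, label="Positive", split="train", synthetic=False):
    return SampleRecord(sample_id=f"{dataset}_{i}", source_dataset=dataset,
                        label=label, au=np.zeros(17), split=split,
                        synthetic=synthetic)


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """End-to-end check of the hand-written conv/pool/linear backward."""
        rng = np.random.default_rng(0)
        spec = BackboneSpec(conv_stages=((3, 4), (3, 6)))
        net = SimpleCNN(spec, size=12, channels=2, seed=1)
        x = rng.normal(size=(5, 12, 12, 2)).astype(np.float32)
        y = np.array([0, 1, 2, 0, 1])
        dfe = (rng.normal(size=(5, net.feature_dim)) * 0.01).astype(np.float32)

        def full_loss():
            logits, feats, _ = net.forward(x)
            z = logits - logits.max(1, keepdims=True)
            p = np.exp(z); p /= p.sum(1, keepdims=True)
            return (-np.log(p[np.arange(5), y]).mean()
                    + float((feats * dfe).sum()))

        logits, feats, cache = net.forward(x)
        z = logits - logits.max(1, keepdims=True)
        p = np.exp(z); p /= p.sum(1, keepdims=True)
        dlogits = ((p - np.eye(3)[y]) / 5).astype(np.float32)
        grads = net.backward(cache, dlogits, dfe)

        eps = 1e-3
        for key in grads:
            param = net.params[key]
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in param.shape)
                orig = param[idx]
                param[idx] = orig + eps; lp = full_loss()
                param[idx] = orig - eps; lm = full_loss()
                param[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(num, rel=5e-2, abs=5e-4)

    def test_input_shape_mismatch_rejected(self):
        net = SimpleCNN(BackboneSpec(), size=32, channels=3, seed=0)
        with pytest.raises(ValueError, match="does not match backbone"):
            net.forward(np.zeros((2, 48, 48, 3), dtype=np.float32))


class TestLODOSplits:
    def test_benchmark_shaped_manifest(self, table1_records):
        splits = make_lodo_splits(table1_records)
        assert len(splits) == 5
        by_name = {s.held_out: s for s in splits}
        assert by_name["CASME"].train_size == 648
        assert by_name["CASME"].test_size == 83
        assert by_name["SMIC"].train_size == 567
        assert "CASME" not in by_name["CASME"].train_datasets

    def test_two_domains_two_splits(self):
        recs = [_au_rec(i, d) for d in ("a", "b") for i in range(3)]
        assert len(make_lodo_splits(recs)) == 2

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_lodo_splits([_au_rec(0, "only")])

    def test_synthetic_records_never_in_test(self):
        recs = ([_au_rec(i, "a") for i in range(3)]
                + [_au_rec(i, "b") for i in range(3)]
                + [_au_rec(10 + i, "b", synthetic=True) for i in range(4)])
        split = [s for s in make_lodo_splits(recs) if s.held_out == "b"][0]
        _, test = split_records(recs, split)
        assert len(test) == 3
        assert all(not r.synthetic for r in test)

    def test_sizes_match_brute_force_partition(self):
        rng = np.random.default_rng(5)
        recs = [_au_rec(i, rng.choice(["x", "y", "z"]),
                        label=rng.choice(LABELS)) for i in range(60)]
        for s in make_lodo_splits(recs):
            assert s.train_size == sum(1 for r in recs
                                       if r.source_dataset != s.held_out)
            assert s.test_size == sum(1 for r in recs
                                      if r.source_dataset == s.held_out)


@pytest.fixture(scope="module")
def toy_training(toy_bench_dir):
    """One short baseline training run on the 2-domain toy benchmark."""
    out, bench = toy_bench_dir
    inputs = load_inputs(bench.records, modality="image")
    split = make_lodo_splits(bench.records)[1]     # hold out siteB
    config = RunConfig(lambda_weight=0.0, epochs=25, brl_start_epoch=2,
                       learning_rate=1e-3, batch_size=12, seed=0, image_size=48)
    state = train(split, bench.records, config, inputs)
    return bench, inputs, split, state


class TestTraining:
    def test_lambda_zero_total_equals_ce(self, toy_training):
        _, _, _, state = toy_training
        for entry in state.loss_log:
            assert entry["l_total"] == pytest.approx(entry["l_ce"])
            assert entry["lambda_effective"] == 0.0

    def test_learns_separable_toy_problem(self, toy_training):
        bench, inputs, split, state = toy_training
        train_recs, _ = split_records(bench.records, split)
        X = np.stack([inputs[r.sample_id] for r in train_recs]).astype(np.float32)
        y = [r.label for r in train_recs]
        from crossmex.trainer import _predict
        pred = [LABELS[i] for i in _predict(state.model, X)]
        acc = np.mean([a == b for a, b in zip(pred, y)])
        assert acc > 0.9

    def test_evaluation_only_after_brl_start(self, toy_training):
        _, _, _, state = toy_training
        assert state.eval_log
        assert all(epoch > 2 for epoch, _ in state.eval_log)
        assert state.best_epoch > 2

    def test_evaluate_consistent_with_metrics_module(self, toy_training):
        bench, inputs, split, state = toy_training
        report = evaluate(state, bench.records, inputs)
        _, test_recs = split_records(bench.records, split)
        X = np.stack([inputs[r.sample_id] for r in test_recs]).astype(np.float32)
        from crossmex.trainer import _predict
        pred = [LABELS[i] for i in _predict(state.model, X)]
        ref = compute_metrics([r.label for r in test_recs], pred, LABELS)
        assert report.acc == ref.acc
        assert report.uar == ref.uar
        assert np.array_equal(report.confusion, ref.confusion)

    def test_single_source_training_has_zero_brl(self, toy_bench_dir):
        out, bench = toy_bench_dir
        inputs = load_inputs(bench.records)
        # hold out siteB -> only siteA trains: L_BRL must vanish identically
        recs = [r for r in bench.records]
        split = [s for s in make_lodo_splits(recs) if s.held_out == "siteB"][0]
        config = RunConfig(lambda_weight=0.5, epochs=3, brl_start_epoch=0,
                           batch_size=8, seed=1, image_size=48)
        state = train(split, recs, config, inputs)
        for entry in state.loss_log:
            assert entry["l_brl"] == 0.0
            assert entry["l_total"] == pytest.approx(0.5 * entry["l_ce"])

    def test_empty_training_set_rejected(self):
        recs = [_au_rec(0, "a", split="test"), _au_rec(0, "b")]
        split = [s for s in make_lodo_splits(recs) if s.held_out == "b"][0]
        with pytest.raises(ValueError, match="empty training set"):
            train(split, recs, RunConfig(epochs=1, brl_start_epoch=0),
                  {r.sample_id: np.zeros((32, 32, 3)) for r in recs})


class TestStubEvaluation:
    class _ConstantModel:
        feature_dim = 4

        def forward(self, x):
            n = len(x)
            logits = np.tile([5.0, 0.0, 0.0], (n, 1))    # always class 0
            return logits, np.zeros((n, 4), np.float32), None

    def test_constant_model_on_balanced_test_set(self):
        recs = [_au_rec(i, "train_ds") for i in range(3)]
        test = [_au_rec(i, "held", label=c) for c in LABELS for i in range(4)]
        all_recs = recs + test
        split = [s for s in make_lodo_splits(all_recs) if s.held_out == "held"][0]
        state = TrainState(model=self._ConstantModel(), head=None,
                           config=RunConfig(), classes=list(LABELS), split=split)
        inputs = {r.sample_id: np.zeros((8, 8, 3), np.float32) for r in all_recs}
        report = evaluate(state, all_recs, inputs)
        assert report.acc == pytest.approx(1 / 3)
        assert report.uar == pytest.approx(1 / 3)


class TestDiagnostics:
    def test_identical_features_give_null_silhouette(self):
        out = feature_diagnostics(np.ones((12, 6)), ["a"] * 6 + ["b"] * 6)
        assert out["silhouette_domain"] is None
        assert np.allclose(out["projection"], 0.0)

    def test_separated_domains_exceed_threshold(self, desk_bench):
        recs = [r for r in desk_bench.records
                if r.source_dataset in ("siteA", "siteB", "siteC")]
        X = np.stack([desk_bench.images[r.sample_id].reshape(-1) for r in recs])
        out = feature_diagnostics(X, [r.source_dataset for r in recs],
                                  [r.label for r in recs])
        assert out["silhouette_domain"] > 0.2
        assert out["boundary"] is not None

    def test_minimum_sample_count(self):
        with pytest.raises(ValueError, match="at least 10"):
            feature_diagnostics(np.zeros((5, 3)), ["a"] * 5)

    def test_plot_written(self, tmp_path, desk_bench):
        recs = desk_bench.records[:40]
        X = np.stack([desk_bench.images[r.sample_id].reshape(-1) for r in recs])
        feature_diagnostics(X, [r.source_dataset for r in recs],
                            plot_path=tmp_path / "proj.png")
        assert (tmp_path / "proj.png").stat().st_size > 0
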