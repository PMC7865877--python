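import numpy as np
import pytest

from ecgdesk import ECGRecord, SyntheticSpec, generate
from ecgdesk.diagnosis import (
    ITEM_CODES,
    NetworkConfig,
    build_network,
    build_reverse_lead_network,
    evaluate,
    predict,
    predict_proba,
    segment_recording,
    train,
)
from ecgdesk.diagnosis.network import ECGNet
from ecgdesk.diagnosis.training import TrainConfig
from ecgdesk.errors import ConfigError, UnknownItemError

# Reduced-width configuration used by the training tests: same 32-layer,
# 8-stage topology, fewer filters so CPU training stays fast.
SMALL = NetworkConfig(base_filters=4, segment_length=256, recurrent_hidden=8,
                      n_classes=20, dropout_rate=0.0)
SMALL_BINARY = NetworkConfig(base_filters=4, segment_length=256,
                             recurrent_hidden=8, n_classes=1, dropout_rate=0.1)

# Frozen regression constant: parameter count of the default configuration.
DEFAULT_N_PARAMS = 10_511_764


def _record(samples):
    return ECGRecord(samples=np.asarray(samples, dtype=float),
                     sampling_rate=125.0)


class TestSegmentRecording:
    def test_exact_division(self):
        cfg = NetworkConfig()
        segs = segment_recording(_record(np.ones(2560)), cfg)
        assert segs.shape == (2, 1280)

    def test_padding(self):
        cfg = NetworkConfig()
        segs = segment_recording(_record(np.ones(1300)), cfg)
        assert segs.shape == (2, 1280)
        assert np.all(segs[1, 20:] == 0.0)

    def test_partition_identity(self):
        cfg = NetworkConfig(segment_length=256)
        x = np.random.default_rng(0).standard_normal(700)
        segs = segment_recording(_record(x), cfg)
        assert np.array_equal(segs.reshape(-1)[: x.size], x)

    def test_short_record_single_padded_segment(self, caplog):
        cfg = NetworkConfig(segment_length=256)
        with caplog.at_level("WARNING"):
            segs = segment_recording(_record(np.ones(100)), cfg)
        assert segs.shape == (1, 256)


class TestBuildNetwork:
    def test_conv_layer_census(self):
        net = build_network(seed=0)
        convs = net.conv_layers()
        assert len(convs) == 32
        assert all(c.kernel_size == 16 for c in convs)
        assert net.config.n_stages == 8

    def test_downsampling_by_256(self):
        net = build_network(seed=0)
        strides = [c.stride for c in net.conv_layers()]
        assert int(np.prod(strides)) == 256

    def test_filter_growth_doubles_every_two_stages(self):
        cfg = NetworkConfig()
        assert [cfg.filters_for_stage(s) for s in range(8)] == [
            32, 32, 64, 64, 128, 128, 256, 256
        ]

    def test_output_arity_and_range(self):
        net = ECGNet(SMALL, seed=0)
        x = np.random.default_rng(1).standard_normal((3, 2, 256))
        probs = net.forward(x)
        assert probs.shape == (3, 20)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_segment_count_does_not_change_arity(self):
        net = ECGNet(SMALL, seed=0)
        rng = np.random.default_rng(2)
        p1 = net.forward(rng.standard_normal((1, 1, 256)))
        p4 = net.forward(rng.standard_normal((1, 4, 256)))
        assert p1.shape == p4.shape == (1, 20)

    def test_invalid_segment_length(self):
        with pytest.raises(ConfigError):
            NetworkConfig(segment_length=1000).validate()

    def test_parameter_count_regression(self):
        assert build_network(seed=0).n_parameters() == DEFAULT_N_PARAMS

    def test_parameter_count_deterministic_in_config(self):
        a = ECGNet(SMALL, seed=0).n_parameters()
        b = ECGNet(SMALL, seed=99).n_parameters()
        assert a == b

    def test_reverse_lead_scalar_output(self):
        net = build_reverse_lead_network(SMALL_BINARY, seed=0)
        x = np.random.default_rng(3).standard_normal((2, 1, 256))
        probs = net.forward(x)
        assert probs.shape == (2, 1)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_reverse_lead_requires_one_class(self):
        with pytest.raises(ConfigError):
            build_reverse_lead_network(SMALL, seed=0)


def _overfit_dataset(n=8):
    rng = np.random.default_rng(1)
    ds = []
    for i in range(n):
        base = np.sin(np.arange(256) / (3.0 + 2 * (i % 2)))
        ds.append((base + 0.05 * rng.standard_normal(256),
                   {"SN"} if i % 2 else {"AF"}))
    return ds


class TestTrain:
    def test_overfit_small_set(self):
        net = ECGNet(SMALL, seed=0)
        trace = train(net, _overfit_dataset(),
                      TrainConfig(epochs=200, batch_size=8, learning_rate=5e-3),
                      seed=0)
        assert trace[-1] < 0.05

    def test_loss_decreases_early(self):
        net = ECGNet(SMALL, seed=0)
        trace = train(net, _overfit_dataset(),
                      TrainConfig(epochs=20, batch_size=8, learning_rate=1e-3),
                      seed=0)
        assert all(trace[i + 1] <= trace[i] + 1e-3 for i in range(len(trace) - 1))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ConfigError):
            train(ECGNet(SMALL, seed=0), [])

    def test_unknown_label_rejected(self):
        with pytest.raises(UnknownItemError):
            train(ECGNet(SMALL, seed=0), [(np.zeros(256), {"NOPE"})],
                  TrainConfig(epochs=1))

    def test_seeded_determinism(self):
        traces = []
        for _ in range(2):
            net = ECGNet(SMALL, seed=7)
            traces.append(train(net, _overfit_dataset(),
                                TrainConfig(epochs=5, batch_size=4), seed=7))
        assert traces[0] == traces[1]

    def test_save_load_round_trip(self, tmp_path):
        net = ECGNet(SMALL, seed=0)
        train(net, _overfit_dataset(), TrainConfig(epochs=2, batch_size=8), seed=0)
        x = np.random.default_rng(4).standard_normal((1, 1, 256))
        before = net.forward(x)
        net.save(tmp_path / "model")
        loaded = ECGNet.load(tmp_path / "model")
        assert loaded.trained
        assert np.allclose(loaded.forward(x), before)


class TestPredict:
    def test_probability_map_has_20_keys(self):
        net = ECGNet(SMALL, seed=0)
        net.trained = True
        result = predict(net, np.zeros(256))
        assert len(result.probabilities) == 20
        assert set(result.probabilities) == set(ITEM_CODES)

    def test_threshold_boundary_counts_positive(self):
        net = ECGNet(SMALL, seed=0)
        net.trained = True
        result = predict(net, np.zeros(256))
        for item, p in result.probabilities.items():
            assert result.calls[item] == (p >= 0.5)

    def test_untrained_warns(self):
        net = ECGNet(SMALL, seed=0)
        with pytest.warns(UserWarning):
            predict(net, np.zeros(256))

    def test_rate_class_separation(self):
        # SNT (130 bpm) vs SNB (45 bpm) must be learnable from synthetic data.
        rng = np.random.default_rng(0)
        ds = []
        for i in range(60):
            tachy = i % 2 == 0
            lr = generate(SyntheticSpec(
                duration=4.096, heart_rate=130.0 if tachy else 45.0,
                rhythm="sinus_tachycardia" if tachy else "sinus_bradycardia",
                seed=int(rng.integers(1e9)),
            ))
            ds.append((lr.record.samples[:512], {"SNT"} if tachy else {"SNB"}))
        cfg = NetworkConfig(base_filters=4, segment_length=512,
                            recurrent_hidden=8, n_classes=20, dropout_rate=0.0)
        net = ECGNet(cfg, seed=1)
        train(net, ds[:40], TrainConfig(epochs=30, batch_size=8,
                                        learning_rate=2e-3), seed=1)
        held = ds[40:]
        snt_idx = ITEM_CODES.index("SNT")
        probs = predict_proba(net, [x for x, _ in held])
        calls = probs[:, snt_idx] >= 0.5
        truth = np.array(["SNT" in labels for _, labels in held])
        recall = np.sum(calls & truth) / np.sum(truth)
        assert recall >= 0.9


def brute_force_auc(y, p):
    """Exhaustive pair-counting ROC-AUC oracle (ties count 1/2)."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    if not pos or not neg:
        return None
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = [{"SN"}, {"AF"}, {"SN", "PVC"}]
        probs = np.array([[1.0 if i in t else 0.0 for i in ITEM_CODES]
                          for t in truth])
        report = evaluate(probs, truth)
        for item in ("SN", "AF", "PVC"):
            m = report.per_item[item]
            assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 1.0
            assert m["roc_auc"] == 1.0

    def test_random_probabilities_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = (rng.random((n, 1)) < 0.5).astype(float)
        p = rng.random((n, 1))
        report = evaluate(p, y, items=["SN"])
        assert 0.45 <= report.per_item["SN"]["roc_auc"] <= 0.55

    def test_six_recording_worked_example(self):
        y = np.array([[1], [0], [1], [0], [1], [0]], dtype=float)
        p = np.array([[0.9], [0.2], [0.6], [0.6], [0.3], [0.1]])
        report = evaluate(p, y, items=["AF"])
        assert report.per_item["AF"]["roc_auc"] == pytest.approx(
            brute_force_auc(y[:, 0], p[:, 0])
        )

    def test_brute_force_on_small_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = int(rng.integers(4, 21))
            y = (rng.random((n, 3)) < 0.4).astype(float)
            p = np.round(rng.random((n, 3)), 2)  # rounding forces some ties
            report = evaluate(p, y, items=["a", "b", "c"])
            for j, item in enumerate(("a", "b", "c")):
                expected = brute_force_auc(y[:, j], p[:, j])
                got = report.per_item[item]["roc_auc"]
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected)

    def test_undefined_auc_reported_absent(self):
        y = np.zeros((5, 1))
        p = np.random.default_rng(0).random((5, 1))
        report = evaluate(p, y, items=["SN"])
        assert report.per_item["SN"]["roc_auc"] is None

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(4)
        y = (rng.random((50, 1)) < 0.5).astype(float)
        p = rng.random((50, 1))
        m = evaluate(p, y, items=["SN"]).per_item["SN"]
        if m["precision"] + m["recall"] > 0:
            expected = (2 * m["precision"] * m["recall"]
                        / (m["precision"] + m["recall"]))
            assert m["f1"] == pytest.approx(expected)
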