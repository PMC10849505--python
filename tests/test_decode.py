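"""Linear decoding designs: separability, null calibration, leakage."""

import numpy as np
import pytest

from seqexpect import decode


def _disjoint_classes(n_classes=4, n_trials=12, n_cells=None, seed=0):
    """Noiseless classes with disjoint support: perfectly separable."""
    if n_cells is None:
        n_cells = 2 * n_classes
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        block = np.zeros((n_trials, n_cells))
        block[:, c * 2:(c + 1) * 2] = 1.0 + rng.random((n_trials, 2)) * 0.1
        X.append(block)
        y.append(np.full(n_trials, c))
    return np.concatenate(X), np.concatenate(y)


class TestDecodeStimulus:
    def test_separable_classes_decode_perfectly(self):
        X, y = _disjoint_classes()
        rep = decode.decode_stimulus(X, y, n_iterations=3,
                                     rng=np.random.default_rng(0))
        assert rep.mean_accuracy == 1.0
        np.testing.assert_allclose(rep.confusion, np.eye(4), atol=1e-12)

    def test_confusion_rows_stochastic(self, small_session, small_events):
        _, activity = small_session
        X, y, _ = decode.stimulus_condition_responses(activity, small_events)
        rep = decode.decode_stimulus(X, y, n_iterations=2,
                                     rng=np.random.default_rng(0))
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 1.0, atol=1e-9)
        assert len(rep.classes) == 15

    def test_shuffled_labels_reach_chance(self):
        X, y = _disjoint_classes(n_classes=5, n_trials=40)
        rep = decode.decode_stimulus(X, y, n_iterations=10,
                                     rng=np.random.default_rng(1),
                                     shuffle_labels=True)
        assert rep.mean_accuracy == pytest.approx(0.2, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            decode.decode_stimulus(np.ones((4, 2)), np.zeros(4))


class TestDecodeBlock:
    def test_block_structure_from_drift(self):
        """A planted per-block mean shift is decodable, with confusion mass
        decaying with block distance."""
        rng = np.random.default_rng(2)
        X, blocks = [], []
        for b in range(5):
            X.append(rng.normal(loc=b * 1.0, scale=1.0, size=(30, 10)))
            blocks.append(np.full(30, b + 1))
        rep = decode.decode_block([(np.concatenate(X), np.concatenate(blocks))],
                                  n_iterations=3, train_per_block=15,
                                  rng=np.random.default_rng(0))
        assert rep.mean_accuracy > 0.5
        cm = rep.confusion
        # off-diagonal decays with |true - predicted|
        assert cm[0, 1] > cm[0, 3]
        assert rep.n_test_trials == 75

    def test_shuffled_blocks_reach_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 8))
        blocks = np.repeat(np.arange(5), 20)
        rep = decode.decode_block([(X, blocks)], n_iterations=10,
                                  train_per_block=10,
                                  rng=np.random.default_rng(0),
                                  shuffle_labels=True)
        assert abs(rep.mean_accuracy - 0.2) < 0.08

    def test_too_small_blocks_rejected(self):
        X = np.ones((10, 3))
        blocks = np.repeat([1, 2], 5)
        with pytest.raises(ValueError, match="train_per_block"):
            decode.decode_block([(X, blocks)], n_iterations=1,
                                train_per_block=5)


class TestDecodeTime:
    def test_structured_bins_decoded_above_chance(self):
        rng = np.random.default_rng(4)
        n_periods, n_bins, n_cells = 40, 6, 12
        G = rng.normal(size=(n_periods, n_bins, n_cells)) * 0.2
        for b in range(n_bins):
            G[:, b, b * 2:(b + 1) * 2] += 2.0
        rep, per_bin = decode.decode_time(G, n_iterations=3,
                                          rng=np.random.default_rng(0))
        assert rep.mean_accuracy > 0.9
        assert per_bin.shape == (6,)

    def test_shuffled_time_labels_reach_chance(self):
        rng = np.random.default_rng(5)
        G = rng.normal(size=(30, 8, 10))
        rep, _ = decode.decode_time(G, n_iterations=8,
                                    rng=np.random.default_rng(0),
                                    shuffle_labels=True)
        assert abs(rep.mean_accuracy - 1 / 8) < 0.05

    def test_split_by_period_prevents_leakage(self):
        """Bin labels shuffled *consistently within each period* (trial
        structure preserved) must still decode at chance when periods carry
        no time information — the leakage detector."""
        rng = np.random.default_rng(6)
        n_periods, n_bins, n_cells = 40, 6, 10
        # per-period random offset, no bin structure
        G = rng.normal(size=(n_periods, 1, n_cells)).repeat(n_bins, axis=1)
        G += rng.normal(size=G.shape) * 0.1
        rep, _ = decode.decode_time(G, n_iterations=5,
                                    rng=np.random.default_rng(0))
        assert abs(rep.mean_accuracy - 1 / 6) < 0.06

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError, match="2 time bins"):
            decode.decode_time(np.ones((10, 1, 3)))
        with pytest.raises(ValueError, match="2 periods"):
            decode.decode_time(np.ones((1, 5, 3)))


def test_zero_amplitude_session_decodes_at_chance():
    """Silencing every planted response drives the stimulus decoder into
    its null band."""
    from seqexpect.schedule import ProtocolConfig, build_protocol
    from seqexpect.simulate import (GeneratorConfig, generate_population,
                                    simulate_session)
    proto = ProtocolConfig(block_size=4)
    events = build_protocol(proto, "baseline")
    cfg = GeneratorConfig(n_mice=1, cells_per_mouse=40, mean_amplitude=0.0,
                          seed=8)
    rng = np.random.default_rng(8)
    cells = generate_population(cfg, "baseline", rng=rng)
    act = simulate_session(cells, events, cfg, rng=rng)
    X, y, _ = decode.stimulus_condition_responses(act, events)
    rep = decode.decode_stimulus(X, y, n_iterations=5,
                                 rng=np.random.default_rng(0))
    assert abs(rep.mean_accuracy - 1 / 15) < 0.06
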