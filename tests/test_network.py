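"""Network wiring, trial execution, classification, and learning plumbing.

Uses deliberately small networks and short windows so each simulated trial
stays cheap; the full-scale learning experiment lives in the acceptance
suite.
"""

import numpy as np
import pytest

from burstnet.network import (Network, NetworkConfig, TrialProtocol, build,
                              classify, train, evaluate)
from burstnet.retina import EncoderConfig, encode, make_patterns
from burstnet.serialize import (save_weight_triplets, load_weight_triplets,
                                config_to_text, config_from_text)

SMALL = dict(n_layer2=60, n_critic=5, seed=3)
PROTO = TrialProtocol(eval_window=200.0, epochs=1)


@pytest.fixture(scope="module")
def small_net():
    return Network(NetworkConfig(**SMALL))


@pytest.fixture(scope="module")
def patterns():
    return make_patterns(n_classes=3, n_per_class=2, seed=5)


def spikes_for(patterns, idx, seed=21, duration=PROTO.trial_duration):
    return encode(patterns.images[idx],
                  EncoderConfig(seed=seed, duration=duration))


class TestBuild:
    def test_zero_probability_means_no_recurrence(self):
        net = build(NetworkConfig(n_layer2=40, conn_prob=0.0, seed=0))
        assert net.n_recurrent_synapses == 0

    def test_full_probability_is_complete_digraph(self):
        net = build(NetworkConfig(n_layer2=40, conn_prob=1.0, seed=0))
        assert net.n_recurrent_synapses == 40 * 39

    def test_synapse_count_matches_binomial(self):
        net = build(NetworkConfig(n_layer2=200, conn_prob=0.2, seed=1))
        n_pairs = 200 * 199
        mean = 0.2 * n_pairs
        sd = np.sqrt(n_pairs * 0.2 * 0.8)
        assert abs(net.n_recurrent_synapses - mean) < 4 * sd

    def test_exc_inh_split(self, small_net):
        assert small_net.n_exc == 48  # 80% of 60

    def test_distance_factors_decay(self, small_net):
        f = small_net.dist_factor
        assert f[0, 0] == 1.0
        assert np.all(f > 0) and np.all(f <= 1.0)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_layer2=0)
        with pytest.raises(ValueError):
            NetworkConfig(exc_fraction=1.0)


class TestClassify:
    def test_clear_winner(self):
        assert classify([6, 1, 1]) == (0, False)

    def test_all_equal_ties_to_lowest(self):
        assert classify([2, 2, 2]) == (0, True)

    def test_permutation_equivariance(self, rng):
        counts = [1, 7, 3, 5]
        w, _ = classify(counts)
        perm = rng.permutation(4)
        w2, _ = classify(np.asarray(counts)[perm])
        assert perm[w2] == w


class TestTrials:
    def test_frozen_trial_leaves_weights_untouched(self, small_net, patterns):
        before = small_net.weights_snapshot()
        small_net.run_trial(spikes_for(patterns, 0), PROTO, learning=False)
        after = small_net.weights_snapshot()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])

    def test_zero_input_trial_is_silent_and_static(self, patterns):
        net = Network(NetworkConfig(**SMALL))
        dark = encode(np.zeros((28, 28)),
                      EncoderConfig(seed=0, duration=PROTO.trial_duration))
        before = net.weights_snapshot()
        rec = net.run_trial(dark, PROTO, learning=True, feedback=True,
                            label=0)
        assert rec.burst_counts.sum() == 0
        np.testing.assert_array_equal(before["W_rec"], net.W_rec)
        np.testing.assert_array_equal(before["W_out"], net.W_out)

    def test_trial_reproducibility(self, patterns):
        recs = []
        for _ in range(2):
            net = Network(NetworkConfig(**SMALL))
            recs.append(net.run_trial(spikes_for(patterns, 2), PROTO))
        np.testing.assert_array_equal(recs[0].burst_counts,
                                      recs[1].burst_counts)
        assert recs[0].n_spikes == recs[1].n_spikes
        assert recs[0].gate == recs[1].gate

    def test_synaptic_latency_precedes_first_response(self):
        # a network with silent input until t0 cannot spike before
        # t0 + tau_L (all neurons start at rest)
        net = Network(NetworkConfig(**SMALL))
        t0 = 50.0
        img = np.ones((28, 28))
        sp = encode(img, EncoderConfig(seed=4, rate_max=80.0,
                                       duration=PROTO.trial_duration))
        sp.trains = [t[t >= t0] for t in sp.trains]
        n_steps = int(round(PROTO.trial_duration / net.cfg.dt))
        raster = net._simulate(sp, n_steps)
        first = np.nonzero(raster.any(axis=0))[0]
        assert first.size > 0
        assert first[0] * net.cfg.dt >= t0 + net.syn.tau_L

    def test_distance_scaling_keeps_activity_sparser(self, patterns):
        base = NetworkConfig(**SMALL)
        local = Network(base)
        flat = Network(NetworkConfig(**{**SMALL, "distance_scale": 1e9}))
        sp = spikes_for(patterns, 0)
        r_local = local.run_trial(sp, PROTO).l2_burst_rate
        r_flat = flat.run_trial(sp, PROTO).l2_burst_rate
        assert r_local < r_flat


class TestTrainEval:
    def test_zero_epochs_leave_weights(self, patterns):
        net = Network(NetworkConfig(**SMALL))
        before = net.weights_snapshot()
        hist = train(net, patterns, TrialProtocol(eval_window=200.0,
                                                  epochs=0))
        assert len(hist) == 0
        np.testing.assert_array_equal(before["W_out"], net.W_out)

    def test_confusion_rows_normalized(self, patterns):
        net = Network(NetworkConfig(**SMALL))
        acc, conf = evaluate(net, patterns, PROTO, repeats=1)
        np.testing.assert_allclose(conf.sum(axis=1), 1.0)
        # balanced classes: mean diagonal equals the accuracy
        assert 100.0 * conf.diagonal().mean() == pytest.approx(acc)

    def test_training_history_records_epochs(self, patterns):
        net = Network(NetworkConfig(**SMALL))
        hist = train(net, patterns,
                     TrialProtocol(eval_window=200.0, epochs=2))
        assert list(hist["epoch"]) == [0, 1]
        assert "train_accuracy" in hist

    def test_end_to_end_determinism(self, patterns):
        counts = []
        for _ in range(2):
            net = Network(NetworkConfig(**SMALL))
            hist = train(net, patterns,
                         TrialProtocol(eval_window=200.0, epochs=1))
            counts.append((hist["train_accuracy"].iloc[0],
                           net.W_out.sum()))
        assert counts[0] == counts[1]


class TestSerialize:
    def test_weight_triplet_roundtrip(self, small_net, tmp_path):
        path = tmp_path / "w.txt"
        save_weight_triplets(path, small_net.W_rec)
        back = load_weight_triplets(path, small_net.W_rec.shape)
        np.testing.assert_allclose(back, small_net.W_rec)

    def test_config_roundtrip(self, tmp_path):
        cfg = NetworkConfig(n_layer2=80, conn_prob=0.3, seed=9)
        path = tmp_path / "net.cfg"
        config_to_text(cfg, path)
        back = config_from_text(NetworkConfig, path)
        assert back == cfg
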