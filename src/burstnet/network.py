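"""Three-layer spiking classification network with actor-critic learning.

Architecture: a pseudo-retinal input layer projects with fixed weights onto
a recurrent second layer of piecewise-linear HR neurons (80% excitatory
pyramidal, 20% inhibitory interneurons, random connectivity p = 0.2 with
distance-dependent coupling on a rectangular grid); the second layer is
fully connected to the classifying output neurons and to a small critic
population.  Second-layer synapses learn by unsupervised BTDP; synapses
onto the output and critic layers learn by RBTDP, gated by the deviation
of the dopamine variable from its 10-ms baseline.  A pattern is classified
by the output neuron with the highest burst count over the evaluation
window (the first 50 ms are discarded as transient).

The public surface is both functional (build / run_trial / classify /
train / evaluate) and object-based: :class:`BurstClassifier` is a model
object built from a configuration whose ``fit`` returns a
:class:`TrainingResults` with the history, confusion matrix and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .actor_critic import CriticConfig, dopamine
from .approx import cube_table, square_table, exp_table
from .neuron import (HRParams, NeuronState, simulate, detect_bursts,
                     SPIKE_THRESHOLD, INTRA_BURST_ISI_MAX, DEFAULT_DT)
from .plasticity import PlasticityParams
from .retina import EncoderConfig, SpikeArray, encode, PatternSet
from .synapse import SynParams

__all__ = [
    "NetworkConfig",
    "TrialProtocol",
    "Network",
    "TrialRecord",
    "build",
    "run_trial",
    "classify",
    "train",
    "evaluate",
    "BurstClassifier",
    "TrainingResults",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, wiring statistics and seeds of the network.

    Desk-scale defaults (200-neuron second layer, 500 ms evaluation) keep a
    trial affordable on one CPU; the publication-scale presets (5000 or
    10000 neurons, 2000 ms) are selectable but long-running.
    """

    n_layer2: int = 200
    exc_fraction: float = 0.8
    conn_prob: float = 0.2
    n_out: int = 3
    n_critic: int = 20
    grid_shape: tuple[int, int] | None = None
    distance_scale: float | None = None  # default 2.0 grid spacings
    drive_sat: float = 8.0    # receptor-saturation clamp on |I_A - I_G|
    weight_sd: float = 0.2
    j_ext: float = 1.0        # fixed input-layer weight (non-plastic)
    input_fanout: float = 0.04  # fraction of layer 2 each ganglion reaches
    I_bias: float = 0.0
    out_gain: float | None = None  # delivery gain onto output/critic layers
    out_sparsity: float = 0.05  # fraction of layer 2 sampled by each readout
    btdp_scale: float = 0.02   # desk-scale factor on recurrent updates
    rbtdp_scale: float = 0.01  # desk-scale factor on readout updates
    reward_baseline: float = 1.0  # dopamine-source drive rate at rest
    dt: float = DEFAULT_DT
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.exc_fraction < 1.0:
            raise ValueError("exc_fraction must lie in (0, 1)")
        if not 0.0 <= self.conn_prob <= 1.0:
            raise ValueError("conn_prob must lie in [0, 1]")
        if min(self.n_layer2, self.n_out, self.n_critic) <= 0:
            raise ValueError("population sizes must be positive")


@dataclass(frozen=True)
class TrialProtocol:
    inter_pattern_gap: float = 100.0   # ms pause between patterns
    eval_window: float = 500.0         # ms scored for classification
    transient_discard: float = 50.0    # ms dropped at trial start
    epochs: int = 6
    feedback_window: float = 100.0     # ms of reward emulation
    auto_stop: bool = False
    plateau_threshold: float = 0.3     # accuracy points between epochs

    def __post_init__(self):
        for name in ("inter_pattern_gap", "eval_window", "transient_discard",
                     "feedback_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def trial_duration(self) -> float:
        return self.transient_discard + self.eval_window


PAPER_SCALE = dict(n_layer2=5000)
PAPER_PROTOCOL = TrialProtocol(eval_window=2000.0)


@dataclass
class TrialRecord:
    winner: int
    tie: bool
    burst_counts: np.ndarray
    correct: bool | None
    gate: float           # raw mean (D - b_D) over the feedback window
    gate_centered: float  # gate minus the critic's running reward prediction
    l2_burst_rate: float
    critic_value: float
    n_spikes: int


class Network:
    """A built network instance: wiring, weights and simulation state."""

    def __init__(self, cfg: NetworkConfig,
                 syn: SynParams = SynParams(),
                 plast: PlasticityParams = PlasticityParams(),
                 critic: CriticConfig = CriticConfig(),
                 neuron: HRParams = HRParams(),
                 n_in: int = 49):
        self.cfg = cfg
        self.syn = syn
        self.plast = plast
        self.critic_cfg = replace(critic, n_critic_neurons=cfg.n_critic)
        self.neuron = neuron
        self.n_in = n_in
        self.rng = np.random.default_rng(cfg.seed)
        self._trial_counter = 0
        self._tie_log: list[int] = []
        # the critic's running prediction of the feedback-window gate:
        # subtracting it centers the reinforcement signal so that at any
        # accuracy level correct trials potentiate and errors depress
        self._gate_baseline = 0.0
        self._gate_baseline_alpha = 0.1
        self._build()

    # -- wiring -----------------------------------------------------------

    def _build(self):
        cfg = self.cfg
        n2 = cfg.n_layer2
        self.n_exc = int(round(cfg.exc_fraction * n2))
        self.n_tot = n2 + cfg.n_out + cfg.n_critic
        rng = self.rng

        # rectangular grid for layer 2 and pairwise distance attenuation
        if cfg.grid_shape is None:
            side = int(np.ceil(np.sqrt(n2)))
            rows = int(np.ceil(n2 / side))
            self.grid_shape = (rows, side)
        else:
            self.grid_shape = cfg.grid_shape
        # a scale of ~2 grid spacings keeps recurrent coupling local;
        # this is what makes the layer's activity sparse rather than
        # epileptic once the whole population bursts together
        self.distance_scale = (cfg.distance_scale if cfg.distance_scale
                               is not None else 2.0)
        pos = np.column_stack(np.unravel_index(np.arange(n2),
                                               self.grid_shape)).astype(float)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        self.dist_factor = np.exp(-dist / self.distance_scale)

        # recurrent wiring: independent Bernoulli(p), no self-connections
        mask = rng.random((n2, n2)) < cfg.conn_prob
        np.fill_diagonal(mask, False)
        self.rec_mask = mask
        # weights are magnitudes drawn from N(0, sd): the *sign* of a
        # synapse comes from its transmitter (AMPA vs GABA), so the folded
        # magnitude keeps the excitation/inhibition balance physical
        self.W_rec = np.where(mask,
                              np.abs(rng.normal(0.0, cfg.weight_sd, (n2, n2))),
                              0.0)
        # fixed input projections: each ganglion cell reaches a random subset
        self.W_in = np.where(rng.random((self.n_in, n2)) < cfg.input_fanout,
                             cfg.j_ext, 0.0)
        # plastic projections to output and critic; each readout neuron
        # samples a sparse random subset of layer 2 so the outputs start
        # with distinct tuning for the reward loop to amplify
        self.W_out = np.where(
            rng.random((n2, cfg.n_out)) < cfg.out_sparsity,
            np.abs(rng.normal(0.0, cfg.weight_sd, (n2, cfg.n_out))), 0.0)
        self.W_crit = np.where(
            rng.random((n2, cfg.n_critic)) < cfg.out_sparsity,
            np.abs(rng.normal(0.0, cfg.weight_sd, (n2, cfg.n_critic))), 0.0)
        # homeostatic targets: each readout neuron keeps its total input
        # weight constant (synaptic scaling), so reinforcement reallocates
        # weight between presynaptic partners instead of inflating it.
        # Budgets are equalized across neurons so baseline excitability is
        # uniform and the winner reflects class tuning, not total weight.
        def _equalize(W):
            sums = W.sum(axis=0)
            budget = float(sums.mean())
            ok = sums > 1e-9
            W[:, ok] *= budget / sums[ok]
            return np.full(W.shape[1], budget)

        self._out_budget = _equalize(self.W_out)
        self._crit_budget = _equalize(self.W_crit)

        # per-target membrane constant and refractory period
        is_pyr = np.ones(self.n_tot, dtype=bool)
        is_pyr[self.n_exc:n2] = False  # layer-2 interneurons
        self.tau_m = np.where(is_pyr, self.syn.tau_m_pyr, self.syn.tau_m_int)
        refr = np.where(is_pyr, self.syn.tau_rp_pyr, self.syn.tau_rp_int)
        self.refr_steps = np.asarray(np.round(refr / cfg.dt), dtype=np.int64)

        # connection index lists for the learning updates (global indexing)
        pre, post = np.nonzero(mask)
        self.rec_pre, self.rec_post = pre.astype(np.int64), post.astype(np.int64)
        self.rec_src_exc = (self.rec_pre < self.n_exc)
        self.rec_post_inh = (self.rec_post >= self.n_exc) & (self.rec_post < n2)
        l2 = np.arange(n2, dtype=np.int64)
        self.out_pre = np.repeat(l2, cfg.n_out)
        self.out_post = n2 + np.tile(np.arange(cfg.n_out, dtype=np.int64), n2)
        self.out_src_exc = (self.out_pre < self.n_exc)
        self.out_post_inh = np.zeros(self.out_pre.size, dtype=bool)
        self.crit_pre = np.repeat(l2, cfg.n_critic)
        self.crit_post = (n2 + cfg.n_out
                          + np.tile(np.arange(cfg.n_critic, dtype=np.int64), n2))
        self.crit_src_exc = (self.crit_pre < self.n_exc)
        self.crit_post_inh = np.zeros(self.crit_pre.size, dtype=bool)

        # rest state of the driven neuron model at the bias current
        rest = simulate("lhr", self.neuron.with_current(cfg.I_bias),
                        NeuronState(-1.6, 0.0, 0.0), duration=500.0,
                        dt=cfg.dt)
        self.rest_state = (float(rest.x[-1]), float(rest.y[-1]),
                           float(rest.z[-1]))

        self._tables = (cube_table(), square_table(), exp_table())
        self._refresh_delivery()

    def _refresh_delivery(self):
        """Pre-scaled AMPA/GABA delivery matrices from current weights."""
        cfg = self.cfg
        n2, n_in = cfg.n_layer2, self.n_in
        n_src = n_in + n2
        WA = np.zeros((n_src, self.n_tot))
        WG = np.zeros((n_src, self.n_tot))
        kA = self.tau_m.astype(float)
        kG = self.tau_m.astype(float)
        WA[:n_in, :n2] = self.W_in * kA[:n2][None, :]
        rec_eff = self.W_rec * self.dist_factor
        # desk-scale gain: keeps the variance of the summed drive onto the
        # readout layers at its publication-scale (5000-neuron) level
        gain = (cfg.out_gain if cfg.out_gain is not None
                else float(np.sqrt(5000.0 / (cfg.out_sparsity * n2))))
        for j in range(n2):
            row = np.zeros(self.n_tot)
            row[:n2] = rec_eff[j]
            row[n2:n2 + cfg.n_out] = gain * self.W_out[j]
            row[n2 + cfg.n_out:] = gain * self.W_crit[j]
            if j < self.n_exc:
                WA[n_in + j] = row * kA
            else:
                WG[n_in + j] = row * kG
        self._WA, self._WG = WA, WG

    @property
    def n_recurrent_synapses(self) -> int:
        return int(self.rec_mask.sum())

    def weights_snapshot(self) -> dict:
        return {"W_rec": self.W_rec.copy(), "W_out": self.W_out.copy(),
                "W_crit": self.W_crit.copy()}

    # -- simulation -------------------------------------------------------

    def _simulate(self, spike_input: SpikeArray, n_steps: int,
                  fixed_point=None) -> np.ndarray:
        cfg = self.cfg
        n_src = self.n_in + cfg.n_layer2
        raster = np.zeros((self.n_in + self.n_tot, n_steps), dtype=np.uint8)
        for cell, train in enumerate(spike_input.trains):
            idx = np.minimum((train / cfg.dt).astype(np.int64), n_steps - 1)
            raster[cell, idx] = 1
        delay_steps = max(1, int(round(self.syn.tau_L / cfg.dt)))
        x0, y0, z0 = self.rest_state
        ct, st, _ = self._tables
        p = self.neuron
        if fixed_point is None:
            status = _kernel.run_network_float(
                n_steps, cfg.dt, raster, n_src, self.n_tot,
                self._WA, self._WG,
                self.syn.tau_dA, self.syn.tau_rA,
                self.syn.tau_dG, self.syn.tau_rG,
                p.a, p.b, p.c, p.d, p.r, p.s, p.q, cfg.I_bias,
                ct.breakpoints, ct.slopes, ct.intercepts,
                st.breakpoints, st.slopes, st.intercepts,
                x0, y0, z0, SPIKE_THRESHOLD, self.refr_steps, delay_steps,
                50.0, cfg.drive_sat)
            if status:
                raise RuntimeError("network integration blew up")
        else:
            fixed_point.run_network(self, raster, n_steps, delay_steps)
        return raster[self.n_in:]

    def run_trial(self, spike_input: SpikeArray, protocol: TrialProtocol,
                  learning: bool = False, feedback: bool = False,
                  label: int | None = None,
                  fixed_point=None) -> TrialRecord:
        """Present one pattern; optionally apply plasticity and reward."""
        cfg = self.cfg
        n2 = cfg.n_layer2
        n_steps = int(round(protocol.trial_duration / cfg.dt))
        raster = self._simulate(spike_input, n_steps, fixed_point)
        self._trial_counter += 1

        # events per neuron, restricted to the evaluation window
        t0 = protocol.transient_discard
        onsets, isi_mean = [], np.zeros(self.n_tot)
        burst_counts_out = np.zeros(cfg.n_out, dtype=int)
        n_spikes = 0
        for k in range(self.n_tot):
            times = (np.nonzero(raster[k])[0] + 1) * cfg.dt
            times = times[times >= t0]
            n_spikes += times.size
            b = detect_bursts(times, INTRA_BURST_ISI_MAX)
            onsets.append(b)
            if times.size >= 2:
                isi = np.diff(times)
                intra = isi[isi <= INTRA_BURST_ISI_MAX]
                isi_mean[k] = float(intra.mean()) if intra.size else 0.0
            if n2 <= k < n2 + cfg.n_out:
                burst_counts_out[k - n2] = b.size

        winner, tie = classify(burst_counts_out)
        if tie:
            self._tie_log.append(self._trial_counter)
        correct = None if label is None else bool(winner == label)

        # dopamine signal over trial + feedback period
        gate, v_value = self._dopamine_gate(onsets, protocol, correct,
                                            feedback)
        gate_centered = gate - self._gate_baseline
        l2_bursts = float(np.mean([onsets[k].size for k in range(n2)]))
        rec = TrialRecord(
            winner=winner, tie=tie, burst_counts=burst_counts_out,
            correct=correct, gate=gate, gate_centered=gate_centered,
            l2_burst_rate=l2_bursts / (protocol.eval_window / 1000.0),
            critic_value=v_value, n_spikes=n_spikes)

        if learning:
            self._apply_plasticity(onsets, isi_mean,
                                   gate_centered if feedback else 0.0)
            if feedback and correct is not None:
                a = self._gate_baseline_alpha
                self._gate_baseline = (1 - a) * self._gate_baseline + a * gate
        return rec

    def _dopamine_gate(self, onsets, protocol: TrialProtocol,
                       correct: bool | None, feedback: bool):
        """Mean (D - b_D) over the feedback window, plus the critic value."""
        cfg = self.cfg
        dt_d = 0.25  # ms; dopamine bookkeeping grid
        n_trial = int(round(protocol.trial_duration / dt_d))
        n_fb = int(round(protocol.feedback_window / dt_d))
        n = n_trial + n_fb
        # critic population burst rate, trailing 100 ms window, Hz
        crit_onsets = onsets[cfg.n_layer2 + cfg.n_out:]
        events = np.zeros(n)
        for b in crit_onsets:
            idx = np.minimum((np.asarray(b) / dt_d).astype(int), n_trial - 1)
            for i in idx:
                events[i] += 1.0
        win = int(round(100.0 / dt_d))
        kern = np.ones(win)
        counts = np.convolve(events, kern)[:n]
        v = counts / cfg.n_critic / (100.0 / 1000.0)  # Hz
        v_value = float(v[n_trial - 1])
        r = np.full(n, cfg.reward_baseline)
        if feedback and correct is not None:
            mult = 2.0 if correct else 0.0
            r[n_trial:] = cfg.reward_baseline * mult
        sig = dopamine(v, r, self.critic_cfg.tau_r, dt_d, self.critic_cfg)
        t_fb0 = n_trial * dt_d
        gate = sig.mean_gate(t0=t_fb0)
        return gate, v_value

    def _apply_plasticity(self, onsets, isi_mean, gate: float):
        p = self.plast
        flat = (np.concatenate([np.asarray(o, dtype=float) for o in onsets])
                if onsets else np.empty(0))
        offsets = np.zeros(len(onsets) + 1, dtype=np.int64)
        offsets[1:] = np.cumsum(np.array([len(o) for o in onsets],
                                         dtype=np.int64))
        _, _, table = self._tables
        args = (flat, offsets, isi_mean,
                p.A_plus, p.A_minus, p.gamma_plus, p.gamma_minus, p.tau,
                p.use_linear_exp, table.breakpoints, table.slopes,
                table.intercepts)

        # weights are transmitter magnitudes: clip to [0, w_max]
        dw = _kernel.pairing_sums(self.rec_pre, self.rec_post, args[0],
                                  args[1], args[2], self.rec_src_exc,
                                  self.rec_post_inh, *args[3:])
        if np.any(dw):
            self.W_rec[self.rec_pre, self.rec_post] = np.clip(
                self.W_rec[self.rec_pre, self.rec_post]
                + self.cfg.btdp_scale * dw, 0.0, p.w_max)

        if gate != 0.0 and flat.size:
            dw = (self.cfg.rbtdp_scale * gate
                  * _kernel.pairing_sums(self.out_pre, self.out_post,
                                         args[0], args[1], args[2],
                                         self.out_src_exc,
                                         self.out_post_inh, *args[3:]))
            n_out = self.cfg.n_out
            self.W_out = np.clip(
                self.W_out + dw.reshape(-1, n_out), 0.0, p.w_max)
            dw = (self.cfg.rbtdp_scale * gate
                  * _kernel.pairing_sums(self.crit_pre, self.crit_post,
                                         args[0], args[1], args[2],
                                         self.crit_src_exc,
                                         self.crit_post_inh, *args[3:]))
            self.W_crit = np.clip(
                self.W_crit + dw.reshape(-1, self.cfg.n_critic),
                0.0, p.w_max)
            self._normalize_readout()
        self._refresh_delivery()

    def _normalize_readout(self):
        for W, budget in ((self.W_out, self._out_budget),
                          (self.W_crit, self._crit_budget)):
            sums = W.sum(axis=0)
            ok = sums > 1e-9
            W[:, ok] *= budget[ok] / sums[ok]

    def calibrate_readout(self, spike_inputs, protocol: TrialProtocol,
                          n_rounds: int = 2):
        """Equalize baseline output responses by scaling readout columns.

        Runs frozen trials on the given spike inputs and rescales each
        output neuron's input weights toward the population-mean burst
        count — a stand-in for the slow homeostatic equilibration of
        intrinsic excitability that a long developmental run provides.
        Sampling heterogeneity otherwise leaves some outputs dominant for
        every pattern, hiding their class tuning from the winner rule.
        """
        for _ in range(n_rounds):
            counts = np.zeros(self.cfg.n_out)
            for sp in spike_inputs:
                rec = self.run_trial(sp, protocol, learning=False)
                counts += rec.burst_counts
            target = counts.mean()
            if target == 0:
                return
            scale = np.clip(target / np.maximum(counts, 0.5), 0.6, 1.8)
            self.W_out *= scale[None, :]
            self._out_budget = self.W_out.sum(axis=0)
            self._refresh_delivery()


def build(cfg: NetworkConfig, **kwargs) -> Network:
    """Construct a network instance from its configuration."""
    return Network(cfg, **kwargs)


def run_trial(network: Network, spike_input: SpikeArray,
              protocol: TrialProtocol, learning: bool = False,
              feedback: bool = False, label: int | None = None) -> TrialRecord:
    return network.run_trial(spike_input, protocol, learning=learning,
                             feedback=feedback, label=label)


def classify(burst_counts) -> tuple[int, bool]:
    """Winner-take-all on burst counts; ties resolve to the lowest index."""
    counts = np.asarray(burst_counts)
    winner = int(np.argmax(counts))
    tie = bool(np.sum(counts == counts[winner]) > 1)
    return winner, tie


def _encoder_for(network: Network, encoder: EncoderConfig, trial_seed: int,
                 protocol: TrialProtocol) -> EncoderConfig:
    return replace(encoder, seed=trial_seed,
                   duration=protocol.trial_duration)


def train(network: Network, dataset: PatternSet, protocol: TrialProtocol,
          encoder: EncoderConfig = EncoderConfig(),
          heldout: PatternSet | None = None,
          eval_repeats: int = 1,
          fixed_point=None) -> pd.DataFrame:
    """Run training epochs of randomized trials; returns the history.

    Each epoch presents the training patterns in random order with
    learning and reward feedback on, then (when a held-out set is given)
    measures accuracy with learning frozen.  When ``protocol.auto_stop``
    is set, training stops once the epoch-to-epoch accuracy improvement
    drops below the plateau threshold.
    """
    rng = np.random.default_rng(network.cfg.seed + 9973)
    rows = []
    prev_acc = None
    for epoch in range(protocol.epochs):
        order = rng.permutation(len(dataset))
        n_correct = 0
        mean_gate = 0.0
        for i in order:
            seed = int(rng.integers(0, 2**31 - 1))
            cfg_e = _encoder_for(network, encoder, seed, protocol)
            spikes = encode(dataset.images[i], cfg_e)
            rec = network.run_trial(spikes, protocol, learning=True,
                                    feedback=True,
                                    label=int(dataset.labels[i]),
                                    fixed_point=fixed_point)
            n_correct += bool(rec.correct)
            mean_gate += rec.gate
        train_acc = 100.0 * n_correct / len(dataset)
        row = {"epoch": epoch, "train_accuracy": train_acc,
               "mean_gate": mean_gate / len(dataset)}
        if heldout is not None:
            acc, _ = evaluate(network, heldout, protocol, encoder=encoder,
                              repeats=eval_repeats, fixed_point=fixed_point)
            row["heldout_accuracy"] = acc
        rows.append(row)
        acc_now = row.get("heldout_accuracy", train_acc)
        if (protocol.auto_stop and prev_acc is not None
                and acc_now - prev_acc < protocol.plateau_threshold):
            break
        prev_acc = acc_now
    return pd.DataFrame(rows)


def evaluate(network: Network, dataset: PatternSet, protocol: TrialProtocol,
             encoder: EncoderConfig = EncoderConfig(), repeats: int = 1,
             fixed_point=None) -> tuple[float, np.ndarray]:
    """Frozen-weight test accuracy (%) and row-normalized confusion matrix."""
    n_classes = network.cfg.n_out
    confusion = np.zeros((n_classes, n_classes))
    rng = np.random.default_rng(network.cfg.seed + 31337)
    n_correct, n_total = 0, 0
    for rep in range(repeats):
        for i in range(len(dataset)):
            seed = int(rng.integers(0, 2**31 - 1))
            cfg_e = _encoder_for(network, encoder, seed, protocol)
            spikes = encode(dataset.images[i], cfg_e)
            rec = network.run_trial(spikes, protocol, learning=False,
                                    feedback=False,
                                    fixed_point=fixed_point)
            label = int(dataset.labels[i])
            confusion[label, rec.winner] += 1
            n_correct += int(rec.winner == label)
            n_total += 1
    rowsum = confusion.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return 100.0 * n_correct / n_total, confusion / rowsum


# ---------------------------------------------------------------------------
# Model / Results surface.
# ---------------------------------------------------------------------------

@dataclass
class TrainingResults:
    """Outcome of fitting a :class:`BurstClassifier`."""

    history: pd.DataFrame
    accuracy: float
    confusion: np.ndarray
    network: Network = field(repr=False, default=None)
    protocol: TrialProtocol = None

    @property
    def n_epochs_run(self) -> int:
        return len(self.history)

    def summary(self) -> str:
        cfg = self.network.cfg
        lines = [
            "Burst-rate spiking classifier",
            "=" * 45,
            f"layer-2 neurons      : {cfg.n_layer2} "
            f"({self.network.n_exc} exc / {cfg.n_layer2 - self.network.n_exc} inh)",
            f"recurrent synapses   : {self.network.n_recurrent_synapses}",
            f"output neurons       : {cfg.n_out}",
            f"epochs run           : {self.n_epochs_run}",
            f"test accuracy        : {self.accuracy:.1f}%",
            "",
            "per-epoch history:",
            self.history.to_string(index=False),
            "",
            "confusion matrix (rows = true class):",
            np.array2string(self.confusion, precision=2),
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cols = [c for c in ("train_accuracy", "heldout_accuracy")
                if c in self.history]
        self.history.plot(x="epoch", y=cols, marker="o", ax=ax)
        ax.set_ylabel("accuracy (%)")
        return ax


class BurstClassifier:
    """Model object: a classification network fitted to a pattern set."""

    def __init__(self, config: NetworkConfig = NetworkConfig(),
                 protocol: TrialProtocol = TrialProtocol(),
                 encoder: EncoderConfig = EncoderConfig(),
                 plasticity: PlasticityParams = PlasticityParams(),
                 critic: CriticConfig = CriticConfig(),
                 n_in: int = 49):
        self.config = config
        self.protocol = protocol
        self.encoder = encoder
        self.network = Network(config, plast=plasticity, critic=critic,
                               n_in=n_in)

    def fit(self, train_set: PatternSet, test_set: PatternSet | None = None,
            eval_repeats: int = 1, calibrate: bool = False) -> TrainingResults:
        if calibrate:
            rng = np.random.default_rng(self.config.seed + 777)
            inputs = []
            for cls in np.unique(train_set.labels):
                idx = np.nonzero(train_set.labels == cls)[0]
                for k in range(min(2, idx.size)):
                    e = replace(self.encoder,
                                seed=int(rng.integers(0, 2**31 - 1)),
                                duration=self.protocol.trial_duration)
                    inputs.append(encode(train_set.images[idx[k]], e))
            self.network.calibrate_readout(inputs, self.protocol)
        history = train(self.network, train_set, self.protocol,
                        encoder=self.encoder, heldout=test_set,
                        eval_repeats=eval_repeats)
        final = test_set if test_set is not None else train_set
        accuracy, confusion = evaluate(self.network, final, self.protocol,
                                       encoder=self.encoder,
                                       repeats=eval_repeats)
        return TrainingResults(history=history, accuracy=accuracy,
                               confusion=confusion, network=self.network,
                               protocol=self.protocol)

    def evaluate(self, dataset: PatternSet, repeats: int = 1,
                 fixed_point=None) -> tuple[float, np.ndarray]:
        return evaluate(self.network, dataset, self.protocol,
                        encoder=self.encoder, repeats=repeats,
                        fixed_point=fixed_point)
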