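"""Actor-critic machinery: value readout, reward-prediction error, dopamine.

The critic is a small population (20 by default) of bursting neurons whose
population burst rate serves as the value estimate ``v(t)``.  The dopamine
variable

    D(t) = v_dot(t) + r(t) - v(t)/tau_r

acts as a continuous-time reward-prediction error; its time derivative
term is realized by two delayed pathways (an excitatory 1.5 ms and an
inhibitory 25 ms connection between the critic and a Poisson
reward-prediction population), emulated here as the finite difference
``(v(t - 1.5) - v(t - 25)) / 23.5``.  The plasticity gate is the deviation
of D from its trailing 10-ms mean baseline ``b_D``.

Reward is emulated through the firing of the dopamine source: a correct
classification doubles its rate for the reward window and a
misclassification silences it for 100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CriticConfig",
    "DopamineSignal",
    "rpe",
    "dopamine",
    "critic_value",
    "reward_emulation",
    "trailing_mean",
]


@dataclass(frozen=True)
class CriticConfig:
    n_critic_neurons: int = 20
    n_rpe_neurons: int = 1000
    exc_delay: float = 1.5   # ms
    inh_delay: float = 25.0  # ms
    gamma: float = 0.5       # discount factor
    tau_r: float = 200.0     # value leak time constant, ms
    baseline_window: float = 10.0  # ms, trailing mean for b_D

    def __post_init__(self):
        if self.n_critic_neurons <= 0 or self.n_rpe_neurons <= 0:
            raise ValueError("population counts must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.tau_r <= 0:
            raise ValueError("tau_r must be positive")


def rpe(r_next: float, v_next: float, v_now: float, gamma: float) -> float:
    """Temporal-difference reward-prediction error r + gamma*V' - V."""
    return r_next + gamma * v_next - v_now


def trailing_mean(series: np.ndarray, window: float, dt: float) -> np.ndarray:
    """Trailing windowed mean over ``(t - window, t]`` for each sample."""
    series = np.asarray(series, dtype=float)
    k = max(1, int(round(window / dt)))
    csum = np.concatenate(([0.0], np.cumsum(series)))
    idx = np.arange(1, series.size + 1)
    lo = np.maximum(0, idx - k)
    return (csum[idx] - csum[lo]) / (idx - lo)


@dataclass
class DopamineSignal:
    """D(t) and its moving-average baseline on a shared time grid."""

    times: np.ndarray
    D: np.ndarray
    b_D: np.ndarray

    @property
    def gate(self) -> np.ndarray:
        """The plasticity gate (D - b_D) per sample."""
        return self.D - self.b_D

    def mean_gate(self, t0: float | None = None, t1: float | None = None
                  ) -> float:
        m = np.ones(self.times.size, dtype=bool)
        if t0 is not None:
            m &= self.times >= t0
        if t1 is not None:
            m &= self.times < t1
        return float(np.mean(self.gate[m])) if m.any() else 0.0

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.D, self.b_D]),
                   header="t D b_D")


def dopamine(v_trace, r_trace, tau_r: float, dt: float,
             cfg: CriticConfig = CriticConfig()) -> DopamineSignal:
    """Dopamine variable from value and reward traces.

    ``v_dot`` uses the two delayed pathways as a finite difference; both
    delayed samples are clamped to the start of the trace until the delay
    lines fill, so ``v_dot`` is zero on a constant value trace from t = 0.
    """
    v = np.asarray(v_trace, dtype=float)
    r = np.asarray(r_trace, dtype=float)
    if v.shape != r.shape or v.ndim != 1:
        raise ValueError("value and reward traces must be equal-length 1-D")
    if tau_r <= 0:
        raise ValueError("tau_r must be positive")
    n = v.size
    k_exc = int(round(cfg.exc_delay / dt))
    k_inh = int(round(cfg.inh_delay / dt))
    idx = np.arange(n)
    v_exc = v[np.maximum(idx - k_exc, 0)]
    v_inh = v[np.maximum(idx - k_inh, 0)]
    v_dot = (v_exc - v_inh) / (cfg.inh_delay - cfg.exc_delay)
    D = v_dot + r - v / tau_r
    b_D = trailing_mean(D, cfg.baseline_window, dt)
    times = (idx + 1) * dt
    return DopamineSignal(times=times, D=D, b_D=b_D)


def critic_value(burst_onsets_per_neuron, window: float) -> float:
    """Population mean burst rate over the window, in events/second."""
    if window <= 0:
        raise ValueError("window must be positive")
    counts = [len(b) for b in burst_onsets_per_neuron]
    if not counts:
        return 0.0
    return float(np.mean(counts) / (window / 1000.0))


def reward_emulation(correct: bool | None,
                     silence_duration: float = 100.0) -> tuple[float, float]:
    """Firing-rate directive for the dopamine source population.

    Returns ``(rate_multiplier, duration_ms)``: doubled rate on a correct
    classification, silence for 100 ms on an incorrect one, unchanged when
    no feedback (``correct is None``).
    """
    if correct is None:
        return 1.0, 0.0
    if correct:
        return 2.0, silence_duration
    return 0.0, silence_duration
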