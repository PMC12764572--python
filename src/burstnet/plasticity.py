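"""Burst-timing-dependent plasticity (BTDP) and its dopamine-gated form.

BTDP updates a weight from the lag between pre- and postsynaptic *burst
onsets* (the inter-burst interval, IBI) with an exponential window whose
learning rate adapts to the mean inter-spike intervals of the two neurons:

    W(x) = (A+ + sigma/gamma+) * exp(-x/tau)   for x >= 0
    W(x) = (A- - sigma/gamma-) * exp(+x/tau)   otherwise

with ``sigma = mean ISI(post) - mean ISI(pre)``, A+ = 0.07, A- = -0.05,
gamma+ = 20, gamma- = 25, tau = 10 ms.  The total update sums W over all
pre/post burst pairings of the trial.  Reinforcement BTDP (RBTDP) gates
this sum by the deviation of the dopamine variable from its 10-ms baseline:
``dw = (D - b_D) * dw_btdp``.

The per-synapse network forms used inside the synaptic impulse brackets
differ in two details from the bare window: the depression learning rate is
printed as ``A- + sigma/gamma-`` there (the sign of the sigma term is
inconsistent between the two formulations in the source material; the
per-synapse forms are taken as normative for network learning while
``btdp_window`` keeps the bare form verbatim), GABA synapses (inhibitory
source) use the swapped branch order, and updates onto inhibitory
interneuron targets are scaled by 0.4.

Sign convention: ``IBI = t_burst_post - t_burst_pre``, so IBI > 0 (pre
leads post) selects the potentiation branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .approx import PiecewiseLinear, exp_table

__all__ = [
    "PlasticityParams",
    "BurstPairing",
    "sigma",
    "btdp_window",
    "btdp_delta",
    "rbtdp_delta",
    "synaptic_rate_modifier",
    "pairing_deltas",
]


@dataclass(frozen=True)
class PlasticityParams:
    A_plus: float = 0.07
    A_minus: float = -0.05
    gamma_plus: float = 20.0
    gamma_minus: float = 25.0
    tau: float = 10.0
    use_linear_exp: bool = False
    w_max: float = 5.0  # weight clip bound; runaway guard

    def exp_decay(self, lag: float, table: PiecewiseLinear | None = None
                  ) -> float:
        """``exp(-lag/tau)`` for lag >= 0, or its piecewise substitution."""
        if self.use_linear_exp:
            table = table if table is not None else _EXP_TABLE
            return float(table(lag))
        return math.exp(-lag / self.tau)


_EXP_TABLE = exp_table()


@dataclass(frozen=True)
class BurstPairing:
    """One pre/post burst-onset pairing within a trial."""

    ibi: float  # t_burst_post - t_burst_pre, ms, signed
    isi_pre_mean: float = 0.0
    isi_post_mean: float = 0.0

    @property
    def sigma(self) -> float:
        return self.isi_post_mean - self.isi_pre_mean


def sigma(isi_post_mean: float, isi_pre_mean: float) -> float:
    """ISI-based learning-rate modulation: post mean minus pre mean."""
    return isi_post_mean - isi_pre_mean


def btdp_window(x: float, sig: float, p: PlasticityParams = PlasticityParams()
                ) -> float:
    """The BTDP weight-change window W(x) at burst lag ``x`` (ms)."""
    if x >= 0:
        return (p.A_plus + sig / p.gamma_plus) * p.exp_decay(x)
    return (p.A_minus - sig / p.gamma_minus) * p.exp_decay(-x)


def btdp_delta(pairings, p: PlasticityParams = PlasticityParams()) -> float:
    """Total unsupervised update: sum of the window over all pairings."""
    return float(sum(btdp_window(pr.ibi, pr.sigma, p) for pr in pairings))


def rbtdp_delta(D: float, b_D: float, btdp_dw: float) -> float:
    """Dopamine-gated update ``(D - b_D) * dw``; vanishes at baseline."""
    return (D - b_D) * btdp_dw


def _network_rate(ibi: float, sig: float, p: PlasticityParams,
                  ampa: bool, post_inhibitory: bool) -> float:
    """Adaptive learning rate of the per-synapse forms (A~ or B~).

    The branch order follows the transmitter of the synapse being
    updated: AMPA synapses (excitatory source) potentiate for IBI > 0,
    GABA synapses (inhibitory source) use the swapped branches.  Updates
    onto inhibitory (interneuron) targets are scaled by 0.4.
    """
    if ampa:
        rate = (p.A_plus + sig / p.gamma_plus) if ibi > 0 else \
               (p.A_minus + sig / p.gamma_minus)
    else:
        rate = (p.A_minus + sig / p.gamma_minus) if ibi > 0 else \
               (p.A_plus + sig / p.gamma_plus)
    if post_inhibitory:
        rate *= 0.4
    return rate


def synaptic_rate_modifier(kind: str, pairing: BurstPairing,
                           p: PlasticityParams = PlasticityParams(),
                           D: float = 0.0, b_D: float = 0.0,
                           synapse: str = "ampa") -> float:
    """Weight increment added inside the synaptic impulse bracket.

    ``kind`` selects the postsynaptic population and learning block:
    ``exc_btdp`` / ``inh_btdp`` for second-layer targets (updates onto
    interneurons carry the 0.4 scale), ``exc_rbtdp`` / ``inh_rbtdp`` for
    the dopamine-gated output/critic projections.  ``synapse`` selects
    the transmitter ("ampa" or "gaba"), which sets the branch order of
    the adaptive rate.
    """
    kinds = ("exc_btdp", "inh_btdp", "exc_rbtdp", "inh_rbtdp")
    if kind not in kinds:
        raise ValueError(f"kind must be one of {kinds}")
    if synapse not in ("ampa", "gaba"):
        raise ValueError("synapse must be 'ampa' or 'gaba'")
    post_inh = kind.startswith("inh")
    rate = _network_rate(pairing.ibi, pairing.sigma, p,
                         synapse == "ampa", post_inh)
    dw = rate * p.exp_decay(abs(pairing.ibi))
    if kind.endswith("rbtdp"):
        dw *= (D - b_D)
    return dw


def pairing_deltas(pre_onsets, post_onsets, sig: float,
                   p: PlasticityParams, source_excitatory: bool,
                   post_inhibitory: bool = False,
                   gate: float | None = None) -> float:
    """Vectorized all-to-all pairing sum for one synapse.

    The branch order follows the source type (AMPA vs GABA) and the 0.4
    scale the target type; ``gate`` (D - b_D) switches the RBTDP form on.
    """
    pre = np.asarray(pre_onsets, dtype=float)
    post = np.asarray(post_onsets, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    ibi = post[None, :] - pre[:, None]
    pos = ibi > 0
    if source_excitatory:
        rate = np.where(pos, p.A_plus + sig / p.gamma_plus,
                        p.A_minus + sig / p.gamma_minus)
    else:
        rate = np.where(pos, p.A_minus + sig / p.gamma_minus,
                        p.A_plus + sig / p.gamma_plus)
    if post_inhibitory:
        rate = 0.4 * rate
    lag = np.abs(ibi)
    if p.use_linear_exp:
        decay = _EXP_TABLE(lag)
    else:
        decay = np.exp(-lag / p.tau)
    dw = float(np.sum(rate * decay))
    if gate is not None:
        dw *= gate
    return dw
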