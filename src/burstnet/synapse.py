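"""AMPA and GABA double-exponential synapse dynamics.

Each synapse filters delayed presynaptic spikes through a rise/decay pair

    tau_d * dI/dt = -I + x
    tau_r * dx/dt = -x + tau_m * factor * J * sum_k delta(t - t_k - tau_L)

so a spike arriving after the latency ``tau_L`` makes the auxiliary
variable jump by ``tau_m * factor * J`` (the discrete unit-pulse reading
of the spike train, as a digital datapath delivers it) and the current
``I`` then traces a double exponential.  ``factor = exp(-r/D)`` attenuates coupling with the
Euclidean grid distance ``r`` between the neurons.  The net drive delivered
to the postsynaptic neuron is ``I_A - I_G``.

Parameter defaults follow the standard cortical values: AMPA decay 2 ms /
rise 0.4 ms, GABA decay 5 ms / rise 1 ms, latency 1 ms, membrane constant
20 ms (pyramidal) or 10 ms (interneuron), refractory 2 ms / 1 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynParams",
    "SynapseState",
    "ampa_step",
    "gaba_step",
    "total_current",
    "distance_factor",
    "double_exp_response",
]


@dataclass(frozen=True)
class SynParams:
    """Synaptic time constants (ms)."""

    tau_m_pyr: float = 20.0
    tau_m_int: float = 10.0
    tau_dA: float = 2.0
    tau_rA: float = 0.4
    tau_dG: float = 5.0
    tau_rG: float = 1.0
    tau_L: float = 1.0
    tau_rp_pyr: float = 2.0
    tau_rp_int: float = 1.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SynapseState:
    """Filtered currents and auxiliaries of one connection."""

    I_A: float = 0.0
    x_A: float = 0.0
    I_G: float = 0.0
    x_G: float = 0.0
    J: float = 1.0
    delay: float = 1.0
    distance_factor: float = 1.0


def distance_factor(r: float, D: float) -> float:
    """Distance attenuation ``exp(-r/D)``; rejects nonpositive scale."""
    if D <= 0:
        raise ValueError("distance scale D must be positive")
    if r < 0:
        raise ValueError("distance r must be nonnegative")
    return math.exp(-r / D)


def _filter_step(I, x, tau_d, tau_r, dt, impulse):
    """Euler update of one rise/decay pair; impulse jumps x exactly."""
    I_new = I + dt * (-I + x) / tau_d
    x_new = x + dt * (-x) / tau_r + impulse
    return I_new, x_new


def ampa_step(st: SynapseState, p: SynParams, pre_spikes_at_t: int,
              dt: float, tau_m: float | None = None) -> SynapseState:
    """Advance the AMPA pair one step; ``pre_spikes_at_t`` impulses land now.

    The caller is responsible for the latency (spikes passed here are the
    ones whose delayed arrival falls in this step) and for refractory
    filtering at the source.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau_m = p.tau_m_pyr if tau_m is None else tau_m
    impulse = tau_m * st.distance_factor * st.J * pre_spikes_at_t
    I_A, x_A = _filter_step(st.I_A, st.x_A, p.tau_dA, p.tau_rA, dt, impulse)
    return SynapseState(I_A=I_A, x_A=x_A, I_G=st.I_G, x_G=st.x_G, J=st.J,
                        delay=st.delay, distance_factor=st.distance_factor)


def gaba_step(st: SynapseState, p: SynParams, pre_spikes_at_t: int,
              dt: float, tau_m: float | None = None) -> SynapseState:
    """Advance the GABA pair one step (mirror of :func:`ampa_step`)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau_m = p.tau_m_pyr if tau_m is None else tau_m
    impulse = tau_m * st.distance_factor * st.J * pre_spikes_at_t
    I_G, x_G = _filter_step(st.I_G, st.x_G, p.tau_dG, p.tau_rG, dt, impulse)
    return SynapseState(I_A=st.I_A, x_A=st.x_A, I_G=I_G, x_G=x_G, J=st.J,
                        delay=st.delay, distance_factor=st.distance_factor)


def total_current(I_A: float, I_G: float) -> float:
    """Net synaptic drive: excitatory minus inhibitory current."""
    return I_A - I_G


def double_exp_response(t, amplitude: float, tau_d: float, tau_r: float):
    """Closed-form current after a unit impulse jump of ``amplitude`` in x.

    Solves the rise/decay pair exactly:
    ``I(t) = A * tau_r/(tau_d - tau_r) * (exp(-t/tau_d) - exp(-t/tau_r))``.
    Used as the analytic oracle for the Euler integration tests.
    """
    t = np.asarray(t, dtype=float)
    if tau_d == tau_r:
        return amplitude * t / tau_d * np.exp(-t / tau_d)
    k = amplitude * tau_r / (tau_d - tau_r)
    return k * (np.exp(-t / tau_d) - np.exp(-t / tau_r))
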