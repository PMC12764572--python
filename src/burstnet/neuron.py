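"""Hindmarsh-Rose neuron, its piecewise-linear variant, and trace metrics.

The three-variable Hindmarsh-Rose (HR) model

    dx/dt = y - a*x^3 + b*x^2 - z + I
    dy/dt = c - d*x^2 - y
    dz/dt = r*(s*(x - q) - z)

produces spiking and square-wave bursting; ``x`` is the membrane potential,
``y`` the fast (Na/K) current and ``z`` the slow (Ca) current.  The linear
HR (LHR) variant replaces ``x^3`` and ``x^2`` with the piecewise-linear
tables from :mod:`burstnet.approx`, which is what the multiplier-less
digital datapath computes.  Integration is forward Euler with dt = 1/256,
and one dimensionless HR time unit is treated as 1 ms so that neuron and
synapse time constants share a clock.

A caveat that matters when comparing the two models: the printed tables
make the LHR rest state near x = -1.30 weakly *stable* at I = 1.5 (the
fast-subsystem determinant C' + 2*S' evaluates to +0.61 from the chord
slopes where the true HR value 3x^2 + 4x = -0.13 is negative), so the LHR
settles to rest after its initial spiking transient instead of bursting
indefinitely.  At I = 2 both models burst recurrently.  See
``docs/methods.md`` for the full analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .approx import PiecewiseLinear, cube_table, square_table

__all__ = [
    "HRParams",
    "NeuronState",
    "NeuronTrace",
    "TraceMetrics",
    "hr_derivs",
    "lhr_derivs",
    "euler_step",
    "simulate",
    "detect_spikes",
    "detect_bursts",
    "compare_traces",
    "DEFAULT_DT",
    "SPIKE_THRESHOLD",
    "INTRA_BURST_ISI_MAX",
]

DEFAULT_DT = 1.0 / 256.0
#: upward-crossing threshold on x for spike detection (model scale ~[-1.6, 2.2])
SPIKE_THRESHOLD = 0.8
#: spikes closer than this (ms) belong to the same burst; the bursting
#: HR at I = 1.5..2 has intra-burst ISIs of 8-30 ms and quiescent gaps
#: of several hundred ms, so 50 ms separates the two regimes cleanly
INTRA_BURST_ISI_MAX = 50.0
#: integration is declared blown up beyond this |x|
BLOWUP_GUARD = 50.0


@dataclass(frozen=True)
class HRParams:
    """HR model constants; defaults give burst firing."""

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    r: float = 0.001
    s: float = 4.0
    q: float = -1.618
    I: float = 0.0

    def with_current(self, I: float) -> "HRParams":
        return replace(self, I=I)


@dataclass(frozen=True)
class NeuronState:
    x: float = -1.0
    y: float = 0.0
    z: float = 0.0

    def as_tuple(self):
        return (self.x, self.y, self.z)


def hr_derivs(st: NeuronState, p: HRParams):
    """Exact HR right-hand side at state ``st``."""
    x, y, z = st.x, st.y, st.z
    dx = y - p.a * x ** 3 + p.b * x * x - z + p.I
    dy = p.c - p.d * x * x - y
    dz = p.r * (p.s * (x - p.q) - z)
    return dx, dy, dz


def lhr_derivs(st: NeuronState, p: HRParams,
               cube: PiecewiseLinear | None = None,
               square: PiecewiseLinear | None = None):
    """LHR right-hand side: table lookups replace the power terms."""
    cube = cube if cube is not None else cube_table()
    square = square if square is not None else square_table()
    x, y, z = st.x, st.y, st.z
    x3 = float(cube(x))
    x2 = float(square(x))
    dx = y - p.a * x3 + p.b * x2 - z + p.I
    dy = p.c - p.d * x2 - y
    dz = p.r * (p.s * (x - p.q) - z)
    return dx, dy, dz


def euler_step(st: NeuronState, derivs_fn, dt: float) -> NeuronState:
    """One forward-Euler update ``s[n+1] = s[n] + dt * f(s[n])``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dx, dy, dz = derivs_fn(st)
    return NeuronState(st.x + dt * dx, st.y + dt * dy, st.z + dt * dz)


# ---------------------------------------------------------------------------
# Compiled single-neuron integrators.
# ---------------------------------------------------------------------------

@njit(cache=False)
def _pw_eval_scalar(bp, a, b, x):
    i = np.searchsorted(bp, x, side="right")
    return a[i] * x + b[i]


@njit(cache=False)
def _simulate_hr(n_steps, dt, x, y, z, a, b, c, d, r, s, q, I, use_tables,
                 cbp, ca, cb, sbp, sa, sb, guard):
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    zs = np.empty(n_steps)
    for i in range(n_steps):
        if use_tables:
            x3 = _pw_eval_scalar(cbp, ca, cb, x)
            x2 = _pw_eval_scalar(sbp, sa, sb, x)
        else:
            x3 = x * x * x
            x2 = x * x
        dx = y - a * x3 + b * x2 - z + I
        dy = c - d * x2 - y
        dz = r * (s * (x - q) - z)
        x += dt * dx
        y += dt * dy
        z += dt * dz
        if abs(x) > guard:
            return xs[:i], ys[:i], zs[:i], True
        xs[i] = x
        ys[i] = y
        zs[i] = z
    return xs, ys, zs, False


class IntegrationError(RuntimeError):
    """Raised when the state leaves the blow-up guard range."""


@dataclass
class NeuronTrace:
    """A simulated voltage trace with derived spike/burst events."""

    dt: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    spike_times: np.ndarray = field(default=None)
    burst_onsets: np.ndarray = field(default=None)

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.x.size + 1) * self.dt

    @property
    def duration(self) -> float:
        return self.x.size * self.dt

    def detect_events(self, threshold: float = SPIKE_THRESHOLD,
                      intra_burst_isi_max: float = INTRA_BURST_ISI_MAX):
        self.spike_times = detect_spikes(self, threshold)
        self.burst_onsets = detect_bursts(self.spike_times,
                                          intra_burst_isi_max)
        return self

    def window(self, t0: float, t1: float) -> "NeuronTrace":
        """Sub-trace on ``[t0, t1)`` with events re-derived."""
        i0, i1 = int(round(t0 / self.dt)), int(round(t1 / self.dt))
        return NeuronTrace(self.dt, self.x[i0:i1], self.y[i0:i1],
                           self.z[i0:i1]).detect_events()

    def to_text(self, path) -> None:
        """Columnar t/x/y/z text dump."""
        arr = np.column_stack([self.times, self.x, self.y, self.z])
        np.savetxt(path, arr, header="t x y z")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["dt"] = self.dt
            for name in ("x", "y", "z"):
                fh.create_dataset(name, data=getattr(self, name))


def simulate(model: str, p: HRParams, ic: NeuronState = NeuronState(),
             duration: float = 2000.0, dt: float = DEFAULT_DT,
             cube: PiecewiseLinear | None = None,
             square: PiecewiseLinear | None = None) -> NeuronTrace:
    """Integrate a single ``'hr'`` or ``'lhr'`` neuron at constant current.

    Returns the trace with spike times and burst onsets populated.
    Raises :class:`IntegrationError` on numerical blow-up.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    model = model.lower()
    if model not in ("hr", "lhr"):
        raise ValueError(f"unknown model {model!r}")
    use_tables = model == "lhr"
    ct = cube if cube is not None else cube_table()
    st = square if square is not None else square_table()
    n_steps = int(round(duration / dt))
    xs, ys, zs, blew_up = _simulate_hr(
        n_steps, dt, ic.x, ic.y, ic.z,
        p.a, p.b, p.c, p.d, p.r, p.s, p.q, p.I, use_tables,
        ct.breakpoints, ct.slopes, ct.intercepts,
        st.breakpoints, st.slopes, st.intercepts, BLOWUP_GUARD)
    if blew_up:
        raise IntegrationError(
            f"|x| exceeded {BLOWUP_GUARD} at t={xs.size * dt:.3f}")
    return NeuronTrace(dt, xs, ys, zs).detect_events()


# ---------------------------------------------------------------------------
# Event extraction.
# ---------------------------------------------------------------------------

def detect_spikes(trace, threshold: float = SPIKE_THRESHOLD) -> np.ndarray:
    """Times of upward threshold crossings of the membrane potential.

    ``trace`` may be a :class:`NeuronTrace` or a bare x-series sampled at
    ``DEFAULT_DT`` (pass a trace for any other dt).
    """
    if isinstance(trace, NeuronTrace):
        x, dt = trace.x, trace.dt
    else:
        x, dt = np.asarray(trace, dtype=float), DEFAULT_DT
    if x.size < 2:
        return np.empty(0)
    up = np.nonzero((x[1:] >= threshold) & (x[:-1] < threshold))[0] + 1
    return (up + 1) * dt


def detect_bursts(spike_times, intra_burst_isi_max: float = INTRA_BURST_ISI_MAX
                  ) -> np.ndarray:
    """First-spike times of groups whose consecutive ISIs stay short."""
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return np.empty(0)
    if np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted")
    gaps = np.diff(st) > intra_burst_isi_max
    onsets = np.concatenate(([st[0]], st[1:][gaps]))
    return onsets


# ---------------------------------------------------------------------------
# Trace comparison metrics.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceMetrics:
    """Similarity of a test trace to a reference trace."""

    nmae: float
    correlation: float
    nrmse: float
    nfd_spike: float
    nfd_burst: float

    def as_dict(self) -> dict:
        return {
            "nmae": self.nmae,
            "correlation": self.correlation,
            "nrmse": self.nrmse,
            "nfd_spike": self.nfd_spike,
            "nfd_burst": self.nfd_burst,
        }


def _nfd(ref_events: np.ndarray, test_events: np.ndarray, window: float
         ) -> float:
    """Normalized frequency difference between two event trains.

    Mean event rates over the window, normalized by the peak instantaneous
    rate of the reference train (reciprocal of its shortest interval); the
    mean reference rate is the fallback normalizer when fewer than two
    reference events exist.
    """
    f_ref = ref_events.size / window
    f_test = test_events.size / window
    if f_ref == 0 and f_test == 0:
        return 0.0
    if ref_events.size >= 2:
        f_norm = 1.0 / np.min(np.diff(ref_events))
    else:
        f_norm = max(f_ref, f_test)
    return float(abs(f_ref - f_test) / f_norm)


def compare_traces(ref: NeuronTrace, test: NeuronTrace) -> TraceMetrics:
    """NMAE, Pearson correlation, NRMSE and spike/burst NFD of x-series."""
    if ref.x.size != test.x.size or ref.dt != test.dt:
        raise ValueError("traces must share dt and length")
    mx = np.max(ref.x)
    diff = ref.x - test.x
    nmae = float(np.mean(np.abs(diff)) / mx)
    nrmse = float(np.sqrt(np.mean((diff / mx) ** 2)))
    if np.ptp(ref.x) == 0 or np.ptp(test.x) == 0:
        corr = 1.0 if np.allclose(ref.x, test.x) else 0.0
    else:
        corr = float(np.corrcoef(ref.x, test.x)[0, 1])
    if ref.spike_times is None:
        ref.detect_events()
    if test.spike_times is None:
        test.detect_events()
    window = ref.duration
    return TraceMetrics(
        nmae=nmae, correlation=corr, nrmse=nrmse,
        nfd_spike=_nfd(ref.spike_times, test.spike_times, window),
        nfd_burst=_nfd(ref.burst_onsets, test.burst_onsets, window),
    )
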