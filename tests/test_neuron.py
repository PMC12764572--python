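"""HR/LHR dynamics, Euler integration, event extraction, trace metrics."""

import numpy as np
import pytest

from burstnet.neuron import (HRParams, NeuronState, hr_derivs, lhr_derivs,
                             euler_step, simulate, detect_spikes,
                             detect_bursts, compare_traces, NeuronTrace)


DEFAULTS = HRParams()


class TestDerivatives:
    def test_hr_at_origin(self):
        dx, dy, dz = hr_derivs(NeuronState(0, 0, 0), DEFAULTS)
        assert dx == 0.0
        assert dy == 1.0
        assert dz == pytest.approx(0.001 * 4 * 1.618)

    def test_hr_at_unit_x(self):
        p = DEFAULTS
        dx, dy, dz = hr_derivs(NeuronState(1, 0, 0), p)
        assert dx == pytest.approx(-1 + 3)
        assert dy == pytest.approx(1 - 5)
        assert dz == pytest.approx(p.r * p.s * (1 - p.q))

    def test_dz_vanishes_on_z_nullcline(self, rng):
        p = DEFAULTS
        for x in rng.uniform(-2, 2, 5):
            z = p.s * (x - p.q)
            _, _, dz = hr_derivs(NeuronState(x, 0.0, z), p)
            assert dz == pytest.approx(0.0, abs=1e-14)

    def test_lhr_matches_hr_at_origin(self):
        assert lhr_derivs(NeuronState(0, 0, 0), DEFAULTS) == \
            hr_derivs(NeuronState(0, 0, 0), DEFAULTS)

    def test_lhr_uses_table_values_at_x2(self):
        # at x = 2 the tables give 6.63 and 3.721 in place of 8 and 4
        dx, dy, _ = lhr_derivs(NeuronState(2, 0, 0), DEFAULTS)
        assert dx == pytest.approx(0 - 1 * 6.63 + 3 * 3.721 - 0 + 0)
        assert dy == pytest.approx(1 - 5 * 3.721)

    def test_lhr_deviation_bounded_by_table_errors(self, tables):
        # |dx_lhr - dx_hr| <= a*eps3 + b*eps2 pointwise (triangle bound)
        xg = np.linspace(-2, 2, 801)
        eps3 = np.abs(tables["cube"](xg) - xg ** 3)
        eps2 = np.abs(tables["square"](xg) - xg ** 2)
        for x, e3, e2 in zip(xg[::50], eps3[::50], eps2[::50]):
            st = NeuronState(float(x), 0.3, -0.2)
            dxh = hr_derivs(st, DEFAULTS)[0]
            dxl = lhr_derivs(st, DEFAULTS)[0]
            assert abs(dxl - dxh) <= DEFAULTS.a * e3 + DEFAULTS.b * e2 + 1e-12


class TestEuler:
    def test_single_step_hand_arithmetic(self):
        p = DEFAULTS.with_current(1.5)
        st = euler_step(NeuronState(0, 0, 0),
                        lambda s: hr_derivs(s, p), 1.0 / 256)
        assert st.x == pytest.approx(1.5 / 256)
        assert st.y == pytest.approx(1.0 / 256)
        assert st.z == pytest.approx(0.001 * 4 * 1.618 / 256)

    def test_two_steps_compose(self):
        p = DEFAULTS.with_current(1.0)
        f = lambda s: hr_derivs(s, p)
        a = euler_step(euler_step(NeuronState(-1, 0, 0), f, 0.01), f, 0.01)
        b = NeuronState(-1, 0, 0)
        for _ in range(2):
            b = euler_step(b, f, 0.01)
        assert a == b

    def test_small_dt_limit(self):
        p = DEFAULTS
        st = euler_step(NeuronState(-1, 0.5, 0.1),
                        lambda s: hr_derivs(s, p), 1e-12)
        assert st.x == pytest.approx(-1, abs=1e-9)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            euler_step(NeuronState(), lambda s: (0, 0, 0), 0.0)


class TestSimulate:
    def test_hr_bursts_recurrently_at_I15(self):
        tr = simulate("hr", DEFAULTS.with_current(1.5), duration=2000.0)
        assert tr.burst_onsets.size >= 2

    def test_rest_neuron_is_silent(self):
        # start from the settled rest state at I=0: no spikes
        warm = simulate("hr", DEFAULTS, NeuronState(-1.6, 0, 0),
                        duration=500.0)
        ic = NeuronState(warm.x[-1], warm.y[-1], warm.z[-1])
        tr = simulate("hr", DEFAULTS, ic, duration=500.0)
        assert tr.spike_times.size == 0

    def test_determinism(self):
        a = simulate("lhr", DEFAULTS.with_current(2.0), duration=300.0)
        b = simulate("lhr", DEFAULTS.with_current(2.0), duration=300.0)
        np.testing.assert_array_equal(a.x, b.x)

    @pytest.mark.parametrize("model", ["hr", "lhr"])
    @pytest.mark.parametrize("current", [0.0, 1.5, 3.0])
    def test_bounded_trajectories(self, model, current):
        tr = simulate(model, DEFAULTS.with_current(current),
                      NeuronState(-1.0, 0, 0), duration=5000.0)
        assert np.max(np.abs(tr.x)) < 5.0

    def test_dt_refinement_stays_close(self):
        # halving dt must leave the slow variable and the event statistics
        # nearly unchanged (the fast spike phases are chaotic and do not
        # converge pointwise, so the waveform NRMSE is not the right lens)
        coarse = simulate("hr", DEFAULTS.with_current(1.5),
                          duration=2000.0, dt=1 / 256)
        fine = simulate("hr", DEFAULTS.with_current(1.5),
                        duration=2000.0, dt=1 / 512)
        sub = NeuronTrace(1 / 256, fine.x[1::2], fine.y[1::2],
                          fine.z[1::2]).detect_events()
        z_nrmse = np.sqrt(np.mean((coarse.z - sub.z) ** 2)) / np.max(coarse.z)
        assert z_nrmse < 0.05
        m = compare_traces(coarse, sub)
        assert m.nfd_spike < 0.05
        assert m.nfd_burst < 0.05

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            simulate("izhikevich", DEFAULTS, duration=1.0)


class TestEvents:
    def test_constant_trace_has_no_spikes(self):
        assert detect_spikes(np.zeros(1000)).size == 0

    def test_single_pulse_single_event(self):
        x = np.concatenate([np.zeros(100), np.linspace(0, 1.5, 50),
                            np.linspace(1.5, 0, 50), np.zeros(100)])
        assert detect_spikes(x, threshold=0.8).size == 1

    def test_spikes_per_burst_at_least_two(self):
        tr = simulate("hr", DEFAULTS.with_current(1.5), duration=2000.0)
        edges = np.concatenate([tr.burst_onsets, [np.inf]])
        for lo, hi in zip(edges[:-1], edges[1:]):
            n = np.sum((tr.spike_times >= lo) & (tr.spike_times < hi))
            assert n >= 2

    def test_burst_grouping(self):
        onsets = detect_bursts([0.0, 1.0, 2.0, 100.0, 101.0],
                               intra_burst_isi_max=10.0)
        np.testing.assert_allclose(onsets, [0.0, 100.0])

    def test_empty_and_sorted_contracts(self):
        assert detect_bursts([]).size == 0
        with pytest.raises(ValueError):
            detect_bursts([2.0, 1.0])

    def test_grouping_is_idempotent(self):
        onsets = detect_bursts([0.0, 1.0, 2.0, 100.0, 101.0, 300.0], 10.0)
        np.testing.assert_allclose(detect_bursts(onsets, 10.0), onsets)


class TestCompare:
    def test_self_comparison_is_identity_tuple(self):
        tr = simulate("hr", DEFAULTS.with_current(1.5), duration=300.0)
        m = compare_traces(tr, tr)
        assert (m.nmae, m.nrmse, m.nfd_spike, m.nfd_burst) == (0, 0, 0, 0)
        assert m.correlation == pytest.approx(1.0)

    def test_rejects_mismatched_traces(self):
        a = simulate("hr", DEFAULTS.with_current(1.5), duration=100.0)
        b = simulate("hr", DEFAULTS.with_current(1.5), duration=50.0)
        with pytest.raises(ValueError):
            compare_traces(a, b)

    def test_trace_io_roundtrip(self, tmp_path):
        tr = simulate("lhr", DEFAULTS.with_current(2.0), duration=20.0)
        path = tmp_path / "trace.txt"
        tr.to_text(path)
        data = np.loadtxt(path)
        np.testing.assert_allclose(data[:, 1], tr.x)
        tr.to_hdf5(tmp_path / "trace.h5")
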