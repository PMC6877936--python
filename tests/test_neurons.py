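"""AdEx single-neuron dynamics: derivatives, spike/reset, integrator accuracy."""

import math

import numpy as np
import pytest

from dgsim.neurons import CELL_PARAMS, NeuronParams, NeuronState, derivative, first_spike_time, step


class TestDerivative:
    def test_gc_rest_is_fixed_point(self):
        """Hard-threshold GC at rest with no input has zero drift."""
        p = CELL_PARAMS["GC"]
        dv, dw = derivative(NeuronState(Vm=p.El), p, 0.0, 0.0)
        assert dv == 0.0 and dw == 0.0

    def test_mc_rest_drift_equals_exponential_term(self):
        """At Vm = El the only current is the spike-initiation term.

        For the mossy cell: gl*DeltaT*exp((El-VT)/DeltaT) = 9.06*exp(-11) pA
        over Cm = 621 pF.
        """
        p = CELL_PARAMS["MC"]
        dv, dw = derivative(NeuronState(Vm=-64.0), p, 0.0, 0.0)
        expected = 4.530 * 2.0 * math.exp((-64.0 + 42.0) / 2.0) / (0.6210 * 1000.0)
        assert dv == pytest.approx(expected, rel=1e-12)
        assert dw == 0.0

    @pytest.mark.parametrize("cell", ["GC", "MC", "BC", "HC"])
    def test_adaptation_decays_at_rest(self, cell):
        p = CELL_PARAMS[cell]
        _, dw = derivative(NeuronState(Vm=p.El, w=10.0), p, 0.0, 0.0)
        assert dw == pytest.approx(-10.0 / p.tau_w)

    def test_nonfinite_input_rejected(self):
        p = CELL_PARAMS["GC"]
        with pytest.raises(ValueError):
            derivative(NeuronState(Vm=p.El), p, float("nan"), 0.0)


class TestStepAndReset:
    def test_spike_resets_voltage_and_bumps_adaptation(self):
        """GC above threshold: Vm -> -74 mV, w += 45 pA, spike flagged."""
        p = CELL_PARAMS["GC"]
        state = NeuronState(Vm=-55.0, w=0.0)
        new, spiked = step(state, p, 0.0, 0.0, 0.1, t=5.0)
        assert spiked
        assert new.Vm == p.Vreset == -74.0
        # w gets one Euler update (alpha*(Vm-El)/tau_w * dt) plus the jump b
        drift = 0.1 * p.alpha * (-55.0 - p.El) / p.tau_w
        assert new.w == pytest.approx(p.b + drift, abs=1e-9)
        assert new.last_spike == pytest.approx(5.1)

    def test_resting_neuron_stays_quiet(self):
        p = CELL_PARAMS["GC"]
        state = NeuronState(Vm=p.El)
        for _ in range(1000):
            state, spiked = step(state, p, 0.0, 0.0, 0.1)
            assert not spiked
        assert state.Vm == pytest.approx(p.El, abs=1e-9)

    def test_reset_invariant_every_spike(self):
        """After every reset Vm = Vreset exactly and w jumps by exactly b."""
        p = CELL_PARAMS["HC"]
        state = NeuronState(Vm=p.El)
        n_spikes = 0
        for _ in range(50000):
            pre = state
            state, spiked = step(state, p, 0.0, 100.0, 0.02)
            if spiked:
                n_spikes += 1
                assert state.Vm == p.Vreset
                _, dw = derivative(pre, p, 0.0, 100.0)
                assert state.w == pytest.approx(pre.w + 0.02 * dw + p.b, abs=1e-12)
        assert n_spikes > 5

    def test_bad_dt_rejected(self):
        p = CELL_PARAMS["GC"]
        with pytest.raises(ValueError):
            step(NeuronState(Vm=p.El), p, 0.0, 0.0, 0.0)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(gl=-1.0), dict(Cm=0.0), dict(Vreset=-40.0), dict(DeltaT=-1.0), dict(tau_w=0.0)],
    )
    def test_invariants_enforced(self, kw):
        base = dict(El=-60.0, gl=1.0, Cm=0.1, Vreset=-70.0, Vthr=-50.0,
                    DeltaT=2.0, alpha=1.0, tau_w=100.0, b=10.0)
        base.update(kw)
        with pytest.raises(ValueError):
            NeuronParams(**base)


class TestIntegratorConvergence:
    def test_bc_first_spike_converges_with_dt(self):
        """Production step (0.1 ms) matches the 1 us reference within 1 ms."""
        p = CELL_PARAMS["BC"]
        coarse = first_spike_time(p, 300.0, 0.1, 200.0)
        fine = first_spike_time(p, 300.0, 1e-3, 200.0)
        assert coarse is not None and fine is not None
        assert abs(coarse - fine) < 1.0

    def test_halving_dt_shrinks_error(self):
        """First-order convergence: halving dt roughly halves the latency error."""
        p = CELL_PARAMS["HC"]
        ref = first_spike_time(p, 100.0, 1e-3, 200.0)
        err = {dt: abs(first_spike_time(p, 100.0, dt, 200.0) - ref) for dt in (0.2, 0.1, 0.05)}
        assert err[0.05] <= err[0.2] + 1e-9
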