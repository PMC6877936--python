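"""Conductance kinetics, synaptic current sign conventions, and STDP."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgsim.synapses import (
    STDPParams,
    Synapse,
    SynapseParams,
    apply_stdp,
    conductance_at,
    effective_gmax,
    stdp_delta,
    synaptic_current,
)

AMPA = SynapseParams(gmax=10.0, receptor="AMPA")


class TestConductance:
    @pytest.mark.parametrize(
        "offset,expected",
        [
            (1.0, 0.0),                       # before the delay elapses
            (2.0, 10.0),                      # instantaneous rise at delay
            (8.0, 10.0 * math.exp(-1.0)),     # one decay constant later
        ],
    )
    def test_single_spike_profile(self, offset, expected):
        assert conductance_at(100.0 + offset, 100.0, AMPA) == pytest.approx(expected)

    def test_nonnegative_and_decaying(self):
        ts = np.linspace(0.0, 50.0, 400)
        g = np.array([conductance_at(t, 0.0, AMPA) for t in ts])
        assert (g >= 0).all()
        after = g[ts >= AMPA.t_delay]
        assert (np.diff(after) <= 1e-12).all()

    def test_receptor_reversal_pinned(self):
        assert SynapseParams(gmax=1.0, receptor="AMPA").Esyn == 0.0
        assert SynapseParams(gmax=1.0, receptor="GABA").Esyn == -80.0
        with pytest.raises(ValueError):
            SynapseParams(gmax=1.0, receptor="NMDA")


class TestSynapticCurrent:
    def test_zero_driving_force_at_reversal(self):
        assert synaptic_current(0.0, 5.0, -80.0) == 0.0

    def test_ampa_depolarizes(self):
        assert synaptic_current(1.0, 0.0, -70.0) == pytest.approx(+70.0)

    def test_gaba_hyperpolarizes(self):
        assert synaptic_current(0.0, 2.0, -60.0) == pytest.approx(-40.0)

    def test_linear_in_conductance(self):
        one = synaptic_current(1.0, 0.0, -55.0)
        assert synaptic_current(3.0, 0.0, -55.0) == pytest.approx(3 * one)


class TestEffectiveGmax:
    def test_weight_scales_plastic_synapses_only(self):
        stdp = STDPParams()
        plastic = Synapse(pre=0, post=0, params=AMPA, weight=2.0, plastic=True)
        fixed = Synapse(pre=0, post=0, params=AMPA, weight=2.0, plastic=False)
        assert effective_gmax(plastic, stdp) == pytest.approx(20.0)
        assert effective_gmax(fixed, stdp) == pytest.approx(10.0)
        plastic.weight = 0.0
        assert effective_gmax(plastic, stdp) == 0.0


class TestSTDPDelta:
    def test_ceiling_blocks_potentiation(self):
        p = STDPParams()
        assert stdp_delta(p.w_max, 5.0, p, causal=True) == 0.0

    def test_causal_at_tau_plus(self):
        p = STDPParams()
        assert stdp_delta(1.0, 20.0, p, causal=True) == pytest.approx(
            (2.0 - 1.0) * 0.1 * math.exp(-1.0))

    def test_acausal_at_tau_minus(self):
        p = STDPParams()
        assert stdp_delta(1.0, 12.0, p, causal=False) == pytest.approx(
            -1.0 * 0.1 * math.exp(-1.0))

    def test_invalid_weight_rejected(self):
        p = STDPParams()
        with pytest.raises(ValueError):
            stdp_delta(2.5, 1.0, p, causal=True)

    @given(w=st.floats(0.0, 2.0), lag=st.floats(0.0, 200.0))
    @settings(max_examples=100, deadline=None)
    def test_regime_signs(self, w, lag):
        """Causal pairings never decrease w; acausal never increase it."""
        p = STDPParams()
        assert stdp_delta(w, lag, p, causal=True) >= 0.0
        assert stdp_delta(w, lag, p, causal=False) <= 0.0


def _plastic(w=1.0):
    return Synapse(pre=0, post=1, params=AMPA, weight=w, plastic=True)


class TestApplySTDP:
    def test_no_post_spikes_leaves_weight(self):
        syn = apply_stdp(_plastic(), [10.0, 30.0], [], STDPParams())
        assert syn.weight == 1.0

    def test_single_causal_pairing(self):
        syn = apply_stdp(_plastic(), [10.0], [30.0], STDPParams())
        assert syn.weight == pytest.approx(1.0 + (2.0 - 1.0) * 0.1 * math.exp(-1.0))

    def test_non_plastic_pathway_rejected(self):
        syn = Synapse(pre=0, post=1, params=AMPA, weight=1.0, plastic=False)
        with pytest.raises(ValueError):
            apply_stdp(syn, [1.0], [2.0], STDPParams())

    @given(
        pre=st.lists(st.floats(0.0, 500.0), max_size=30),
        post=st.lists(st.floats(0.0, 500.0), max_size=30),
        w0=st.floats(0.0, 2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_weight_stays_bounded(self, pre, post, w0):
        p = STDPParams()
        syn = apply_stdp(_plastic(w0), sorted(pre), sorted(post), p)
        assert 0.0 <= syn.weight <= p.w_max

    def test_matches_explicit_event_replay(self, rng):
        """Interleaved trains agree with an independent step-by-step oracle."""
        p = STDPParams()
        pre = np.sort(rng.uniform(0, 300, 25)).tolist()
        post = np.sort(rng.uniform(0, 300, 25)).tolist()
        # oracle: explicit chronological replay of the nearest-neighbour rule
        w = 1.0
        lp = lpost = None
        for t, kind in sorted([(t, "pre") for t in pre] + [(t, "post") for t in post]):
            if kind == "pre":
                if lpost is not None:
                    w = max(0.0, w - w * p.eta_minus * math.exp(-(t - lpost) / p.tau_minus))
                lp = t
            else:
                if lp is not None:
                    w = min(p.w_max, w + (p.w_max - w) * p.eta_plus * math.exp(-(t - lp) / p.tau_plus))
                lpost = t
        syn = apply_stdp(_plastic(), pre, post, p)
        assert syn.weight == pytest.approx(w, abs=1e-12)
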