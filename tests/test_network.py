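"""Circuit construction, neurogenesis, maturation and the simulation loop."""

import numpy as np
import pytest

from dgsim.io import preset_config
from dgsim.metrics import rate_vector
from dgsim.network import (
    MaturationSchedule,
    add_newborn_gc,
    advance_maturation,
    build,
    neurogenesis_births,
    simulate,
)
from dgsim.neurons import CELL_PARAMS, first_spike_time
from dgsim.stimuli import Protocol, make_pattern, make_pattern_pair, pair_protocol


def _cfg(**kw):
    return preset_config("200gc", **kw)


class TestBuild:
    def test_layer_sizes_for_200gc_preset(self, rng):
        net = build(_cfg(), rng)
        sizes = net.layer_sizes()
        assert sizes == {"LEC": 100, "GC": 200, "MC": 50, "BC": 25, "HC": 50}
        assert (net.stage[:200] == 5).all()  # initial GCs mature

    def test_zero_probability_pathway_has_no_synapses(self, rng):
        cfg = _cfg(conn_prob={("MC", "GC"): 0.0})
        net = build(cfg, rng)
        mc = net.layer_slice("MC")
        rows = slice(net.n_lec + mc.start, net.n_lec + mc.stop)
        assert net.G[rows, :200].sum() == 0.0

    def test_full_probability_pathway_is_dense_with_table_gmax(self, rng):
        cfg = _cfg(conn_prob={("MC", "GC"): 1.0})
        net = build(cfg, rng)
        mc = net.layer_slice("MC")
        block = net.G[net.n_lec + mc.start : net.n_lec + mc.stop, :200]
        assert block.shape == (50, 200)
        assert (block == 1.0).all()  # MC->GC peak conductance 1.0 nS

    def test_inhibitory_sources_flagged(self, rng):
        net = build(_cfg(), rng)
        for layer, flag in (("GC", False), ("MC", False), ("BC", True), ("HC", True)):
            s = net.layer_slice(layer)
            assert (net.pre_inh[net.n_lec + s.start : net.n_lec + s.stop] == flag).all()


class TestNeurogenesisBirths:
    def test_count_is_rate_times_duration(self):
        cfg = _cfg(neurogenesis_rate=3.0)
        assert len(neurogenesis_births(cfg, 0.0, 1.0)) == 3
        assert len(neurogenesis_births(cfg, 2.0, 2.0)) == 6

    def test_zero_rate_never_births(self):
        cfg = _cfg(neurogenesis_rate=0.0)
        assert neurogenesis_births(cfg, 0.0, 10.0) == []

    def test_births_evenly_spaced_inside_window(self):
        cfg = _cfg(neurogenesis_rate=3.0)
        times = neurogenesis_births(cfg, 5.0, 1.0)
        assert times == pytest.approx([5.0 + 1 / 6, 5.5, 5.0 + 5 / 6])


class TestNewbornGC:
    def test_stage1_wiring_current_and_attenuation(self, rng):
        net = build(_cfg(neurogenesis_rate=3.0), rng)
        active = np.arange(10)
        idx = add_newborn_gc(net, 0.5, active, rng)
        assert net.n_gc == 201 and net.alive[idx]
        assert net.conn[:, idx].sum() == 4          # ceil(0.4 * 10)
        assert set(np.where(net.conn[:, idx])[0]) <= set(active)
        assert net.I_inj[idx] == 100.0
        assert net.inh_att[idx] == pytest.approx(0.2)
        assert net.stage[idx] == 1

    def test_empty_active_set_is_noop(self, rng):
        net = build(_cfg(neurogenesis_rate=3.0), rng)
        assert add_newborn_gc(net, 0.5, np.array([]), rng) is None
        assert net.n_gc == 200

    def test_maturation_schedule_stages(self, rng):
        """Born at t=0 with 5 s maturation: stage 2,3,4,5 at t=1,2,3,4 s."""
        net = build(_cfg(neurogenesis_rate=1.0), rng)
        idx = add_newborn_gc(net, 0.0, np.arange(10), rng)
        expected_inj = {1: 50.0, 2: 20.0, 3: 0.0, 4: 0.0}
        for t in (1.0, 2.0, 3.0, 4.0):
            advance_maturation(net, t, np.array([]), rng)
            assert net.stage[idx] == t + 1
            assert net.I_inj[idx] == expected_inj[t]
        advance_maturation(net, 99.0, np.array([]), rng)
        assert net.stage[idx] == 5  # absorbing

    def test_stage_transition_adds_fresh_afferents_during_stimulus(self, rng):
        net = build(_cfg(neurogenesis_rate=1.0), rng)
        active = np.arange(10)
        idx = add_newborn_gc(net, 0.0, active, rng)
        before = set(np.where(net.conn[:, idx])[0])
        advance_maturation(net, 1.0, active, rng)  # stage 2, ratio 0.3 -> 3 new
        after = set(np.where(net.conn[:, idx])[0])
        assert before <= after
        assert len(after - before) == min(3, 10 - len(before))

    def test_schedule_invariants(self):
        s = MaturationSchedule(stage_duration=1.0)
        assert s.inj_current == (100.0, 50.0, 20.0, 0.0, 0.0)
        assert s.inh_attenuation == (0.2, 0.6, 0.8, 1.0, 1.0)
        assert s.ec_connect_ratio == (0.4, 0.3, 0.2, 0.1, 0.1)
        assert s.stage_at(0.0) == 1 and s.stage_at(4.2) == 5 and s.stage_at(17.0) == 5


class TestSimulate:
    def test_background_only_lec_rate(self, rng):
        """Empty protocol: LEC spikes at the 0.1 Hz background rate."""
        net = build(_cfg(), rng)
        rec = simulate(net, Protocol(events=(), total_duration=5.0))
        n = (rec.layer == "LEC").sum()
        expect = 0.1 * 100 * 5.0  # rate * n_lec * seconds
        assert abs(n - expect) < 4 * np.sqrt(expect) + 5

    def test_active_lec_rate_near_40hz(self, rng):
        net = build(_cfg(), rng)
        pat = make_pattern(100, 0.1, rng)
        rec = simulate(net, Protocol(events=((pat, 0.0, 10.0),), total_duration=10.0))
        act = sorted(pat.active)
        rates = rate_vector(rec, "LEC", (0.0, 10000.0)).rates
        pooled = rates[act].mean()  # 10 neurons x 10 s -> SE = sqrt(40/100)
        assert abs(pooled - 40.0) < 3 * np.sqrt(40.0 / 100.0)
        assert rates[[i for i in range(100) if i not in act]].mean() < 1.0

    def test_determinism_same_seed_bit_identical(self):
        cfg = _cfg(neurogenesis_rate=3.0)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            a, b = make_pattern_pair(100, 0.1, 0.3, rng)
            net = build(cfg, rng)
            rec = simulate(net, pair_protocol(a, b, 1.0, 2.0))
            outs.append((rec.neuron_id.copy(), rec.t_ms.copy()))
        assert (outs[0][0] == outs[1][0]).all()
        assert (outs[0][1] == outs[1][1]).all()

    def test_frozen_weights_without_plasticity(self, rng):
        net = build(_cfg(), rng)
        pat = make_pattern(100, 0.1, rng)
        w0 = net.Wp.copy()
        simulate(net, Protocol(events=((pat, 0.0, 1.0),), total_duration=1.0),
                 plasticity_on=False)
        assert (net.Wp == w0).all()

    def test_gc_count_accounting(self, rng):
        """GC count = initial + sum of scheduled births; never decreases."""
        cfg = _cfg(neurogenesis_rate=3.0)
        a, b = make_pattern_pair(100, 0.1, 0.3, rng)
        net = build(cfg, rng)
        simulate(net, pair_protocol(a, b, 1.0, 3.0))
        assert net.n_gc == 200 + 3 + 3  # 3 births per 1 s stimulus
        simulate(net, Protocol(events=(), total_duration=1.0))
        assert net.n_gc == 206  # no stimulus, no births

    def test_sparse_mature_gc_coding(self, rng):
        """During a 1 s concept stimulus fewer than 20% of mature GCs fire."""
        fracs = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            net = build(_cfg(), r)
            pat = make_pattern(100, 0.1, r)
            rec = simulate(net, Protocol(events=((pat, 0.0, 1.0),), total_duration=1.0),
                           plasticity_on=False, neurogenesis_on=False)
            g = (rec.layer == "GC")
            fracs.append(len(set(rec.neuron_id[g])) / 200)
        assert np.mean(fracs) < 0.2

    def test_developing_gcs_outfire_mature_ones(self, rng):
        """Stage 1-3 cells (tonic depolarization) fire above the mature mean."""
        cfg = _cfg(neurogenesis_rate=3.0)
        a, b = make_pattern_pair(100, 0.1, 0.3, rng)
        net = build(cfg, rng)
        rec = simulate(net, pair_protocol(a, b, 1.0, 1.0))
        rates = rate_vector(rec, "GC", (0.0, 2000.0)).rates
        newborn = rates[200:net.n_gc]
        assert newborn.mean() > rates[:200].mean()

    def test_engine_matches_scalar_reference_for_constant_current(self):
        """First BC spike in the network engine agrees with the fine-step
        single-neuron integrator under pure current injection."""
        rng = np.random.default_rng(0)
        cfg = _cfg(conn_prob={k: 0.0 for k in _cfg().conn_prob_table})
        net = build(cfg, rng)
        bc = net.layer_slice("BC")
        net.I_inj[bc.start] = 300.0
        rec = simulate(net, Protocol(events=(), total_duration=0.2))
        t_engine = rec.t_ms[(rec.layer == "BC") & (rec.neuron_id == 0)].min()
        t_ref = first_spike_time(CELL_PARAMS["BC"], 300.0, 1e-3, 200.0)
        assert abs(t_engine - t_ref) < 1.0
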