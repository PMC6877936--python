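"""The LEC -> dentate gyrus circuit: construction, neurogenesis, simulation.

Circuit layout (feedforward perforant path plus hilar feedback):

    LEC -> GC   AMPA, plastic (STDP)
    LEC -> BC   AMPA
    GC  -> MC   AMPA          MC -> GC   AMPA
    GC  -> HC   AMPA          MC -> HC   AMPA
    BC  -> GC   GABA          HC -> GC   GABA

LEC neurons are independent Poisson sources (40 Hz when carrying the
active part of a concept code, 0.1 Hz background); GC, MC, BC and HC are
AdEx neurons.  Each potential (pre, post) pair on a pathway is connected
independently with that pathway's probability.

Adult neurogenesis adds granule cells during stimuli at a fixed rate.
A newborn GC matures through five equal-length stages; each stage sets a
tonic depolarizing current (100/50/20/0/0 pA), an attenuation factor on
the GABA conductance it receives (0.2/0.6/0.8/1.0/1.0), and a propensity
to wire onto the LEC neurons that are firing when the stage is entered
(fractions 0.4/0.3/0.2/0.1/0.1 of the currently active LEC set).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .neurons import CELL_PARAMS
from .stimuli import Protocol, RATE_BACKGROUND
from .synapses import STDPParams, T_DELAY, TAU_DECAY

__all__ = [
    "PATHWAYS",
    "DEFAULT_CONN_PROB",
    "NetworkConfig",
    "MaturationSchedule",
    "Network",
    "SpikeRecords",
    "build",
    "neurogenesis_births",
    "add_newborn_gc",
    "advance_maturation",
    "simulate",
]

log = logging.getLogger(__name__)

#: (pre, post, receptor) for every pathway in the circuit.
PATHWAYS: tuple[tuple[str, str, str], ...] = (
    ("LEC", "GC", "AMPA"),
    ("LEC", "BC", "AMPA"),
    ("GC", "MC", "AMPA"),
    ("GC", "HC", "AMPA"),
    ("MC", "GC", "AMPA"),
    ("MC", "HC", "AMPA"),
    ("BC", "GC", "GABA"),
    ("HC", "GC", "GABA"),
)

#: Connection probabilities per pathway.  These are free parameters of the
#: model (the published projection ratios are shown only graphically); the
#: defaults are calibrated on the 200-GC preset so that (i) granule-cell
#: coding is sparse — fewer than 20% of mature GCs fire during a concept
#: stimulus — and (ii) a repeated stimulus evokes a reproducible GC rate
#: vector (same-concept cosine similarity near 0.9), which together give
#: the near-identity input/output similarity map the circuit shows without
#: neurogenesis.  Sparse perforant-path afferents plus a dense HIPP-cell
#: feedback blanket and moderately dense basket inhibition realize both.
DEFAULT_CONN_PROB: dict[tuple[str, str], float] = {
    ("LEC", "GC"): 0.02,
    ("LEC", "BC"): 0.2,
    ("GC", "MC"): 0.2,
    ("GC", "HC"): 0.5,
    ("MC", "GC"): 0.1,
    ("MC", "HC"): 0.2,
    ("BC", "GC"): 0.2,
    ("HC", "GC"): 1.0,
}


@dataclass(frozen=True)
class MaturationSchedule:
    """Five-stage newborn granule cell trajectory."""

    stage_duration: float  # s
    inj_current: tuple[float, ...] = (100.0, 50.0, 20.0, 0.0, 0.0)       # pA
    inh_attenuation: tuple[float, ...] = (0.2, 0.6, 0.8, 1.0, 1.0)
    ec_connect_ratio: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1, 0.1)

    def __post_init__(self) -> None:
        if not (len(self.inj_current) == len(self.inh_attenuation)
                == len(self.ec_connect_ratio) == 5):
            raise ValueError("maturation schedule lists must have length 5")
        if self.stage_duration <= 0:
            raise ValueError("stage_duration must be positive")

    def stage_at(self, age_s: float) -> int:
        """Maturation stage (1-5) at a given age."""
        if age_s < 0:
            raise ValueError("negative age")
        return min(5, int(age_s / self.stage_duration) + 1)


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, pathway tables and simulation settings for one network."""

    n_lec: int
    n_gc_initial: int
    n_mc: int
    n_bc: int
    n_hc: int
    neurogenesis_rate: float = 0.0         # newborn GCs per second of stimulus
    maturation_period: float = 5.0         # s, split into 5 equal stages
    gmax_table: dict = field(default_factory=dict)       # (pre, post) -> nS
    conn_prob_table: dict = field(default_factory=lambda: dict(DEFAULT_CONN_PROB))
    dt: float = 0.1                        # ms
    stdp: STDPParams = field(default_factory=STDPParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        for n in (self.n_lec, self.n_gc_initial, self.n_mc, self.n_bc, self.n_hc):
            if n <= 0:
                raise ValueError("layer sizes must be positive")
        if self.neurogenesis_rate < 0:
            raise ValueError("neurogenesis rate must be non-negative")
        if self.dt <= 0 or self.maturation_period <= 0:
            raise ValueError("dt and maturation_period must be positive")
        for key in self.gmax_table:
            if key not in {(p, q) for p, q, _ in PATHWAYS}:
                raise ValueError(f"unknown pathway {key} in gmax table")
        for key, p in self.conn_prob_table.items():
            if key not in {(p_, q) for p_, q, _ in PATHWAYS}:
                raise ValueError(f"unknown pathway {key} in connection table")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"connection probability {p} outside [0, 1]")

    @property
    def schedule(self) -> MaturationSchedule:
        return MaturationSchedule(stage_duration=self.maturation_period / 5.0)


@dataclass
class SpikeRecords:
    """All spikes of one simulation run.

    ``neuron_id`` is the within-layer index; ``layer`` is one of
    LEC/GC/MC/BC/HC; times are in ms from the start of the run.
    """

    neuron_id: np.ndarray
    layer: np.ndarray
    t_ms: np.ndarray
    layer_sizes: dict

    def layer_size(self, layer: str) -> int:
        return self.layer_sizes[layer]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"neuron_id": self.neuron_id, "layer": self.layer, "spike_time_ms": self.t_ms}
        )


class Network:
    """Mutable network state backed by flat arrays (see ``_engine``).

    DG neurons occupy one flat index range: granule-cell slots first (a
    capacity block that neurogenesis fills in), then MC, BC, HC.  Global
    presynaptic source ids put the ``n_lec`` Poisson inputs before the DG
    block.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        self.schedule = config.schedule
        self.rng = rng
        self.n_lec = config.n_lec
        self.gc_cap = config.n_gc_initial
        self.n_gc = config.n_gc_initial
        self.n_mc = config.n_mc
        self.n_bc = config.n_bc
        self.n_hc = config.n_hc
        self.t_ms = 0.0
        self._delay_steps = int(round(T_DELAY / config.dt))
        self._decay = math.exp(-config.dt / TAU_DECAY)
        self._alloc()
        self._wire_initial()

    # ---- layout helpers -------------------------------------------------

    @property
    def n_dg(self) -> int:
        return self.gc_cap + self.n_mc + self.n_bc + self.n_hc

    def layer_slice(self, layer: str) -> slice:
        if layer == "GC":
            return slice(0, self.gc_cap)
        if layer == "MC":
            return slice(self.gc_cap, self.gc_cap + self.n_mc)
        if layer == "BC":
            return slice(self.gc_cap + self.n_mc, self.gc_cap + self.n_mc + self.n_bc)
        if layer == "HC":
            return slice(self.gc_cap + self.n_mc + self.n_bc, self.n_dg)
        raise KeyError(layer)

    def layer_sizes(self) -> dict:
        return {"LEC": self.n_lec, "GC": self.n_gc, "MC": self.n_mc,
                "BC": self.n_bc, "HC": self.n_hc}

    # ---- allocation and wiring ------------------------------------------

    def _alloc(self) -> None:
        N = self.n_dg
        M = self.n_lec + N
        f = lambda fill=0.0: np.full(N, fill)
        self.alive = np.zeros(N, dtype=np.bool_)
        self.El, self.gl, self.Cm = f(), f(), f(1.0)
        self.Vr, self.Vt, self.DT = f(), f(1.0), f()
        self.al, self.tw, self.bi = f(), f(1.0), f()
        for layer in ("GC", "MC", "BC", "HC"):
            p = CELL_PARAMS[layer]
            s = self.layer_slice(layer)
            # capacitance enters the kernel in pF (pA/pF = mV/ms)
            self.El[s], self.gl[s], self.Cm[s] = p.El, p.gl, p.Cm * 1e3
            self.Vr[s], self.Vt[s], self.DT[s] = p.Vreset, p.Vthr, p.DeltaT
            self.al[s], self.tw[s], self.bi[s] = p.alpha, p.tau_w, p.b
        self.Vm = self.El.copy()
        self.wad = f()
        self.I_inj = f()
        self.inh_att = f(1.0)
        self.g_exc, self.g_inh = f(), f()
        self.buf_exc = np.zeros((self._delay_steps + 1, N))
        self.buf_inh = np.zeros((self._delay_steps + 1, N))
        self.buf_pos = 0
        self.G = np.zeros((M, N))
        self.pre_inh = np.zeros(M, dtype=np.bool_)
        for layer in ("BC", "HC"):
            s = self.layer_slice(layer)
            self.pre_inh[self.n_lec + s.start : self.n_lec + s.stop] = True
        self.Wp = np.zeros((self.n_lec, self.gc_cap))
        self.conn = np.zeros((self.n_lec, self.gc_cap), dtype=np.uint8)
        self.birth_time = np.full(self.gc_cap, -np.inf)  # s; -inf = mature at build
        self.stage = np.full(self.gc_cap, 5, dtype=np.int64)
        self.last_pre = np.full(self.n_lec, -1.0e18)
        self.last_post = np.full(self.gc_cap, -1.0e18)

    def _gmax(self, pre: str, post: str) -> float:
        try:
            return self.config.gmax_table[(pre, post)]
        except KeyError:
            raise KeyError(f"gmax for pathway {pre}->{post} missing from config") from None

    def _prob(self, pre: str, post: str) -> float:
        return self.config.conn_prob_table[(pre, post)]

    def _wire_initial(self) -> None:
        cfg = self.config
        # mark permanent populations alive; GC slots up to the initial count
        self.alive[: self.n_gc] = True
        for layer in ("MC", "BC", "HC"):
            self.alive[self.layer_slice(layer)] = True
        # plastic perforant path onto the initial (mature) granule cells
        mask = self.rng.random((self.n_lec, self.n_gc)) < self._prob("LEC", "GC")
        self.conn[:, : self.n_gc] = mask
        self.Wp[:, : self.n_gc] = mask.astype(float)
        self.G[: self.n_lec, : self.n_gc] = self._gmax("LEC", "GC") * self.Wp[:, : self.n_gc]
        # remaining pathways, fixed weights
        for pre, post, _rec in PATHWAYS[1:]:
            self._wire_block(pre, post)

    def _wire_block(self, pre: str, post: str, post_idx: np.ndarray | None = None) -> None:
        """Bernoulli-wire pre-layer onto post columns (all alive posts by default)."""
        s_pre = self.layer_slice(pre) if pre != "LEC" else slice(0, self.n_lec)
        rows = np.arange(s_pre.start, s_pre.stop)
        if pre != "LEC":
            rows = rows[self.alive[s_pre]] + self.n_lec
        if post_idx is None:
            s_post = self.layer_slice(post)
            cols = np.arange(s_post.start, s_post.stop)
            if post == "GC":
                cols = cols[self.alive[s_post]]
        else:
            cols = np.asarray(post_idx)
        mask = self.rng.random((rows.size, cols.size)) < self._prob(pre, post)
        self.G[np.ix_(rows, cols)] = self._gmax(pre, post) * mask

    # ---- growth ----------------------------------------------------------

    def ensure_gc_capacity(self, extra: int) -> None:
        """Grow the granule-cell block to hold ``extra`` more cells."""
        need = self.n_gc + extra
        if need <= self.gc_cap:
            return
        old_cap, old_N = self.gc_cap, self.n_dg
        add = need - old_cap

        def expand(a: np.ndarray, fill) -> np.ndarray:
            out = np.full(old_N + add, fill, dtype=a.dtype)
            out[:old_cap] = a[:old_cap]
            out[old_cap + add :] = a[old_cap:]
            return out

        p = CELL_PARAMS["GC"]
        self.alive = expand(self.alive, False)
        for name, fill in (("El", p.El), ("gl", p.gl), ("Cm", p.Cm * 1e3), ("Vr", p.Vreset),
                           ("Vt", p.Vthr), ("DT", p.DeltaT), ("al", p.alpha),
                           ("tw", p.tau_w), ("bi", p.b), ("Vm", p.El), ("wad", 0.0),
                           ("I_inj", 0.0), ("inh_att", 1.0), ("g_exc", 0.0),
                           ("g_inh", 0.0)):
            setattr(self, name, expand(getattr(self, name), fill))
        for name in ("buf_exc", "buf_inh"):
            a = getattr(self, name)
            out = np.zeros((a.shape[0], old_N + add))
            out[:, :old_cap] = a[:, :old_cap]
            out[:, old_cap + add :] = a[:, old_cap:]
            setattr(self, name, out)
        Gnew = np.zeros((self.n_lec + old_N + add, old_N + add))
        rmap = np.concatenate(  # old column/row (dg) index -> new index
            [np.arange(old_cap), np.arange(old_cap, old_N) + add]
        )
        Gnew[np.ix_(np.concatenate([np.arange(self.n_lec), self.n_lec + rmap]),
                    rmap)] = self.G
        self.G = Gnew
        pre_new = np.zeros(self.n_lec + old_N + add, dtype=np.bool_)
        pre_new[np.concatenate([np.arange(self.n_lec), self.n_lec + rmap])] = self.pre_inh
        self.pre_inh = pre_new
        for name, fill in (("Wp", 0.0), ("conn", 0)):
            a = getattr(self, name)
            out = np.zeros((self.n_lec, old_cap + add), dtype=a.dtype)
            out[:, :old_cap] = a
            setattr(self, name, out)
        def expand_gc(a: np.ndarray, fill) -> np.ndarray:
            out = np.full(old_cap + add, fill, dtype=a.dtype)
            out[:old_cap] = a
            return out

        self.birth_time = expand_gc(self.birth_time, -np.inf)
        self.stage = expand_gc(self.stage, 5)
        self.last_post = expand_gc(self.last_post, -1.0e18)
        self.gc_cap = old_cap + add

    # ---- state management -------------------------------------------------

    def reset_dynamic_state(self) -> None:
        """Return every membrane/conductance variable to rest; keep wiring."""
        self.Vm[:] = self.El
        self.wad[:] = 0.0
        self.g_exc[:] = 0.0
        self.g_inh[:] = 0.0
        self.buf_exc[:] = 0.0
        self.buf_inh[:] = 0.0
        self.buf_pos = 0
        self.last_pre[:] = -1.0e18
        self.last_post[:] = -1.0e18
        self.t_ms = 0.0

    def mature_all(self) -> None:
        """Promote every developing granule cell to the mature stage.

        Used between the growth phase and the test phase: once stimuli
        stop, no further input wiring can occur, so the remaining stage
        transitions only remove the immature injected current and
        inhibition attenuation.
        """
        gc = np.arange(self.gc_cap)[self.alive[: self.gc_cap]]
        self.stage[gc] = 5
        self.I_inj[gc] = 0.0
        self.inh_att[gc] = 1.0

    def gc_stage_props(self, idx: int, stage: int) -> None:
        sched = self.schedule
        self.stage[idx] = stage
        self.I_inj[idx] = sched.inj_current[stage - 1]
        self.inh_att[idx] = sched.inh_attenuation[stage - 1]


def build(config: NetworkConfig, rng: np.random.Generator | None = None) -> Network:
    """Construct and wire a network; all initial granule cells are mature."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return Network(config, rng)


def neurogenesis_births(
    config: NetworkConfig, stimulus_onset: float, stimulus_duration: float
) -> list[float]:
    """Deterministic birth times (s) within one stimulus window.

    round(rate * duration) cells, evenly spaced at window centers; no
    births occur outside stimulus windows.
    """
    n = int(round(config.neurogenesis_rate * stimulus_duration))
    return [stimulus_onset + (i + 0.5) * stimulus_duration / n for i in range(n)]


def add_newborn_gc(
    net: Network, t: float, active_lec: np.ndarray, rng: np.random.Generator | None = None
) -> int | None:
    """Insert one stage-1 granule cell at time ``t`` (s).

    Afferents: ceil(ratio_1 * |active|) of the currently firing LEC
    neurons, plastic at weight 1; plus BC->GC and HC->GC inhibition at the
    standard probabilities.  Efferents: GC->MC and GC->HC at the standard
    probabilities.  (Newborns receive no mossy-cell feedback until they
    appear in later wiring events, mirroring their late synaptic
    integration.)
    """
    if rng is None:
        rng = net.rng
    active_lec = np.asarray(list(active_lec), dtype=np.int64)
    if active_lec.size == 0:
        log.warning("add_newborn_gc called with no active LEC neurons; skipped")
        return None
    net.ensure_gc_capacity(1)
    idx = net.n_gc
    net.n_gc += 1
    net.alive[idx] = True
    net.birth_time[idx] = t
    net.Vm[idx] = CELL_PARAMS["GC"].El
    net.wad[idx] = 0.0
    net.gc_stage_props(idx, 1)
    k = math.ceil(net.schedule.ec_connect_ratio[0] * active_lec.size)
    chosen = rng.choice(active_lec, size=min(k, active_lec.size), replace=False)
    net.conn[chosen, idx] = 1
    net.Wp[chosen, idx] = 1.0
    net.G[chosen, idx] = net._gmax("LEC", "GC") * 1.0
    # efferents and inhibitory afferents at standard pathway probabilities
    for pre, post in ((("GC", "MC")), ("GC", "HC")):
        s_post = net.layer_slice(post)
        mask = rng.random(s_post.stop - s_post.start) < net._prob(pre, post)
        cols = np.arange(s_post.start, s_post.stop)[mask]
        net.G[net.n_lec + idx, cols] = net._gmax(pre, post)
    for pre in ("BC", "HC"):
        s_pre = net.layer_slice(pre)
        mask = rng.random(s_pre.stop - s_pre.start) < net._prob(pre, "GC")
        rows = np.arange(s_pre.start, s_pre.stop)[mask] + net.n_lec
        net.G[rows, idx] = net._gmax(pre, "GC")
    log.debug("birth t=%.3f s gc=%d afferents=%d", t, idx, chosen.size)
    return idx


def advance_maturation(
    net: Network, t: float, active_lec: np.ndarray, rng: np.random.Generator | None = None
) -> None:
    """Promote developing granule cells whose age crossed a stage boundary.

    On entering stage k the cell takes that stage's injected current and
    inhibition attenuation; if a stimulus is active it additionally wires
    onto ceil(ratio_k * |active|) of the active LEC neurons it is not yet
    connected to.  Stages never decrease; stage 5 is absorbing.
    """
    if rng is None:
        rng = net.rng
    active_lec = np.asarray(list(active_lec), dtype=np.int64)
    for idx in range(net.gc_cap):
        if not net.alive[idx] or net.stage[idx] >= 5 or not np.isfinite(net.birth_time[idx]):
            continue
        new_stage = net.schedule.stage_at(max(0.0, t - net.birth_time[idx]))
        if new_stage <= net.stage[idx]:
            continue
        net.gc_stage_props(idx, new_stage)
        if active_lec.size:
            ratio = net.schedule.ec_connect_ratio[new_stage - 1]
            k = math.ceil(ratio * active_lec.size)
            fresh = active_lec[net.conn[active_lec, idx] == 0]
            if fresh.size:
                chosen = rng.choice(fresh, size=min(k, fresh.size), replace=False)
                net.conn[chosen, idx] = 1
                net.Wp[chosen, idx] = 1.0
                net.G[chosen, idx] = net._gmax("LEC", "GC")
        log.debug("stage transition t=%.3f s gc=%d -> %d", t, idx, new_stage)


def _protocol_events(net: Network, protocol: Protocol, neurogenesis_on: bool):
    """Timeline of (t_s, priority, kind, payload) driver events."""
    events = []
    births_total = 0
    for pat, onset, dur in protocol.events:
        events.append((onset, 1, "stim_on", pat))
        events.append((onset + dur, 0, "stim_off", None))
        if neurogenesis_on and net.config.neurogenesis_rate > 0:
            for bt in neurogenesis_births(net.config, onset, dur):
                events.append((bt, 2, "birth", None))
                births_total += 1
    if neurogenesis_on:
        # stage transitions for cells born during this run
        horizon = protocol.total_duration
        stage_dur = net.schedule.stage_duration
        for t, _, kind, _ in list(events):
            if kind == "birth":
                for k in range(1, 5):
                    tt = t + k * stage_dur
                    if tt < horizon:
                        events.append((tt, 3, "stage", None))
        # and for cells already developing when the run starts
        for idx in range(net.gc_cap):
            if net.alive[idx] and net.stage[idx] < 5 and np.isfinite(net.birth_time[idx]):
                age0 = net.t_ms / 1000.0 - net.birth_time[idx]
                for k in range(net.stage[idx], 5):
                    tt = k * stage_dur - age0
                    if 0 <= tt < protocol.total_duration:
                        events.append((tt, 3, "stage", None))
    events.sort(key=lambda e: (e[0], e[1]))
    return events, births_total


def simulate(
    net: Network,
    protocol: Protocol,
    plasticity_on: bool = True,
    neurogenesis_on: bool = True,
    rng: np.random.Generator | None = None,
    max_chunk_steps: int = 20000,
) -> SpikeRecords:
    """Run the network through a stimulus protocol and return all spikes.

    The timeline is split at stimulus boundaries, births and maturation
    stage transitions; between consecutive events the compiled kernel
    advances the state at the configured dt.  With ``plasticity_on``
    False the perforant-path weights are frozen; with ``neurogenesis_on``
    False no cells are born and no stage transitions occur.  Times in the
    returned records are ms from the start of this call.
    """
    if rng is None:
        rng = net.rng
    cfg = net.config
    dt = cfg.dt
    t_start_ms = net.t_ms
    events, births_total = _protocol_events(net, protocol, neurogenesis_on)
    if births_total:
        net.ensure_gc_capacity(births_total)

    ids_acc: list[np.ndarray] = []
    ts_acc: list[np.ndarray] = []
    active_pattern = None

    def lec_probs() -> np.ndarray:
        r = np.full(net.n_lec, RATE_BACKGROUND)
        if active_pattern is not None:
            r[list(active_pattern.active)] = active_pattern.rate_active
        return r * dt / 1000.0

    def run_until(t_target_s: float) -> None:
        nonlocal ids_acc, ts_acc
        target_ms = t_start_ms + t_target_s * 1000.0
        steps_left = int(round((target_ms - net.t_ms) / dt))
        p = lec_probs()
        while steps_left > 0:
            steps = min(steps_left, max_chunk_steps)
            uni = rng.random((steps, net.n_lec))
            cap = steps * 64 + 4096
            sid = np.empty(cap, dtype=np.int64)
            st = np.empty(cap, dtype=np.float64)
            nsp, done, net.buf_pos = _engine.run_chunk(
                steps, dt, net.t_ms, p, uni,
                net.alive, net.El, net.gl, net.Cm, net.Vr, net.Vt, net.DT,
                net.al, net.tw, net.bi, net.Vm, net.wad, net.I_inj, net.inh_att,
                net.g_exc, net.g_inh, net.buf_exc, net.buf_inh, net.buf_pos,
                net.G, net.pre_inh, net.Wp, net.conn, net.gc_cap,
                net._gmax("LEC", "GC"), plasticity_on,
                cfg.stdp.eta_plus, cfg.stdp.eta_minus,
                cfg.stdp.tau_plus, cfg.stdp.tau_minus, cfg.stdp.w_max,
                net.last_pre, net.last_post,
                net._delay_steps, net._decay, sid, st,
            )
            if done < steps:
                raise RuntimeError("spike buffer overflow in simulation chunk")
            ids_acc.append(sid[:nsp].copy())
            ts_acc.append(st[:nsp].copy())
            net.t_ms += steps * dt
            steps_left -= steps

    for t_ev, _prio, kind, payload in events:
        run_until(t_ev)
        t_abs = t_start_ms / 1000.0 + t_ev  # network-clock seconds
        if kind == "stim_on":
            active_pattern = payload
            log.debug("stimulus %s on at %.3f s", payload.id, t_ev)
        elif kind == "stim_off":
            active_pattern = None
        elif kind == "birth":
            act = np.array(sorted(active_pattern.active)) if active_pattern else np.array([])
            add_newborn_gc(net, t_abs, act, rng)
        elif kind == "stage":
            act = np.array(sorted(active_pattern.active)) if active_pattern else np.array([])
            advance_maturation(net, t_abs, act, rng)
    run_until(protocol.total_duration)

    ids = np.concatenate(ids_acc) if ids_acc else np.empty(0, dtype=np.int64)
    ts = np.concatenate(ts_acc) if ts_acc else np.empty(0)
    ts = ts - t_start_ms
    layer = np.empty(ids.size, dtype="<U3")
    local = np.empty(ids.size, dtype=np.int64)
    lec_mask = ids < net.n_lec
    layer[lec_mask] = "LEC"
    local[lec_mask] = ids[lec_mask]
    dg = ids - net.n_lec
    for name in ("GC", "MC", "BC", "HC"):
        s = net.layer_slice(name)
        m = ~lec_mask & (dg >= s.start) & (dg < s.stop)
        layer[m] = name
        local[m] = dg[m] - s.start
    return SpikeRecords(neuron_id=local, layer=layer, t_ms=ts,
                        layer_sizes=net.layer_sizes())
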