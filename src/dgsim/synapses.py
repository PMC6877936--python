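"""Conductance-based synapses and spike-timing-dependent plasticity.

A presynaptic spike at time ts opens the receptor after a fixed axonal
delay; the conductance jumps to gmax at ts + t_delay and then decays as a
single exponential with time constant tau_decay.  Synaptic current uses
the driving-force convention

    I_syn = g_exc (E_AMPA - Vm) + g_inh (E_GABA - Vm)

so that AMPA (E = 0 mV) depolarizes and GABA (E = -80 mV) hyperpolarizes;
the current enters the membrane equation with a plus sign.

The perforant-path synapses (LEC -> GC) carry a dimensionless plastic
weight in [0, w_max] updated by a soft-bounded STDP rule with
nearest-neighbour pairing: causal pairings (pre before post) potentiate,
with the increment scaled by the remaining headroom (w_max - w); acausal
pairings depress, scaled by the current weight.  The soft bounds make the
weight structurally confined to [0, w_max].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SynapseParams",
    "Synapse",
    "STDPParams",
    "E_AMPA",
    "E_GABA",
    "conductance_at",
    "synaptic_current",
    "effective_gmax",
    "stdp_delta",
    "apply_stdp",
]

E_AMPA = 0.0    # mV
E_GABA = -80.0  # mV

#: shared receptor kinetics (ms)
T_DELAY = 2.0
TAU_DECAY = 6.0


@dataclass(frozen=True)
class SynapseParams:
    """Static description of one synapse class.

    Esyn is pinned by the receptor: 0 mV for AMPA, -80 mV for GABA.
    """

    gmax: float
    receptor: str = "AMPA"
    t_delay: float = T_DELAY
    tau_decay: float = TAU_DECAY

    def __post_init__(self) -> None:
        if self.gmax < 0 or self.t_delay < 0 or self.tau_decay <= 0:
            raise ValueError("invalid synapse kinetics")
        if self.receptor not in ("AMPA", "GABA"):
            raise ValueError(f"unknown receptor {self.receptor!r}")

    @property
    def Esyn(self) -> float:
        return E_AMPA if self.receptor == "AMPA" else E_GABA


@dataclass
class Synapse:
    """One connection, optionally plastic (LEC -> GC carries STDP)."""

    pre: int
    post: int
    params: SynapseParams
    weight: float = 1.0
    plastic: bool = False
    pre_spike_buffer: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class STDPParams:
    """Soft-bounded STDP parameters (published defaults)."""

    eta_plus: float = 0.1
    eta_minus: float = 0.1
    tau_plus: float = 20.0   # ms
    tau_minus: float = 12.0  # ms
    w_max: float = 2.0

    def __post_init__(self) -> None:
        for name in ("eta_plus", "eta_minus", "tau_plus", "tau_minus", "w_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def conductance_at(t: float, spike_time: float, params: SynapseParams) -> float:
    """Conductance (nS) at time t due to one presynaptic spike.

    Zero before the delay elapses; instantaneous rise to gmax at
    spike_time + t_delay followed by exponential decay.
    """
    dt = t - spike_time - params.t_delay
    if dt < 0:
        return 0.0
    return params.gmax * math.exp(-dt / params.tau_decay)


def synaptic_current(g_total_exc: float, g_total_inh: float, Vm: float) -> float:
    """Total synaptic current (pA) from summed AMPA and GABA conductances (nS)."""
    if g_total_exc < 0 or g_total_inh < 0:
        raise ValueError("conductances must be non-negative")
    return g_total_exc * (E_AMPA - Vm) + g_total_inh * (E_GABA - Vm)


def effective_gmax(syn: Synapse, stdp: STDPParams | None = None) -> float:
    """Peak conductance including the plastic weight multiplier."""
    return syn.params.gmax * (syn.weight if syn.plastic else 1.0)


def stdp_delta(w: float, dt_pre_to_post: float, params: STDPParams, causal: bool) -> float:
    """Weight change for one pre/post pairing.

    Parameters
    ----------
    w : float
        Current weight, must lie in [0, w_max].
    dt_pre_to_post : float
        Pairing lag |t_post - t_pre| in ms (sign carried by ``causal``).
    causal : bool
        True for pre-before-post (potentiation), False for post-before-pre
        (depression).
    """
    if not 0.0 <= w <= params.w_max:
        raise ValueError(f"weight {w} outside [0, {params.w_max}]")
    lag = abs(dt_pre_to_post)
    if causal:
        return (params.w_max - w) * params.eta_plus * math.exp(-lag / params.tau_plus)
    return -w * params.eta_minus * math.exp(-lag / params.tau_minus)


def apply_stdp(
    syn: Synapse,
    pre_spikes: list[float],
    post_spikes: list[float],
    params: STDPParams,
) -> Synapse:
    """Replay nearest-neighbour STDP over two spike trains, in event order.

    Every post spike potentiates against the most recent pre spike at or
    before it; every pre spike depresses against the most recent strictly
    earlier post spike.  Simultaneous pre/post events count as causal.
    This mirrors the online rule the network engine applies spike by
    spike, and doubles as its independent replay oracle in tests.
    """
    if not syn.plastic:
        raise ValueError("STDP applied to a non-plastic synapse")
    events = sorted(
        [(t, 0) for t in pre_spikes] + [(t, 1) for t in post_spikes]
    )  # pre sorts before post at equal times -> simultaneous pairing is causal
    w = syn.weight
    last_pre = -math.inf
    last_post = -math.inf
    for t, kind in events:
        if kind == 0:  # pre spike: pair with most recent post (acausal)
            if math.isfinite(last_post):
                w += stdp_delta(w, t - last_post, params, causal=False)
            last_pre = t
        else:  # post spike: pair with most recent pre (causal)
            if math.isfinite(last_pre):
                w += stdp_delta(w, t - last_pre, params, causal=True)
            last_post = t
        w = min(max(w, 0.0), params.w_max)
    syn.weight = w
    return syn
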