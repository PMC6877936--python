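"""Adaptive exponential integrate-and-fire (AdEx) point neurons.

All four dentate gyrus cell types — granule cells (GC), mossy cells (MC),
basket cells (BC) and HIPP cells (HC) — share the same two-variable AdEx
dynamics

    Cm dVm/dt = gl (El - Vm) + gl DeltaT exp((Vm - VT)/DeltaT) + I_syn + I_inj - w
    tau_w dw/dt = alpha (Vm - El) - w

with a hard reset when Vm crosses the firing threshold: Vm <- Vreset and
w <- w + b.  The GC parameter set has DeltaT = 0, which we treat as the
hard-threshold (leaky integrate-and-fire) limit: the exponential
spike-initiation term is dropped and the cell fires exactly at Vthr.

Units follow the usual conductance-based convention: mV, ms, nS, pA.
Capacitance is stored in nF as published but enters the dynamics in pF
(nS*mV = pA and pA/pF = mV/ms), so dVm/dt divides by 1000*Cm.  The
granule-cell membrane time constant Cm/gl is then 223 ms, and the
effective constant under a 10 nS synaptic conductance is ~0.7 ms, which
keeps forward Euler at dt = 0.1 ms stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "NeuronParams",
    "NeuronState",
    "CELL_PARAMS",
    "derivative",
    "step",
    "first_spike_time",
]

# Exponent cap for the spike-initiation term.  Threshold detection fires
# long before the argument reaches this value in any sane trajectory; the
# cap only guards against overflow in pathological states.
_EXP_CAP = 10.0


@dataclass(frozen=True)
class NeuronParams:
    """AdEx parameters for one cell type.

    Attributes
    ----------
    El : float
        Resting (leak reversal) potential, mV.
    gl : float
        Leak conductance, nS.
    Cm : float
        Membrane capacitance, nF.
    Vreset : float
        Post-spike reset voltage, mV.
    Vthr : float
        Firing threshold, mV.  Doubles as the exponential-term midpoint
        VT (the published parameter table gives a single value for both).
    DeltaT : float
        Slope factor, mV.  Zero selects the hard-threshold limit.
    alpha : float
        Subthreshold adaptation coupling, nS.
    tau_w : float
        Adaptation time constant, ms.
    b : float
        Spike-triggered adaptation increment, pA.
    cell_type : str
        One of ``GC``, ``MC``, ``BC``, ``HC``.
    """

    El: float
    gl: float
    Cm: float
    Vreset: float
    Vthr: float
    DeltaT: float
    alpha: float
    tau_w: float
    b: float
    cell_type: str = "GC"

    def __post_init__(self) -> None:
        if not (self.gl > 0 and self.Cm > 0):
            raise ValueError("gl and Cm must be positive")
        if not self.Vreset < self.Vthr:
            raise ValueError("Vreset must lie below Vthr")
        if self.DeltaT < 0:
            raise ValueError("DeltaT must be non-negative")
        if not self.tau_w > 0:
            raise ValueError("tau_w must be positive")


@dataclass
class NeuronState:
    """Dynamic state of a single neuron.

    ``stage`` is the maturation stage (1-5) for granule cells; all other
    cell types are fixed at the mature stage 5.  ``injected`` is the
    stage-dependent depolarizing current given to developing cells, pA.
    """

    Vm: float
    w: float = 0.0
    last_spike: float | None = None
    stage: int = 5
    injected: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Vm) and math.isfinite(self.w)):
            raise ValueError("non-finite neuron state")
        if self.stage not in (1, 2, 3, 4, 5):
            raise ValueError("stage must be in 1..5")


#: Published AdEx parameters per cell type (mV / nS / nF / pA / ms).
CELL_PARAMS: dict[str, NeuronParams] = {
    "GC": NeuronParams(El=-87.0, gl=0.030, Cm=0.0067, Vreset=-74.0, Vthr=-56.0,
                       DeltaT=0.0, alpha=2.0, tau_w=45.0, b=45.0, cell_type="GC"),
    "MC": NeuronParams(El=-64.0, gl=4.530, Cm=0.6210, Vreset=-49.0, Vthr=-42.0,
                       DeltaT=2.0, alpha=2.0, tau_w=180.0, b=82.9, cell_type="MC"),
    "BC": NeuronParams(El=-52.0, gl=18.054, Cm=0.1793, Vreset=-45.0, Vthr=-39.0,
                       DeltaT=2.0, alpha=0.1, tau_w=100.0, b=20.5, cell_type="BC"),
    "HC": NeuronParams(El=-59.0, gl=1.930, Cm=0.0584, Vreset=-56.0, Vthr=-50.0,
                       DeltaT=2.0, alpha=0.82, tau_w=93.0, b=15.0, cell_type="HC"),
}


def exp_term(Vm: float, params: NeuronParams) -> float:
    """Spike-initiation current gl*DeltaT*exp((Vm-VT)/DeltaT), pA.

    Returns 0 in the DeltaT = 0 hard-threshold limit.  The exponent
    argument is capped to keep the value finite above threshold.
    """
    if params.DeltaT == 0.0:
        return 0.0
    arg = min((Vm - params.Vthr) / params.DeltaT, _EXP_CAP)
    return params.gl * params.DeltaT * math.exp(arg)


def derivative(
    state: NeuronState,
    params: NeuronParams,
    I_syn_total: float,
    I_inj: float = 0.0,
) -> tuple[float, float]:
    """Time derivatives (dVm/dt in mV/ms, dw/dt in pA/ms) of the AdEx system."""
    if not all(map(math.isfinite, (state.Vm, state.w, I_syn_total, I_inj))):
        raise ValueError("non-finite input to derivative")
    I_total = (
        params.gl * (params.El - state.Vm)
        + exp_term(state.Vm, params)
        + I_syn_total
        + I_inj
        - state.w
    )
    dVm = I_total / (params.Cm * 1000.0)  # pA / pF -> mV/ms
    dw = (params.alpha * (state.Vm - params.El) - state.w) / params.tau_w
    return dVm, dw


def step(
    state: NeuronState,
    params: NeuronParams,
    I_syn_total: float,
    I_inj: float,
    dt: float,
    t: float = 0.0,
) -> tuple[NeuronState, bool]:
    """Advance one forward-Euler step of length ``dt`` ms.

    The threshold test Vm >= Vthr runs after the Euler update; on a spike
    the voltage is reset and the adaptation current is bumped by ``b``.
    Returns the new state and a spike flag.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dVm, dw = derivative(state, params, I_syn_total, I_inj)
    Vm = state.Vm + dt * dVm
    w = state.w + dt * dw
    spiked = Vm >= params.Vthr
    last = state.last_spike
    if spiked:
        Vm = params.Vreset
        w += params.b
        last = t + dt
    return replace(state, Vm=Vm, w=w, last_spike=last), spiked


def first_spike_time(
    params: NeuronParams,
    I_inj: float,
    dt: float,
    t_max: float,
) -> float | None:
    """Time (ms) of the first spike under constant current injection.

    Starts from rest (Vm = El, w = 0) and integrates with the same
    forward-Euler scheme as :func:`step`.  Run at dt = 1e-3 ms this serves
    as a fine-step reference for validating the production step size.
    """
    state = NeuronState(Vm=params.El)
    t = 0.0
    while t < t_max:
        state, spiked = step(state, params, 0.0, I_inj, dt, t)
        t += dt
        if spiked:
            return t
    return None
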