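"""Vectorized integration kernel for the LEC -> dentate gyrus circuit.

The network state lives in flat numpy arrays owned by
:class:`dgsim.network.Network`; this module holds the numba-compiled inner
loop that advances that state over a span of steps during which the
topology and stimulus are constant (the Python driver splits the timeline
at births, stage transitions and stimulus boundaries).

Step order, repeated every dt:

1. decay the per-neuron summed AMPA/GABA conductances by exp(-dt/tau) and
   add the increments whose axonal delay elapses this step;
2. membrane update of every AdEx neuron using the post-delivery
   conductances (inhibitory conductance onto a granule cell is scaled by
   its maturation-stage attenuation factor).  The voltage uses an
   exponential-Euler step: the conductance terms define an instantaneous
   equilibrium V_inf and time constant tau_eff = Cm / g_total toward
   which Vm relaxes exactly over dt, while the spike-initiation current,
   the adaptation current and injected currents are held constant across
   the step.  Granule cells have Cm = 6.7 pF, so summed inhibition of
   order 100 nS drives tau_eff far below any practical dt; the
   exponential update stays stable and accurate where a plain
   forward-Euler voltage step would oscillate and fire spuriously.  The
   adaptation variable w relaxes on tens of milliseconds and keeps a
   plain Euler update;
3. draw LEC Poisson spikes for this step, schedule their conductance
   arrivals ``delay`` later, and apply STDP depression pairings
   (pre spike against the most recent post spike of each plastic target);
4. threshold-test the AdEx neurons; a spike resets Vm, bumps the
   adaptation current, schedules delayed conductance onto its targets,
   and (for granule cells, when plasticity is on) applies STDP
   potentiation pairings against the most recent spike of each afferent
   LEC neuron.

Spike times are stamped at the end of the step in which they occur.
Nearest-neighbour pairing is realized through the ``last_pre`` /
``last_post`` time arrays; a simultaneous pre/post pair counts as causal
because LEC spikes are processed before the threshold test.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_chunk"]

_NEVER = -1.0e18  # sentinel for "no spike yet"


@njit(cache=True)
def run_chunk(
    steps,
    dt,
    t0,
    lec_p,          # (n_lec,) spike probability per step
    uniforms,       # (steps, n_lec)
    alive,          # (N,) bool
    El, gl, Cm, Vr, Vt, DT, al, tw, bi,  # (N,) AdEx parameters
    Vm, wad,        # (N,) state
    I_inj,          # (N,) stage-dependent injected current, pA
    inh_att,        # (N,) attenuation on inhibitory conductance
    g_exc, g_inh,   # (N,) summed conductances, nS
    buf_exc, buf_inh,  # (delay_steps+1, N) circular delivery buffers
    buf_pos,        # current read index into the circular buffers
    G,              # (n_lec + N, N) effective peak conductance per connection
    pre_inh,        # (n_lec + N,) bool: presynaptic source releases GABA
    Wp, conn,       # (n_lec, gc_cap) plastic weights and adjacency
    gc_cap,
    gmax_lec_gc,
    plasticity_on,
    etap, etam, taup, taum, wmax,
    last_pre,       # (n_lec,)
    last_post,      # (gc_cap,)
    delay_steps,
    decay,          # exp(-dt / tau_decay)
    spike_id, spike_t,  # output buffers (global source ids, ms)
):
    """Advance ``steps`` Euler steps; returns (n_spikes, steps_done, buf_pos)."""
    n_lec = lec_p.shape[0]
    N = Vm.shape[0]
    D1 = delay_steps + 1
    cap = spike_id.shape[0]
    nsp = 0
    pos = buf_pos
    for k in range(steps):
        if nsp > cap - (n_lec + N):
            return nsp, k, pos
        t_new = t0 + (k + 1) * dt

        for i in range(N):
            g_exc[i] = g_exc[i] * decay + buf_exc[pos, i]
            g_inh[i] = g_inh[i] * decay + buf_inh[pos, i]
            buf_exc[pos, i] = 0.0
            buf_inh[pos, i] = 0.0

        for i in range(N):
            if not alive[i]:
                continue
            v = Vm[i]
            ge = g_exc[i]
            gi = g_inh[i] * inh_att[i]
            iexp = 0.0
            if DT[i] > 0.0:
                arg = (v - Vt[i]) / DT[i]
                if arg > 10.0:
                    arg = 10.0
                iexp = gl[i] * DT[i] * math.exp(arg)
            gtot = gl[i] + ge + gi
            v_inf = (gl[i] * El[i] + gi * (-80.0) + iexp + I_inj[i] - wad[i]) / gtot
            # exponential relaxation toward v_inf (exc reversal is 0 mV)
            Vm[i] = v_inf + (v - v_inf) * math.exp(-dt * gtot / Cm[i])
            wad[i] = wad[i] + dt * (al[i] * (v - El[i]) - wad[i]) / tw[i]

        dpos = (pos + delay_steps) % D1
        for j in range(n_lec):
            if uniforms[k, j] < lec_p[j]:
                spike_id[nsp] = j
                spike_t[nsp] = t_new
                nsp += 1
                for i in range(N):
                    gji = G[j, i]
                    if gji != 0.0:
                        buf_exc[dpos, i] += gji
                if plasticity_on:
                    for g in range(gc_cap):
                        if conn[j, g] == 1 and last_post[g] > _NEVER:
                            w = Wp[j, g]
                            w += -w * etam * math.exp(-(t_new - last_post[g]) / taum)
                            if w < 0.0:
                                w = 0.0
                            Wp[j, g] = w
                            G[j, g] = gmax_lec_gc * w
                last_pre[j] = t_new

        for i in range(N):
            if alive[i] and Vm[i] >= Vt[i]:
                Vm[i] = Vr[i]
                wad[i] += bi[i]
                sid = n_lec + i
                spike_id[nsp] = sid
                spike_t[nsp] = t_new
                nsp += 1
                if pre_inh[sid]:
                    for q in range(N):
                        gq = G[sid, q]
                        if gq != 0.0:
                            buf_inh[dpos, q] += gq
                else:
                    for q in range(N):
                        gq = G[sid, q]
                        if gq != 0.0:
                            buf_exc[dpos, q] += gq
                if plasticity_on and i < gc_cap:
                    for j in range(n_lec):
                        if conn[j, i] == 1 and last_pre[j] > _NEVER:
                            w = Wp[j, i]
                            w += (wmax - w) * etap * math.exp(-(t_new - last_pre[j]) / taup)
                            if w > wmax:
                                w = wmax
                            Wp[j, i] = w
                            G[j, i] = gmax_lec_gc * w
                    last_post[i] = t_new

        pos = (pos + 1) % D1
    return nsp, steps, pos
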