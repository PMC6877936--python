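"""The spike-timing-dependent plasticity window on the perforant path.

Prints the weight change for a single pre/post pairing as a function of
the timing lag, starting from the mid-range weight w = 1.  Causal
pairings (pre before post) potentiate with a 20 ms window; acausal ones
depress with a 12 ms window; soft bounds scale updates by the remaining
headroom.
"""

from dgsim.synapses import STDPParams, stdp_delta

p = STDPParams()
print(f"w_max={p.w_max}, eta+={p.eta_plus}, eta-={p.eta_minus}, "
      f"tau+={p.tau_plus} ms, tau-={p.tau_minus} ms\n")
print(" lag(ms)   pre->post Δw   post->pre Δw")
for lag in (0.0, 5.0, 12.0, 20.0, 40.0, 80.0):
    dp = stdp_delta(1.0, lag, p, causal=True)
    dm = stdp_delta(1.0, lag, p, causal=False)
    print(f"  {lag:5.0f}    {dp:+.5f}       {dm:+.5f}")

print("\nPositive column: potentiation of causal pairings, largest at lag 0")
print("and e-folding over tau+; negative column: depression of acausal")
print("pairings over tau-. At w = w_max the causal update vanishes (soft bound).")
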