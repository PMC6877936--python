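"""Step-current response of the four dentate gyrus cell types.

Integrates each AdEx neuron from rest under a constant injected current
and prints the first-spike latency and the spike count over 500 ms.
Latency shortens and rate grows with current; the granule cell (tiny
leak, hard threshold) is by far the most excitable.
"""

from dgsim.neurons import CELL_PARAMS, NeuronState, step

DT = 0.1  # ms

for cell, current in [("GC", 20.0), ("MC", 300.0), ("BC", 300.0), ("HC", 100.0)]:
    p = CELL_PARAMS[cell]
    state = NeuronState(Vm=p.El)
    first, count, t = None, 0, 0.0
    while t < 500.0:
        state, spiked = step(state, p, 0.0, current, DT, t)
        t += DT
        if spiked:
            count += 1
            first = first or t
    print(f"{cell}: I = {current:5.0f} pA -> first spike at "
          f"{first:6.1f} ms, {count:3d} spikes in 500 ms")

print("\nEach line: constant-current response from rest; the latency reflects")
print("the membrane time constant and the rate is capped by spike-triggered")
print("adaptation (w jumps by b per spike and decays with tau_w).")
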