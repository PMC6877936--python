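# Methods

## Model overview

The network is a scaled-down perforant-path circuit.  LEC inputs are
independent Poisson sources carrying binary concept codes (10% of
neurons at 40 Hz, background 0.1 Hz).  The DG contains four AdEx
populations wired as

```
LEC → GC (AMPA, plastic)     LEC → BC (AMPA)
GC → MC, GC → HC (AMPA)      MC → GC, MC → HC (AMPA)
BC → GC, HC → GC (GABA)
```

Three size presets (200, 400, 1000 initial GCs) fix the layer counts and
the per-pathway peak conductances; all neuron parameters are the
published per-type values.  Simulations run at dt = 0.1 ms.

## Units and integration

Parameters are given in mV / nS / nF / pA / ms.  A consistent system for
these equations needs capacitance in pF (nS·mV = pA, pA/pF = mV/ms), so
capacitances enter the dynamics as 1000×the tabulated nF values.  The
granule-cell membrane (Cm = 6.7 pF, gl = 0.03 nS) then has a 223 ms leak
time constant but becomes very fast under synaptic bombardment: summed
GABA conductance of order 100 nS gives an effective time constant of
tens of microseconds.  A plain forward-Euler voltage update at
dt = 0.1 ms is unstable in that regime (it oscillates across threshold
and emits spurious spikes), so the engine uses an exponential-Euler
step: within each dt the conductances define an equilibrium potential
and effective time constant toward which Vm relaxes exactly, while the
spike-initiation current, adaptation current and injected currents are
held constant over the step.  This is unconditionally stable, reduces to
forward Euler for slow membranes, and the production step reproduces the
first-spike latency of a 1 µs forward-Euler reference within 1 ms (a
standing acceptance test).  The scalar single-neuron API
(`neurons.step`) keeps the plain Euler form for transparency; both
integrators converge to the same trajectories as dt → 0.

The GC parameter row has ΔT = 0; we treat it as the hard-threshold limit
of AdEx (no exponential term, spike exactly at Vthr).  For the other
types the exponent argument is capped at +10 to avoid overflow in
pathological states.  There is no refractory period; the reset alone
limits firing.

## Synapses and plasticity

A presynaptic spike increments the target's receptor conductance by the
synaptic peak value after a 2 ms delay; conductances decay exponentially
with τ = 6 ms.  Per-neuron summed conductances with a per-step decay
factor make this O(1) per synapse event.  Currents use the driving-force
convention `I = g(E_syn − Vm)` with E_AMPA = 0 mV, E_GABA = −80 mV, so
AMPA depolarizes and GABA hyperpolarizes.

LEC→GC synapses carry a weight in [0, 2] (initial 1.0, mid-range) with
soft-bounded STDP: a post spike potentiates against the most recent
spike of each connected afferent, Δw = (w_max − w)·η₊·exp(−Δt/τ₊); a pre
spike depresses against the most recent post spike,
Δw = −w·η₋·exp(−Δt/τ₋).  Pairing is nearest-neighbour (the cheapest
standard choice; an all-pairs variant would scale both terms together),
applied online at spike events; simultaneous pre/post events count as
causal.  An offline replay (`synapses.apply_stdp`) implements the same
rule over explicit spike trains and serves as the oracle for the engine.

## Neurogenesis and maturation

Births occur only during stimuli, at a deterministic count
round(rate × duration), evenly spaced at window centers (the published
protocol gives a rate, not a point process; determinism removes one
variance source, and a Poisson alternative would only widen the spread).
A newborn starts at stage 1 wired to ⌈0.4·|active|⌉ of the currently
firing LEC neurons at weight 1, receives BC/HC inhibition and projects
to MC/HC at the standard pathway probabilities.  Each time its age
crosses a fifth of the maturation period it advances a stage, taking
that stage's injected current (100/50/20/0/0 pA) and GABA attenuation
(0.2/0.6/0.8/1.0/1.0), and — if a stimulus is active at that moment —
wiring onto the stage's fraction (0.3/0.2/0.1/0.1) of the active LEC
neurons it is not yet connected to.  Stages never regress; stage 5 is
absorbing.  The injected current makes stage 1–3 cells fire tonically
(tens of Hz) regardless of input, which is what lets temporally adjacent
stimuli share them.

Test phases present each concept for one stimulus duration from a rested
dynamic state with plasticity and neurogenesis frozen.  In pair trials
the network is first brought to full maturity: between the end of
training and the (conceptually later) test no stimuli occur, and stage
transitions without an active stimulus add no wiring, so fast-forwarding
the schedule is exact up to negligible background plasticity.  In the
multi-context experiment the fast-forward is optional and off by
default; there the still-immature cohort is a fixed ~15 cells and an
ever-smaller fraction of the grown layer.

## Connection probabilities (calibration)

The projection ratios between layers are not recoverable from the
source tables, so they are explicit configuration with calibrated
defaults:

| pathway | p | pathway | p |
|---|---|---|---|
| LEC→GC | 0.02 | MC→GC | 0.1 |
| LEC→BC | 0.2 | MC→HC | 0.2 |
| GC→MC | 0.2 | BC→GC | 0.2 |
| GC→HC | 0.5 | HC→GC | 1.0 |

Calibration targeted the circuit's stated qualitative behavior on the
200-GC preset, in this order: (i) sparse granule coding — fewer than 20%
of mature GCs fire during a 1 s concept stimulus; (ii) reproducible
codes — presenting the same concept twice yields GC rate vectors with
cosine similarity near 0.9, so that the no-neurogenesis input→output
similarity map is close to the identity; (iii) the neurogenesis regimes
(integration for adjacent stimuli, integration of highly similar pairs).
Two structural lessons from the calibration: sparse perforant-path
afferents (mean two per GC) give each responder a graded, wiring-
determined drive, and a *fully* connected basket-cell blanket
synchronizes winner selection so strongly that codes become
irreproducible (same-stimulus cosine ≈ 0.5) — moderately dense BC
inhibition (p = 0.2) plus a dense HIPP feedback blanket (p = 1.0)
provides the activity-scaled threshold without the synchrony.

## Randomness and reproducibility

Every stochastic element (wiring, pattern draws, Poisson inputs, newborn
afferent choices) flows from one `numpy` Generator per trial.  Trial
seeds derive from a base seed and the cell coordinates via SHA-256
(stable across platforms, < 2³¹).  Identical (config, protocol, seed)
gives bit-identical spike records; a test asserts this.

## What the synthetic pieces do and do not show

Concept codes are uniform random sparse sets with exactly constructed
pairwise overlaps; real entorhinal codes are neither uniform nor exactly
binary, so quantitative PSI values speak to the model, not to cortex.
The multi-context reference matrix is a synthetic two-level block matrix
(within-context similarity 0.6, across 0.1, truncated Gaussian noise
SD 0.05) standing in for a human feature-norm similarity matrix; it
preserves the block structure such a matrix exhibits but none of its
graded semantic detail, so context-experiment results show that the
learned geometry acquires the right *block* organization, not that it
matches human similarity judgments entry by entry.  A loader for a real
concepts×features CSV is provided.

## Known limitations

- At neurogenesis 3/s with 5 s spacing the model integrates slightly
  where the crossover behavior would demand weak separation at low input
  similarity: a newborn's afferents are drawn from the active input set,
  so its cross-stimulus drive grows linearly with input overlap and its
  (weight-saturated) cross response sits in the same conductance range as
  mature responders — no response threshold can remove the cross-talk
  without silencing the mature code.  The integration side of the regime
  (adjacent stimuli, high similarity) is robust.
- Context-repetition convergence saturates early: STDP at the published
  rates consolidates a newborn's afferents within its first stimulus, so
  most of the reference-similarity gain arrives with the first
  repetition and later passes plateau.
- No CA3, no cell death, no novelty-modulated neurogenesis rate, no
  spatial (MEC) input; maturation is accelerated to seconds by design,
  with stimulus durations scaled in proportion (2 s and 4 s stimuli for
  the 10 s and 20 s maturation variants).
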