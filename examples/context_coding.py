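"""Multi-context concept coding against a block-structured reference.

Trains the 200-GC network on one pass over 14 contexts x 4 concepts
(neurogenesis 3 cells/s), tests all 56 concepts, and compares the
granule-cell concept-similarity matrix with a synthetic feature-norm
style reference (high within-context similarity, low across) and with
the raw input (EC) codes.
"""

import numpy as np

from dgsim.experiments import ContextSpec, run_context_experiment, synth_reference_matrix
from dgsim.io import preset_config

cfg = preset_config("200gc", neurogenesis_rate=3.0)
ref = synth_reference_matrix(rng=np.random.default_rng(0))
spec = ContextSpec(config=cfg, repetitions=(1,), n_runs=1, base_seed=8)
res = run_context_experiment(spec, ref)

gc = res["gc_matrix"][1].values
iu = np.triu_indices(56, 1)
ctx = np.repeat(np.arange(14), 4)
within = ctx[iu[0]] == ctx[iu[1]]
print(f"GC-reference matrix similarity: {100 * res['matrix_similarity_mean'][1]:.2f}%")
print(f"EC-reference matrix similarity: {100 * res['ec_reference_similarity'][1]:.2f}%")
print(f"mean GC similarity within contexts: {gc[iu][within].mean():.3f}")
print(f"mean GC similarity across contexts: {gc[iu][~within].mean():.3f}")
print("\nAfter one pass the granule-cell geometry already matches the")
print("reference better than the random input codes do: concepts of the")
print("same context moved closer (integration) and different contexts")
print("moved apart (separation).")
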