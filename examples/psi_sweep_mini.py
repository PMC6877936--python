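"""A miniature PSI sweep with a tidy summary table.

Sweeps neurogenesis rate {0, 3} x interval {1, 5} s at 30% input
similarity, 3 runs per cell, and prints the per-cell mean and standard
deviation of PSI.  The full factorial design of the published experiment
(6 rates x 5 intervals x 10 similarities x 10 runs = 3000 trials) uses
exactly the same harness via `dgsim sweep`.
"""

from dgsim.experiments import SweepSpec, run_sweep, summarize_sweep
from dgsim.io import preset_config

spec = SweepSpec(
    config=preset_config("200gc"),
    rates=(0.0, 3.0),
    intervals=(1.0, 5.0),
    similarities=(0.3,),
    n_runs=3,
    base_seed=0,
)
table = run_sweep(spec)
print(summarize_sweep(table).to_string(index=False))
print("\nWithout neurogenesis (rate 0) the interval has no systematic effect;")
print("with neurogenesis, short intervals push the mean PSI negative")
print("(integration through shared newborn cells).")
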