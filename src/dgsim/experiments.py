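"""End-to-end protocols: the pairwise PSI sweep and the 14-context experiment.

Both experiments share a two-phase trial structure.  In the
training/growth phase, stimuli drive the network with STDP and
neurogenesis enabled.  The test phase then re-presents each concept for
one stimulus duration with plasticity and neurogenesis switched off, and
population rate vectors over each presentation give the input (EC) and
output (GC) similarities.  The test runs after the youngest granule cell
has matured: no stimuli are delivered while the last cohort finishes
developing, so the intervening stage transitions only strip the
immature excitability boosts and add no wiring, and are applied directly.

The multi-context experiment evaluates the learned concept geometry
against a reference concept-similarity matrix.  The reference shipped
here is a synthetic stand-in for a feature-norm (property-listing)
similarity matrix: concepts within a context are highly similar, across
contexts weakly so, with truncated Gaussian perturbations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    PSIRecord,
    SimilarityMatrix,
    rate_vector,
    similarity,
    similarity_matrix,
    matrix_similarity,
    psi,
)
from .network import NetworkConfig, build, simulate
from .stimuli import (
    Protocol,
    context_protocol,
    make_context_set,
    make_pattern_pair,
    pair_protocol,
)

__all__ = [
    "SweepSpec",
    "ContextSpec",
    "derive_seed",
    "run_pair_trial",
    "run_sweep",
    "run_context_experiment",
    "synth_reference_matrix",
    "load_reference_matrix",
]


def derive_seed(base_seed: int, *fields) -> int:
    """Stable per-cell seed from the base seed and the cell coordinates.

    Floats are quantized to 1e-3 before hashing so the derivation does not
    depend on repr formatting; the result is a non-negative 31-bit int.
    """
    parts = [str(int(base_seed))]
    for f in fields:
        parts.append(str(int(round(f * 1000))) if isinstance(f, float) else str(f))
    digest = hashlib.sha256("|".join(parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class SweepSpec:
    """Factorial pair-trial sweep over neurogenesis rate, interval, similarity."""

    config: NetworkConfig
    rates: tuple[float, ...]
    intervals: tuple[float, ...]          # onset-to-onset, s
    similarities: tuple[float, ...]       # fractions
    n_runs: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rates and self.intervals and self.similarities):
            raise ValueError("sweep lists must be non-empty")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.rates) * len(self.intervals) * len(self.similarities) * self.n_runs


@dataclass(frozen=True)
class ContextSpec:
    """Multi-context concept-coding experiment settings."""

    config: NetworkConfig
    n_contexts: int = 14
    per_context: int = 4
    repetitions: tuple[int, ...] = (1, 2, 3, 4, 5)
    sparsity: float = 0.1
    max_pairwise: float = 0.5
    n_runs: int = 10
    base_seed: int = 0
    mature_before_test: bool = False


def run_pair_trial(
    config: NetworkConfig,
    ng_rate: float,
    time_interval: float,
    input_similarity: float,
    seed: int,
    sparsity: float = 0.1,
    mature_before_test: bool = True,
) -> PSIRecord:
    """One seeded trial: build, train on a concept pair, test, compute PSI.

    The stimulus duration scales with the maturation period (1 s for the
    5 s period, 2 s for 10 s, 4 s for 20 s) so stimulus and development
    time scales stay matched.
    """
    rng = np.random.default_rng(seed)
    duration = config.maturation_period / 5.0
    cfg = NetworkConfig(**{**config.__dict__, "neurogenesis_rate": ng_rate})
    a, b = make_pattern_pair(cfg.n_lec, sparsity, input_similarity, rng)
    net = build(cfg, rng)
    train = pair_protocol(a, b, duration=duration, time_interval=time_interval)
    simulate(net, train, plasticity_on=True, neurogenesis_on=True)
    if mature_before_test:
        net.mature_all()

    def present(pattern):
        # independent test presentation from a rested network state
        net.reset_dynamic_state()
        rec = simulate(net, Protocol(events=((pattern, 0.0, duration),),
                                     total_duration=duration),
                       plasticity_on=False, neurogenesis_on=False)
        w = (0.0, duration * 1000.0)
        return rate_vector(rec, "LEC", w), rate_vector(rec, "GC", w)

    ec_a, gc_a = present(a)
    ec_b, gc_b = present(b)
    sim_ec = similarity(ec_a, ec_b)
    sim_gc = similarity(gc_a, gc_b)
    return PSIRecord(
        neurogenesis_rate=ng_rate,
        time_interval=time_interval,
        input_similarity=input_similarity,
        seed=seed,
        sim_EC=sim_ec,
        sim_GC=sim_gc,
        psi=psi(sim_ec, sim_gc),
    )


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Full factorial sweep; returns the tidy per-trial PSI table.

    Per-cell seeds derive deterministically from the base seed and the
    cell coordinates, so any sub-slice of the sweep reproduces exactly.
    """
    rows = []
    for rate in spec.rates:
        for interval in spec.intervals:
            for sim in spec.similarities:
                for run in range(spec.n_runs):
                    seed = derive_seed(spec.base_seed, rate, interval, sim, run)
                    rec = run_pair_trial(spec.config, rate, interval, sim, seed)
                    rows.append(rec.__dict__)
                    if progress:
                        print(f"rate={rate} TI={interval} sim={sim} run={run} "
                              f"psi={rec.psi:+.3f}")
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and std of PSI per (rate, interval, similarity) cell."""
    return (
        table.groupby(["neurogenesis_rate", "time_interval", "input_similarity"])
        .agg(psi_mean=("psi", "mean"), psi_std=("psi", "std"), n=("psi", "size"))
        .reset_index()
    )


def synth_reference_matrix(
    n_contexts: int = 14,
    per_context: int = 4,
    within_sim: float = 0.6,
    across_sim: float = 0.1,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> SimilarityMatrix:
    """Synthetic block-structured concept similarity reference.

    Stands in for a feature-norm similarity matrix: entries for concept
    pairs within a context sit near ``within_sim``, across contexts near
    ``across_sim``, perturbed by truncated Gaussian noise and clipped to
    [0, 1]; unit diagonal, symmetric.
    """
    if not 0.0 <= across_sim < within_sim <= 1.0:
        raise ValueError("need 0 <= across_sim < within_sim <= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    k = n_contexts * per_context
    labels = tuple(f"ctx{i:02d}_c{j}" for i in range(n_contexts) for j in range(per_context))
    ctx = np.repeat(np.arange(n_contexts), per_context)
    vals = np.where(ctx[:, None] == ctx[None, :], within_sim, across_sim).astype(float)
    noise = rng.normal(0.0, noise_sd, size=(k, k))
    noise = np.triu(noise, 1)
    vals = np.clip(vals + noise + noise.T, 0.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(labels=labels, values=vals)


def load_reference_matrix(path: str, n_contexts: int = 14, per_context: int = 4) -> SimilarityMatrix:
    """Build a reference similarity matrix from a concepts x features CSV.

    Rows are concepts ordered context-by-context (first column = label);
    remaining columns are feature values.  The matrix is the pairwise
    cosine similarity of the feature vectors.
    """
    df = pd.read_csv(path, index_col=0)
    if len(df) != n_contexts * per_context:
        raise ValueError(f"expected {n_contexts * per_context} concept rows, got {len(df)}")
    feats = df.to_numpy(dtype=float)
    labels = tuple(f"ctx{i:02d}_c{j}" for i in range(n_contexts) for j in range(per_context))
    return similarity_matrix(list(feats), labels=labels)


def run_context_experiment(
    spec: ContextSpec,
    reference: SimilarityMatrix,
) -> dict:
    """Train on repeated context passes and compare GC geometry to a reference.

    For every repetition count and run, a fresh network learns a fresh
    random 56-concept code set (all pairwise input similarities below the
    bound), then all concepts are tested.  Returns per-repetition mean and
    per-run matrix similarities, the GC similarity matrices of the first
    run, and the matching EC (input) matrices.
    """
    duration = spec.config.maturation_period / 5.0
    out = {"repetitions": list(spec.repetitions), "gc_matrix": {}, "ec_matrix": {},
           "matrix_similarity": {}, "matrix_similarity_mean": {},
           "ec_reference_similarity": {}}
    for rep in spec.repetitions:
        sims, ec_sims = [], []
        for run in range(spec.n_runs):
            seed = derive_seed(spec.base_seed, "ctx", rep, run)
            rng = np.random.default_rng(seed)
            patterns = make_context_set(
                spec.n_contexts, spec.per_context, spec.config.n_lec,
                spec.sparsity, rng, max_pairwise=spec.max_pairwise,
            )
            if tuple(p.id for p in patterns) != reference.labels:
                raise ValueError("reference matrix labels do not match the concept set")
            net = build(spec.config, rng)
            train = context_protocol(patterns, rep, rng, duration=duration)
            simulate(net, train, plasticity_on=True, neurogenesis_on=True)
            if spec.mature_before_test:
                net.mature_all()
            gc_vecs, ec_vecs = [], []
            w = (0.0, duration * 1000.0)
            for p in patterns:
                net.reset_dynamic_state()
                rec = simulate(net, Protocol(events=((p, 0.0, duration),),
                                             total_duration=duration),
                               plasticity_on=False, neurogenesis_on=False)
                gc_vecs.append(rate_vector(rec, "GC", w))
                ec_vecs.append(rate_vector(rec, "LEC", w))
            labels = tuple(p.id for p in patterns)
            gc_mat = similarity_matrix(gc_vecs, labels=labels)
            ec_mat = similarity_matrix(ec_vecs, labels=labels)
            sims.append(matrix_similarity(gc_mat, reference))
            ec_sims.append(matrix_similarity(ec_mat, reference))
            if run == 0:
                out["gc_matrix"][rep] = gc_mat
                out["ec_matrix"][rep] = ec_mat
        out["matrix_similarity"][rep] = sims
        out["matrix_similarity_mean"][rep] = float(np.mean(sims))
        out["ec_reference_similarity"][rep] = float(np.mean(ec_sims))
    return out
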