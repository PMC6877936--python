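"""Binary LEC concept patterns and timed stimulus protocols.

Each concept is a sparse binary code over the lateral entorhinal cortex
(LEC) input layer: 10% of the LEC neurons fire at 40 Hz while the rest
emit 0.1 Hz background spikes.  Pairwise code similarity is the cosine of
the binary vectors, which for equal-size active sets reduces to
|A ∩ B| / |A| — so a pair with a requested similarity is built by sharing
exactly that fraction of active indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConceptPattern",
    "Protocol",
    "RATE_ACTIVE",
    "RATE_BACKGROUND",
    "make_pattern",
    "make_pattern_pair",
    "make_context_set",
    "pair_protocol",
    "context_protocol",
    "binary_similarity",
]

RATE_ACTIVE = 40.0      # Hz
RATE_BACKGROUND = 0.1   # Hz


@dataclass(frozen=True)
class ConceptPattern:
    """A binary concept code on the LEC layer."""

    id: str
    active: frozenset[int]
    n_lec: int
    rate_active: float = RATE_ACTIVE
    rate_background: float = RATE_BACKGROUND
    context: str | None = None

    def rates(self) -> np.ndarray:
        """Per-neuron firing rate vector (Hz)."""
        r = np.full(self.n_lec, self.rate_background)
        r[list(self.active)] = self.rate_active
        return r

    def binary(self) -> np.ndarray:
        v = np.zeros(self.n_lec)
        v[list(self.active)] = 1.0
        return v


@dataclass(frozen=True)
class Protocol:
    """Ordered, non-overlapping timed stimulus events.

    ``events`` holds (pattern, onset_s, duration_s) triples sorted by onset.
    """

    events: tuple[tuple[ConceptPattern, float, float], ...]
    total_duration: float

    def __post_init__(self) -> None:
        end = 0.0
        for _, onset, dur in self.events:
            if onset < end - 1e-9:
                raise ValueError("protocol events overlap")
            end = onset + dur
        if self.events and end > self.total_duration + 1e-9:
            raise ValueError("events extend past total duration")


def binary_similarity(a: ConceptPattern, b: ConceptPattern) -> float:
    """Cosine similarity of the binary codes (= overlap/size for equal sizes)."""
    inter = len(a.active & b.active)
    return inter / float(np.sqrt(len(a.active) * len(b.active)))


def _n_active(n_lec: int, sparsity: float) -> int:
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    return int(round(sparsity * n_lec))


def make_pattern(
    n_lec: int,
    sparsity: float,
    rng: np.random.Generator,
    id: str = "concept",
    context: str | None = None,
) -> ConceptPattern:
    """Uniformly random active set of round(sparsity * n_lec) LEC neurons."""
    k = _n_active(n_lec, sparsity)
    active = frozenset(rng.choice(n_lec, size=k, replace=False).tolist())
    return ConceptPattern(id=id, active=active, n_lec=n_lec, context=context)


def make_pattern_pair(
    n_lec: int,
    sparsity: float,
    target_similarity: float,
    rng: np.random.Generator,
    ids: tuple[str, str] = ("A", "B"),
) -> tuple[ConceptPattern, ConceptPattern]:
    """Two patterns whose binary cosine similarity equals the target exactly.

    The active sets share exactly k = target_similarity * |active| neurons;
    k must come out integral.
    """
    n_act = _n_active(n_lec, sparsity)
    k_shared_f = target_similarity * n_act
    k_shared = int(round(k_shared_f))
    if abs(k_shared_f - k_shared) > 1e-9 or not 0 <= k_shared <= n_act:
        raise ValueError(
            f"target similarity {target_similarity} infeasible for {n_act} active neurons"
        )
    need = 2 * n_act - k_shared
    if need > n_lec:
        raise ValueError("pattern pair does not fit in the LEC layer")
    pool = rng.choice(n_lec, size=need, replace=False)
    shared = pool[:k_shared]
    only_a = pool[k_shared:n_act]
    only_b = pool[n_act:]
    a = ConceptPattern(ids[0], frozenset(np.concatenate([shared, only_a]).tolist()), n_lec)
    b = ConceptPattern(ids[1], frozenset(np.concatenate([shared, only_b]).tolist()), n_lec)
    return a, b


def make_context_set(
    n_contexts: int,
    per_context: int,
    n_lec: int,
    sparsity: float,
    rng: np.random.Generator,
    max_pairwise: float = 0.5,
    max_tries: int = 10000,
) -> list[ConceptPattern]:
    """Random concept codes grouped into contexts, all pairwise similarity < max_pairwise.

    Rejection sampling: each candidate pattern is redrawn until it clears
    the similarity bound against every previously accepted pattern.
    """
    n_act = _n_active(n_lec, sparsity)
    accepted: list[ConceptPattern] = []
    for ci in range(n_contexts):
        for cj in range(per_context):
            label = f"ctx{ci:02d}_c{cj}"
            for _ in range(max_tries):
                cand = make_pattern(n_lec, sparsity, rng, id=label, context=f"ctx{ci:02d}")
                if all(len(cand.active & p.active) / n_act < max_pairwise
                       for p in accepted):
                    accepted.append(cand)
                    break
            else:
                raise RuntimeError(
                    f"rejection sampling failed for {label} after {max_tries} tries "
                    f"(n_lec={n_lec}, sparsity={sparsity}, bound={max_pairwise})"
                )
    return accepted


def pair_protocol(
    a: ConceptPattern,
    b: ConceptPattern,
    duration: float = 1.0,
    time_interval: float = 1.0,
) -> Protocol:
    """Two-stimulus protocol with onset-to-onset spacing ``time_interval`` s.

    An interval equal to the stimulus duration means back-to-back
    presentation; a 5 s interval puts the second onset 5 s after the
    first.
    """
    if time_interval < duration:
        raise ValueError("time_interval below stimulus duration: events would overlap")
    events = ((a, 0.0, duration), (b, time_interval, duration))
    return Protocol(events=events, total_duration=time_interval + duration)


def context_protocol(
    patterns: list[ConceptPattern],
    repetitions: int,
    rng: np.random.Generator,
    duration: float = 1.0,
    inter_context_gap: float = 0.0,
) -> Protocol:
    """Back-to-back presentation of all contexts, repeated whole-pass.

    Contexts run in fixed order within a pass; the four concepts of each
    context are shuffled afresh for every presentation of that context.
    The full pass over all contexts is repeated ``repetitions`` times.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    by_ctx: dict[str, list[ConceptPattern]] = {}
    for p in patterns:
        by_ctx.setdefault(p.context or p.id, []).append(p)
    events = []
    t = 0.0
    for _ in range(repetitions):
        for ctx in by_ctx:
            order = rng.permutation(len(by_ctx[ctx]))
            for idx in order:
                events.append((by_ctx[ctx][idx], t, duration))
                t += duration
            t += inter_context_gap
    return Protocol(events=tuple(events), total_duration=t)
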