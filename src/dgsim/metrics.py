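"""Population-rate vectors, cosine similarity and the pattern separation index.

The similarity between two population responses is the normalized dot
product (cosine) of their firing-rate vectors.  The pattern separation
index (PSI) compares input (EC) and output (GC) similarities for the
same concept pair:

    PSI = (Sim_EC - Sim_GC) / Sim_EC        if Sim_EC > Sim_GC
    PSI = (Sim_EC - Sim_GC) / (1 - Sim_EC)  if Sim_EC < Sim_GC

PSI > 0 means the GC layer pulled the codes apart (pattern separation);
PSI < 0 means it pushed them together (pattern integration); both
branches are normalized to land in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateVector",
    "SimilarityMatrix",
    "PSIRecord",
    "rate_vector",
    "similarity",
    "psi",
    "similarity_matrix",
    "matrix_similarity",
]


@dataclass(frozen=True)
class RateVector:
    """Per-neuron mean firing rates (Hz) of one layer over a time window."""

    layer: str
    rates: np.ndarray
    window: tuple[float, float]  # (start_ms, end_ms)

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric K x K concept-similarity matrix with unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")

    def upper_triangle(self) -> np.ndarray:
        """Strict upper triangle, flattened row-major."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass(frozen=True)
class PSIRecord:
    """One pair trial: conditions, measured similarities, and PSI."""

    neurogenesis_rate: float
    time_interval: float
    input_similarity: float
    seed: int
    sim_EC: float
    sim_GC: float
    psi: float


def rate_vector(spikes, layer: str, window: tuple[float, float]) -> RateVector:
    """Mean firing rates over ``window`` (ms) for every neuron of a layer.

    ``spikes`` is a :class:`~dgsim.network.SpikeRecords`; silent neurons
    contribute zeros, so the vector length always equals the layer size.
    """
    start, end = window
    if end <= start:
        raise ValueError("empty rate window")
    n = spikes.layer_size(layer)
    sel = (spikes.layer == layer) & (spikes.t_ms >= start) & (spikes.t_ms < end)
    counts = np.bincount(spikes.neuron_id[sel], minlength=n).astype(float)
    return RateVector(layer=layer, rates=counts / ((end - start) / 1000.0), window=window)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("cosine similarity of a zero vector defined as 0", stacklevel=3)
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def similarity(a: RateVector | np.ndarray, b: RateVector | np.ndarray) -> float:
    """Normalized dot product of two rate vectors; 0 if either is all-zero."""
    va = a.rates if isinstance(a, RateVector) else np.asarray(a, float)
    vb = b.rates if isinstance(b, RateVector) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError("rate vector length mismatch")
    return _cosine(va, vb)


def psi(sim_EC: float, sim_GC: float) -> float:
    """Pattern separation index from input and output similarities."""
    if not (0.0 <= sim_EC <= 1.0 and 0.0 <= sim_GC <= 1.0):
        raise ValueError("similarities must lie in [0, 1]")
    diff = sim_EC - sim_GC
    if diff > 0:
        return diff / sim_EC
    if diff < 0:
        return diff / (1.0 - sim_EC)
    return 0.0


def similarity_matrix(vectors: list[RateVector | np.ndarray], labels=None) -> SimilarityMatrix:
    """All-pairs cosine similarity; unit diagonal by construction."""
    arrs = [v.rates if isinstance(v, RateVector) else np.asarray(v, float) for v in vectors]
    k = len(arrs)
    if labels is None:
        labels = tuple(str(i) for i in range(k))
    vals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = _cosine(arrs[i], arrs[j])
    return SimilarityMatrix(labels=tuple(labels), values=vals)


def matrix_similarity(m1: SimilarityMatrix, m2: SimilarityMatrix) -> float:
    """Cosine similarity of two concept matrices over strict upper triangles.

    The unit diagonals carry no information and would inflate agreement,
    so they are excluded.
    """
    if m1.labels != m2.labels:
        raise ValueError("similarity matrices carry different concept labels")
    return _cosine(m1.upper_triangle(), m2.upper_triangle())


def records_to_frame(records: list[PSIRecord]) -> pd.DataFrame:
    """Tidy PSI table, one row per trial."""
    return pd.DataFrame([r.__dict__ for r in records])
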