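"""Configuration presets, YAML loading, and result serialization.

Three size presets mirror the published scaled-down networks; the
pathway peak conductances are the published per-size tables and the
layer sizes scale with the initial granule cell count.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import SimilarityMatrix
from .network import DEFAULT_CONN_PROB, NetworkConfig

__all__ = ["PRESETS", "ConfigError", "RunManifest", "preset_config", "load_config",
           "write_results", "read_matrix_csv", "write_matrix_csv"]


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


#: layer sizes (LEC, GC, MC, BC, HC), max neurogenesis rate, and peak
#: conductances (nS) per pathway for each network size preset.
PRESETS: dict[str, dict] = {
    "200gc": {
        "sizes": dict(n_lec=100, n_gc_initial=200, n_mc=50, n_bc=25, n_hc=50),
        "max_ng_rate": 5.0,
        "gmax": {
            ("LEC", "GC"): 10.0, ("LEC", "BC"): 12.0,
            ("GC", "MC"): 6.0, ("GC", "HC"): 1.0,
            ("MC", "GC"): 1.0, ("MC", "HC"): 0.2,
            ("BC", "GC"): 120.0, ("HC", "GC"): 20.0,
        },
    },
    "400gc": {
        "sizes": dict(n_lec=200, n_gc_initial=400, n_mc=100, n_bc=50, n_hc=100),
        "max_ng_rate": 10.0,
        "gmax": {
            ("LEC", "GC"): 6.0, ("LEC", "BC"): 8.0,
            ("GC", "MC"): 10.0, ("GC", "HC"): 0.4,
            ("MC", "GC"): 1.0, ("MC", "HC"): 0.1,
            ("BC", "GC"): 120.0, ("HC", "GC"): 30.0,
        },
    },
    "1000gc": {
        "sizes": dict(n_lec=500, n_gc_initial=1000, n_mc=250, n_bc=125, n_hc=250),
        "max_ng_rate": 25.0,
        "gmax": {
            ("LEC", "GC"): 3.1, ("LEC", "BC"): 5.0,
            ("GC", "MC"): 12.0, ("GC", "HC"): 0.1,
            ("MC", "GC"): 1.0, ("MC", "HC"): 0.1,
            ("BC", "GC"): 120.0, ("HC", "GC"): 20.0,
        },
    },
}


def preset_config(
    preset: str = "200gc",
    neurogenesis_rate: float = 0.0,
    maturation_period: float = 5.0,
    conn_prob: dict | None = None,
    dt: float = 0.1,
    seed: int | None = None,
) -> NetworkConfig:
    """A :class:`NetworkConfig` for one of the published size presets."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; valid presets: {sorted(PRESETS)}")
    p = PRESETS[preset]
    probs = dict(DEFAULT_CONN_PROB)
    if conn_prob:
        probs.update(conn_prob)
    return NetworkConfig(
        **p["sizes"],
        neurogenesis_rate=neurogenesis_rate,
        maturation_period=maturation_period,
        gmax_table=dict(p["gmax"]),
        conn_prob_table=probs,
        dt=dt,
        seed=seed,
    )


def _pathway_key(s: str) -> tuple[str, str]:
    pre, _, post = s.partition("->")
    return pre.strip().upper(), post.strip().upper()


def load_config(path: str | Path) -> NetworkConfig:
    """Load a network configuration from a YAML file.

    Schema: top-level ``preset`` selects size/conductance defaults;
    optional sections ``neurogenesis`` (rate, maturation_period),
    ``topology`` (``"PRE->POST": prob`` overrides), ``synapses``
    (``"PRE->POST": gmax`` overrides) and ``simulation`` (dt, seed).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    preset = raw.get("preset", "200gc")
    ng = raw.get("neurogenesis", {})
    sim = raw.get("simulation", {})
    try:
        cfg = preset_config(
            preset,
            neurogenesis_rate=float(ng.get("rate", 0.0)),
            maturation_period=float(ng.get("maturation_period", 5.0)),
            conn_prob={_pathway_key(k): float(v)
                       for k, v in raw.get("topology", {}).items()},
            dt=float(sim.get("dt", 0.1)),
            seed=sim.get("seed"),
        )
    except (ValueError, TypeError) as e:
        raise ConfigError(str(e)) from e
    gmax_over = {_pathway_key(k): float(v) for k, v in raw.get("synapses", {}).items()}
    if gmax_over:
        table = dict(cfg.gmax_table)
        table.update(gmax_over)
        cfg = NetworkConfig(**{**cfg.__dict__, "gmax_table": table})
    return cfg


@dataclass(frozen=True)
class RunManifest:
    """Inventory of one result set, sufficient to re-run it."""

    config: dict
    seed: int | None
    version: str
    created: str
    files: tuple[str, ...]


def _config_dict(cfg: NetworkConfig) -> dict:
    d = dict(cfg.__dict__)
    d["gmax_table"] = {f"{k[0]}->{k[1]}": v for k, v in d["gmax_table"].items()}
    d["conn_prob_table"] = {f"{k[0]}->{k[1]}": v for k, v in d["conn_prob_table"].items()}
    d["stdp"] = dict(d["stdp"].__dict__)
    return d


def write_matrix_csv(mat: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(mat.values, index=list(mat.labels), columns=list(mat.labels)).to_csv(path)


def read_matrix_csv(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(labels=tuple(df.columns), values=df.to_numpy(dtype=float))


def write_results(
    out_dir: str | Path,
    config: NetworkConfig,
    seed: int | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
    matrices: dict[str, SimilarityMatrix] | None = None,
) -> RunManifest:
    """Write tidy CSV tables and labeled matrices plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in (tables or {}).items():
        fn = f"{name}.csv"
        df.to_csv(out / fn, index=False)
        files.append(fn)
    for name, mat in (matrices or {}).items():
        fn = f"{name}.csv"
        write_matrix_csv(mat, out / fn)
        files.append(fn)
    manifest = RunManifest(
        config=_config_dict(config),
        seed=seed,
        version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        files=tuple(files),
    )
    (out / "manifest.json").write_text(json.dumps(manifest.__dict__, indent=2, default=str))
    return manifest
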