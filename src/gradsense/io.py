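"""Config-file parsing and tabular serialization.

The run configuration is a small nested YAML document::

    receptors:
      angles:  [0.7853981633974483, 3.141592653589793, -1.5707963267948966]
      extents: [0.10471975511965977, 0.10471975511965977, 0.20943951023931953]
    source:  {R: 2.0, theta0: 0.0, D: 1.0}
    solver:  {n_nodes: 64, tol: 1.0e-12}
    simulate: {M: 10000, T_max: 1000.0, seed: 7}
    inference: {r_min: 1.05, r_max: 40.0, n_r: 64, n_theta: 256, M_s: 1001}

Unknown keys are rejected so typos fail loudly.  Floats are serialized with
full ``repr`` precision, so configurations round-trip bit-exactly.  Count
tables are CSV with header ``receptor_id,count``; arrival tables are CSV
with header ``time,angle,receptor_id,censored``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import CountTable, ReceptorConfig, SourceSpec, build_config
from .simulate import ArrivalTable

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "read_counts",
    "write_counts",
    "read_arrivals",
    "write_arrivals",
    "write_metadata",
]

_SOLVER_DEFAULTS = {"n_nodes": 64, "tol": 1e-12}
_SIMULATE_DEFAULTS = {"M": 10_000, "T_max": 1000.0, "seed": 0}
_INFERENCE_DEFAULTS = {"r_min": 1.05, "r_max": 40.0, "n_r": 64,
                       "n_theta": 256, "M_s": 1001}


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for CLI runs; all defaults documented above."""

    receptors: ReceptorConfig
    source: SourceSpec
    solver: dict = field(default_factory=lambda: dict(_SOLVER_DEFAULTS))
    simulate: dict = field(default_factory=lambda: dict(_SIMULATE_DEFAULTS))
    inference: dict = field(default_factory=lambda: dict(_INFERENCE_DEFAULTS))


def _merge_section(raw: dict, defaults: dict, name: str) -> dict:
    unknown = set(raw) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    out = dict(defaults)
    out.update(raw)
    return out


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    unknown = set(raw) - {"receptors", "source", "solver", "simulate",
                          "inference"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    try:
        rec = raw["receptors"]
        receptors = build_config(rec["angles"], rec["extents"])
    except KeyError as exc:
        raise ConfigError(f"missing receptor key: {exc}") from exc
    unknown = set(raw.get("receptors", {})) - {"angles", "extents"}
    if unknown:
        raise ConfigError(f"unknown keys in 'receptors': {sorted(unknown)}")
    src_raw = raw.get("source", {})
    unknown = set(src_raw) - {"R", "theta0", "D"}
    if unknown:
        raise ConfigError(f"unknown keys in 'source': {sorted(unknown)}")
    source = SourceSpec(R=src_raw.get("R", 2.0),
                        theta0=src_raw.get("theta0", 0.0),
                        D=src_raw.get("D", 1.0))
    return RunConfig(
        receptors=receptors,
        source=source,
        solver=_merge_section(raw.get("solver", {}), _SOLVER_DEFAULTS,
                              "solver"),
        simulate=_merge_section(raw.get("simulate", {}), _SIMULATE_DEFAULTS,
                                "simulate"),
        inference=_merge_section(raw.get("inference", {}),
                                 _INFERENCE_DEFAULTS, "inference"),
    )


def save_config(cfg: RunConfig, path) -> None:
    """Serialize a run configuration (full float precision)."""
    doc = {
        "receptors": {
            "angles": [float(a) for a in cfg.receptors.angles],
            "extents": [float(e) for e in cfg.receptors.extents],
        },
        "source": {"R": cfg.source.R, "theta0": cfg.source.theta0,
                   "D": cfg.source.D},
        "solver": cfg.solver,
        "simulate": cfg.simulate,
        "inference": cfg.inference,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_counts(path, total: int | None = None, t: float = np.inf) -> CountTable:
    """Read a ``receptor_id,count`` CSV into a :class:`CountTable`."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["receptor_id", "count"]:
        raise ConfigError(f"{path}: expected header receptor_id,count")
    counts = np.zeros(int(df["receptor_id"].max()) + 1, dtype=np.int64)
    counts[df["receptor_id"].to_numpy()] = df["count"].to_numpy()
    return CountTable(counts=counts,
                      total=int(counts.sum()) if total is None else total,
                      t=t)


def write_counts(counts: CountTable, path) -> None:
    pd.DataFrame(
        {"receptor_id": np.arange(counts.counts.size),
         "count": counts.counts}
    ).to_csv(path, index=False)


def write_arrivals(table: ArrivalTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_arrivals(path) -> ArrivalTable:
    df = pd.read_csv(path)
    need = ["time", "angle", "receptor_id", "censored"]
    if list(df.columns[: len(need)]) != need:
        raise ConfigError(f"{path}: expected header {','.join(need)}")
    cens = df["censored"].to_numpy().astype(bool)
    times = df["time"].to_numpy(dtype=float)
    return ArrivalTable(
        times=times,
        angles=df["angle"].to_numpy(dtype=float),
        receptor_ids=df["receptor_id"].to_numpy(dtype=np.int64),
        censored=cens,
        M=len(df),
        T_max=float(times[cens].max()) if cens.any() else float(times.max()),
        seed=-1,
    )


def write_metadata(path, **fields) -> None:
    """Run-metadata JSON (seed, versions, parameters) for reproducibility."""
    import scipy

    from . import __version__

    meta = {
        "gradsense": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
    }
    meta.update(fields)
    Path(path).write_text(json.dumps(meta, indent=2, default=repr))
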