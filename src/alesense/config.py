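"""Run configuration files.

A single YAML document aggregates everything a run needs: the gas balance
parameters, the simulator's study conditions, and the analysis thresholds.
Every process constant appears exactly once; unspecified keys fall back to
the package defaults documented on :class:`~alesense.simulate.SimConfig` and
:class:`~alesense.pipeline.AnalysisConfig`.

Schema (all sections optional)::

    seed: 1
    gas:
      f_air_in: 69.0        # L/h
      v_reactor: 0.575      # L
      y_o2_in: 0.2091       # mole fraction
      y_co2_in: 0.0004
    simulate:
      mu_init: 0.30         # 1/h
      mu_stable: 0.61
      n_batches: 22
      ...
    analysis:
      r2_threshold: 0.98
      window_fraction: 0.5
      mu_reference: 0.61    # 1/h, for relative fitness
      ...
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .offgas import GasSpec
from .pipeline import AnalysisConfig
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: simulator + analysis + seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim.seed != self.seed:
            object.__setattr__(self, "sim",
                               dataclasses.replace(self.sim, seed=self.seed))


def _filter_fields(cls, mapping: dict, context: str) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return mapping


def load_config(path: str | Path | None = None, *,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; missing keys use package defaults."""
    doc: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        doc = raw
    if overrides:
        doc = {**doc, **overrides}

    gas = GasSpec(**_filter_fields(GasSpec, doc.get("gas", {}) or {}, "gas"))
    seed = int(doc.get("seed", 0))

    sim_kwargs = dict(doc.get("simulate", {}) or {})
    sim_kwargs.pop("gas", None)
    sim_kwargs.pop("seed", None)
    sim = SimConfig(gas=gas, seed=seed,
                    **_filter_fields(SimConfig, sim_kwargs, "simulate"))

    ana_kwargs = dict(doc.get("analysis", {}) or {})
    ana_kwargs.pop("gas", None)
    analysis = AnalysisConfig(gas=gas,
                              **_filter_fields(AnalysisConfig, ana_kwargs, "analysis"))

    extra = set(doc) - {"gas", "simulate", "analysis", "seed"}
    if extra:
        raise ValueError(f"unknown top-level config keys: {sorted(extra)}")
    return RunConfig(sim=sim, analysis=analysis, seed=seed)


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Write a configuration as YAML (fully explicit, stable key order)."""
    path = Path(path)
    sim = dataclasses.asdict(config.sim)
    sim.pop("gas")
    sim.pop("seed")
    ana = dataclasses.asdict(config.analysis)
    ana.pop("gas")
    doc = {
        "seed": config.seed,
        "gas": dataclasses.asdict(config.sim.gas),
        "simulate": sim,
        "analysis": ana,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path
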