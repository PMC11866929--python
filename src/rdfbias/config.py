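"""Run configuration: a single YAML file, validated strictly.

Unknown keys are rejected outright — a typo in a schedule key silently
falling back to a default is the classic way to burn a week of runs.  A
serialised copy of the parsed configuration is written next to the
outputs of every run so any artifact can be re-analysed exactly.

Layout (all blocks optional except ``engine``)::

    seed: 1
    log_level: INFO
    output_dir: out
    engine:
      n_particles: 500
      density: 0.8
      dt: 0.002
      temperature: 1.0
      thermostat_damping: 0.5
      pressure: null          # set to enable the Berendsen barostat
      barostat_tau: 2.0
      n_steps: 10000
      species: X
      lj:
        X-X: {epsilon: 1.0, sigma: 1.0, cutoff: 2.5, shift: true}
    bias:
      target_file: target.rdf
      gamma: 5.0
      sample_every: 10
      window: 100
      equilibrate: 0
      kappa_mode: none
      kappa_factor: 1.0
      n_updates: 300
      grid: {delta: 0.05, b: 80, r_lo: 0.0}
    weighting:
      mode: identical         # identical | frequency | xray
      factors: {O: 8.0, H: 1.0}
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .controller import BiasSchedule
from .engine import EngineConfig, LJParams
from .grid import RDFGrid
from .weighting import (SpeciesWeighting, frequency_pair_weights,
                        xray_pair_weights)

__all__ = ["RunConfig", "load_config"]

_ENGINE_KEYS = {"n_particles", "density", "dt", "temperature",
                "thermostat_damping", "pressure", "barostat_tau", "n_steps",
                "seed", "species", "lj"}
_BIAS_KEYS = {"target_file", "gamma", "sample_every", "window", "equilibrate",
              "kappa_mode", "kappa_factor", "grid", "n_updates"}
_GRID_KEYS = {"delta", "b", "r_lo"}
_WEIGHT_KEYS = {"mode", "factors"}
_TOP_KEYS = {"seed", "log_level", "output_dir", "engine", "bias", "weighting"}
_LJ_KEYS = {"epsilon", "sigma", "cutoff", "shift"}


class ConfigError(ValueError):
    pass


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    """Validated run configuration."""

    engine: EngineConfig
    n_particles: int = 500
    density: float = 0.8
    species: str = "X"
    schedule: BiasSchedule | None = None
    target_file: str | None = None
    grid: RDFGrid | None = None
    weighting: SpeciesWeighting = field(default_factory=SpeciesWeighting.identical)
    n_updates: int = 300
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "out"
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        """Stable hash of the raw configuration for provenance logging."""
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def write_copy(self, directory) -> Path:
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "config_used.yaml"
        path.write_text(yaml.safe_dump(self.raw, sort_keys=True))
        return path


def _parse_lj(block: dict) -> dict[tuple[str, str], LJParams]:
    params = {}
    for pair_key, sub in block.items():
        parts = tuple(sorted(str(pair_key).split("-")))
        if len(parts) != 2:
            raise ConfigError(f"LJ pair key {pair_key!r} must look like 'A-B'")
        _reject_unknown(sub, _LJ_KEYS, f"engine.lj.{pair_key}")
        params[parts] = LJParams(**sub)
    return params


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    if "engine" not in raw:
        raise ConfigError(f"{path}: missing required 'engine' block")
    eng = dict(raw["engine"])
    _reject_unknown(eng, _ENGINE_KEYS, "engine")
    seed = int(raw.get("seed", eng.get("seed", 0)))
    n_particles = int(eng.pop("n_particles", 500))
    density = float(eng.pop("density", 0.8))
    species = str(eng.pop("species", "X"))
    lj_block = eng.pop("lj", None)
    lj_params = _parse_lj(lj_block) if lj_block else {
        (species, species): LJParams()
    }
    eng.pop("seed", None)
    engine = EngineConfig(lj_params=lj_params, seed=seed, **eng)

    schedule = None
    target_file = None
    grid = None
    n_updates = 300
    if "bias" in raw:
        bias = dict(raw["bias"])
        _reject_unknown(bias, _BIAS_KEYS, "bias")
        target_file = bias.get("target_file")
        n_updates = int(bias.get("n_updates", 300))
        if "grid" in bias:
            g = dict(bias["grid"])
            _reject_unknown(g, _GRID_KEYS, "bias.grid")
            grid = RDFGrid(n_bins=int(g["b"]), delta=float(g["delta"]),
                           r_lo=float(g.get("r_lo", 0.0)))
        schedule = BiasSchedule(
            sample_every=int(bias.get("sample_every", 10)),
            window=int(bias.get("window", 100)),
            equilibrate=int(bias.get("equilibrate", 0)),
            gamma=float(bias.get("gamma", 5.0)),
            kappa_mode=str(bias.get("kappa_mode", "none")),
            kappa_factor=float(bias.get("kappa_factor", 1.0)),
        )

    weighting = SpeciesWeighting.identical()
    if "weighting" in raw:
        wb = dict(raw["weighting"])
        _reject_unknown(wb, _WEIGHT_KEYS, "weighting")
        mode = wb.get("mode", "identical")
        if mode != "identical":
            factors = {str(k): float(v) for k, v in (wb.get("factors") or {}).items()}
            # concentrations are taken from the configured composition;
            # single-species configs fall back to the implicit species
            conc = {species: 1.0}
            if mode == "frequency":
                weighting = frequency_pair_weights(conc)
            elif mode == "xray":
                weighting = xray_pair_weights(conc, factors or None)
            else:
                raise ConfigError(f"unknown weighting mode {mode!r}")

    return RunConfig(
        engine=engine,
        n_particles=n_particles,
        density=density,
        species=species,
        schedule=schedule,
        target_file=target_file,
        grid=grid,
        weighting=weighting,
        n_updates=n_updates,
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        output_dir=str(raw.get("output_dir", "out")),
        raw=raw,
    )
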