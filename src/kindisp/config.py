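"""Configuration loading, result serialization and run manifests.

Config files are YAML with a versioned schema; unknown keys are rejected
by name so typos fail loudly.  Every results CSV is written alongside a
JSON manifest holding the resolved settings and seeds needed to reproduce
it byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .analytics import Demography, SocialEffects
from .errors import ConfigError
from .simulator import SimConfig

__all__ = [
    "SCHEMA_VERSION",
    "CONFIG_DEFAULTS",
    "load_config",
    "resolve_config",
    "dump_config",
    "write_results",
    "RunManifest",
]

SCHEMA_VERSION = 1

#: flat key -> (default, coercion); n and c are required.
CONFIG_DEFAULTS: dict[str, tuple[Any, type]] = {
    "schema_version": (SCHEMA_VERSION, int),
    "n": (None, int),
    "c": (None, float),
    "k": (10, int),
    "benefit": (0.1, float),
    "cost": (0.05, float),
    "baseline": (0.5, float),
    "num_patches": (500, int),
    "generations": (5000, int),
    "burn_in": (2000, int),
    "mutation_prob": (0.01, float),
    "mutation_sd": (0.02, float),
    "P_lo": (0.5, float),
    "P_hi": (1.5, float),
    "seed": (0, int),
    "freeze_dispersal": (False, bool),
    "freeze_altruism": (False, bool),
    "init_altruism": (0.5, float),
    "init_norm": (0.5, float),
}


def resolve_config(raw: Mapping[str, Any]) -> SimConfig:
    """Fill defaults, validate, and build a SimConfig from a flat mapping."""
    unknown = sorted(set(raw) - set(CONFIG_DEFAULTS))
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    values: dict[str, Any] = {}
    for key, (default, typ) in CONFIG_DEFAULTS.items():
        if key in raw:
            try:
                values[key] = typ(raw[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"key '{key}': {exc}") from exc
        elif default is None:
            raise ConfigError(f"missing required key '{key}'")
        else:
            values[key] = default
    if values["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {values['schema_version']} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    try:
        demog = Demography(n=values["n"], c=values["c"], k=values["k"])
        effects = SocialEffects(
            benefit=values["benefit"],
            cost=values["cost"],
            baseline=values["baseline"],
        )
        return SimConfig(
            demog=demog,
            effects=effects,
            num_patches=values["num_patches"],
            generations=values["generations"],
            burn_in=values["burn_in"],
            mutation_prob=values["mutation_prob"],
            mutation_sd=values["mutation_sd"],
            P_lo=values["P_lo"],
            P_hi=values["P_hi"],
            seed=values["seed"],
            freeze_dispersal=values["freeze_dispersal"],
            freeze_altruism=values["freeze_altruism"],
            init_altruism=values["init_altruism"],
            init_norm=values["init_norm"],
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> SimConfig:
    """Parse a YAML config file into a validated SimConfig."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return resolve_config(raw)


def dump_config(config: SimConfig) -> dict[str, Any]:
    """Flatten a SimConfig back to the on-disk key set (round-trips)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "n": config.demog.n,
        "c": config.demog.c,
        "k": config.demog.k,
        "benefit": config.effects.benefit,
        "cost": config.effects.cost,
        "baseline": config.effects.baseline,
        "num_patches": config.num_patches,
        "generations": config.generations,
        "burn_in": config.burn_in,
        "mutation_prob": config.mutation_prob,
        "mutation_sd": config.mutation_sd,
        "P_lo": config.P_lo,
        "P_hi": config.P_hi,
        "seed": config.seed,
        "freeze_dispersal": config.freeze_dispersal,
        "freeze_altruism": config.freeze_altruism,
        "init_altruism": config.init_altruism,
        "init_norm": config.init_norm,
    }


def _format(value: Any) -> str:
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.12g}"
    return str(value)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility sidecar written next to every results CSV."""

    command: str
    master_seed: int
    settings: dict[str, Any]
    cell_seeds: dict[str, int] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return self

    def write(self, csv_path: str | Path) -> Path:
        path = Path(csv_path).with_suffix(".manifest.json")
        path.write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
            + "\n"
        )
        return path


def write_results(
    records: Sequence[Any],
    path: str | Path,
    fields: Sequence[str] | None = None,
    manifest: RunManifest | None = None,
) -> Path:
    """Write homogeneous dataclass records to CSV (12 significant digits).

    An empty record list yields a header-only file (``fields`` required in
    that case).  When a manifest is given it is finalized and written next
    to the CSV.
    """
    path = Path(path)
    if fields is None:
        if not records:
            raise ConfigError(
                "cannot infer a header from an empty record list"
            )
        fields = [f.name for f in dataclasses.fields(records[0])]
    lines = [",".join(fields)]
    for rec in records:
        lines.append(
            ",".join(_format(getattr(rec, f)) for f in fields)
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise ConfigError(f"cannot write {path}: {exc}") from exc
    if manifest is not None:
        manifest.finish().write(path)
    return path
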