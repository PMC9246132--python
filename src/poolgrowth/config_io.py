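"""Config schema, validation, deterministic seeding and output writing.

A run is described by a flat YAML/JSON mapping with three blocks: the
experiment name, the model parameters, and execution/output settings.
Validation is strict — unknown keys are rejected before any computation —
and every run emits a manifest (config echo, package version, seed, wall
time, output digests) so that stochastic outputs are reproducible
byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .core import FeedbackParams, PoolConfig, PoolMode

__all__ = ["RunConfig", "RunManifest", "load_config", "write_outputs",
           "derive_seed", "ConfigError"]

EXPERIMENTS = {"simulate", "distribution", "fixed_points", "scaling",
               "state_diagram", "residence", "flagella", "centrosome",
               "nucleus", "llps_map", "coexistence"}

_MODEL_KEYS = {"alpha", "beta", "k_plus", "k_minus", "kappa", "N_total", "V",
               "M", "mode", "rho", "alpha2", "beta2", "kappa2"}
_EXEC_KEYS = {"t_max", "max_events", "seed", "burn_in", "record_dt",
              "production", "growth", "init_sizes"}
_OUTPUT_KEYS = {"out_dir", "formats"}
_ORGANELLE_KEYS = {"spec"}


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


@dataclass
class RunConfig:
    experiment: str
    model: dict = field(default_factory=dict)
    execution: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def feedback_params(self, suffix: str = "") -> FeedbackParams:
        m = self.model
        if f"kappa{suffix}" in m and f"k_plus{suffix}" not in m:
            return FeedbackParams.from_kappa(
                float(m.get(f"alpha{suffix}", m.get("alpha", 0.0))),
                float(m.get(f"beta{suffix}", m.get("beta", 0.0))),
                float(m[f"kappa{suffix}"]))
        return FeedbackParams(
            alpha=float(m.get(f"alpha{suffix}", m.get("alpha", 0.0))),
            beta=float(m.get(f"beta{suffix}", m.get("beta", 0.0))),
            k_plus=float(m.get(f"k_plus{suffix}", m.get("k_plus", 1.0))),
            k_minus=float(m.get(f"k_minus{suffix}", m.get("k_minus", 1.0))))

    def pool_config(self) -> PoolConfig:
        m = self.model
        return PoolConfig(N_total=int(m.get("N_total", 0)),
                          V=float(m.get("V", 1.0)), M=int(m.get("M", 1)),
                          mode=PoolMode(m.get("mode", "limiting_pool")),
                          rho=float(m.get("rho", 0.0)))


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int | None
    started: str
    finished: str
    digests: dict

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _validate_block(name: str, block: dict, allowed: set) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{name}' block: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Defaults are filled for omitted keys; schema violations list the
    offending keys.  A negative beta is accepted with a warning: positive
    feedback from size-dependent disassembly has no known biophysical
    realization, though the regime is mathematically well-defined.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - {"experiment", "model", "execution", "output"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    exp = raw.get("experiment")
    if exp not in EXPERIMENTS:
        raise ConfigError(f"experiment must be one of {sorted(EXPERIMENTS)}; "
                          f"got {exp!r}")
    model = dict(raw.get("model") or {})
    organelle = exp in {"flagella", "centrosome", "nucleus", "llps_map"}
    _validate_block("model", model,
                    _MODEL_KEYS | (_ORGANELLE_KEYS if organelle else set()))
    execution = dict(raw.get("execution") or {})
    _validate_block("execution", execution, _EXEC_KEYS)
    output = dict(raw.get("output") or {})
    _validate_block("output", output, _OUTPUT_KEYS)
    mode = model.get("mode", "limiting_pool")
    if mode == "constant_concentration" and "rho" not in model:
        raise ConfigError("constant_concentration mode requires 'rho'")
    for key in ("beta", "beta2"):
        if float(model.get(key, 0.0)) < 0:
            warnings.warn(
                "beta < 0 gives positive feedback from size-dependent "
                "disassembly, a regime with no known biophysical realization",
                stacklevel=2)
    cfg = RunConfig(experiment=exp, model=model, execution=execution,
                    output=output)
    cfg.pool_config()                       # validates model numbers
    if not organelle:
        cfg.feedback_params()
    return cfg


def derive_seed(seed: int, stream: int) -> int:
    """Counter-based substream derivation: independent seeds per channel/run.

    Hashing (seed, stream) keeps unrelated draws stable when optional
    channels or extra runs are added; results stay below 2**31.
    """
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(results: dict, cfg: RunConfig, out_dir) -> RunManifest:
    """Write result files and a manifest with their digests.

    ``results`` maps file names to writers: a pandas DataFrame (written as
    TSV/CSV by extension), a JSON-serializable mapping, or a callable taking
    the target path.  The output directory is checked writable before any
    file is produced.
    """
    out = Path(out_dir)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_test"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise ConfigError(f"output directory {out} is not writable: {e}")
    digests = {}
    for name, obj in results.items():
        path = out / name
        if callable(obj):
            obj(path)
        elif hasattr(obj, "to_csv"):
            sep = "\t" if path.suffix == ".tsv" else ","
            obj.to_csv(path, sep=sep, index=False)
        else:
            path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                       default=_jsonable))
        digests[name] = _digest(path)
    manifest = RunManifest(
        config={"experiment": cfg.experiment, "model": cfg.model,
                "execution": cfg.execution, "output": cfg.output},
        version=__version__, seed=cfg.execution.get("seed"),
        started=started,
        finished=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        digests=digests)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
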