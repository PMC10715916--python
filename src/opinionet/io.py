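"""Configuration loading, result writers and run manifests.

Configs are YAML or JSON mappings of :class:`SimulationConfig` fields; a
``scenario`` key expands to the named (alpha_in, alpha_out) pair.  Unknown
keys and out-of-range values are rejected with the offending field named.

Every CLI invocation writes one output directory containing a
``manifest.json`` (config echo, code version, seeds, timestamps, file
inventory with SHA-256 digests) from which the run can be reproduced
bit-identically on the same platform.  Trajectory floats are written with 17
significant digits so round-tripped values compare exactly.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .dynamics import SimulationConfig, SimulationResult
from .experiments import SCENARIOS, EnsembleSummary

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "config_from_mapping",
    "RunManifest",
    "write_manifest",
    "write_trajectory_csv",
    "write_summary_csv",
    "write_ensemble_json",
    "write_results_csv",
]

_FLOAT_FMT = "%.17g"


class ConfigError(ValueError):
    """Invalid or unknown simulation configuration."""


def config_from_mapping(data: dict | None) -> SimulationConfig:
    """Build a validated config from a plain mapping.

    Omitted fields take the standard defaults; a ``scenario`` key sets the
    alpha pair and may not be combined with explicit alpha values.
    """
    data = dict(data or {})
    scenario = data.pop("scenario", None)
    if scenario is not None:
        if "alpha_in" in data or "alpha_out" in data:
            raise ConfigError(
                "give either 'scenario' or explicit alpha_in/alpha_out, not both"
            )
        if str(scenario) not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
            )
        sc = SCENARIOS[str(scenario)]
        data["alpha_in"] = sc.alpha_in
        data["alpha_out"] = sc.alpha_out
    try:
        return SimulationConfig(**data)
    except Exception as exc:  # pydantic ValidationError names the field
        raise ConfigError(str(exc)) from exc


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML/JSON config file (empty file → defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_mapping(data)


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True)
    )


@dataclass
class RunManifest:
    """Reproducibility record for one output directory."""

    command: str
    config: dict
    seed: int
    code_version: str
    created_utc: str
    outputs: dict[str, dict] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir,
    command: str,
    config: SimulationConfig,
    seed: int,
    extra: dict | None = None,
) -> Path:
    """Write manifest.json inventorying every file already in ``outdir``."""
    from . import __version__

    outdir = Path(outdir)
    manifest = RunManifest(
        command=command,
        config=config.model_dump(),
        seed=seed,
        code_version=__version__,
        created_utc=datetime.now(timezone.utc).isoformat(),
        extra=extra or {},
    )
    for f in sorted(outdir.iterdir()):
        if f.name == "manifest.json" or not f.is_file():
            continue
        manifest.outputs[f.name] = {
            "bytes": f.stat().st_size,
            "sha256": _sha256(f),
        }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True))
    return path


def write_trajectory_csv(result: SimulationResult, path) -> None:
    """Long-format per-agent mean opinions: (step, agent_id, mean_opinion)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "agent_id", "mean_opinion"])
        for row, t in enumerate(result.record_steps):
            for i in range(result.mean_trajectory.shape[1]):
                w.writerow(
                    [int(t), i, _FLOAT_FMT % result.mean_trajectory[row, i]]
                )


def write_summary_csv(result: SimulationResult, path) -> None:
    """Per-step disagreement and consensus flag: (step, sigma, consensus_flag)."""
    cons = result.consensus_step
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "sigma", "consensus_flag"])
        for t, s in enumerate(result.sigma):
            flag = int(cons is not None and t >= cons)
            w.writerow([t, _FLOAT_FMT % s, flag])


def write_ensemble_json(summary: EnsembleSummary, path) -> None:
    """Per-run consensus times plus the ensemble consensus frequency."""
    payload = {
        "reps": summary.reps,
        "base_seed": summary.base_seed,
        "t_max": summary.config.t_max,
        "consensus_count": summary.consensus_count,
        "consensus_frequency": summary.consensus_frequency,
        "consensus_times": summary.consensus_times,
        "config": summary.config.model_dump(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_results_csv(table, path) -> None:
    """Tidy sweep/ensemble results table as CSV."""
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
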