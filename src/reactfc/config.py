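"""YAML run configuration: one file drives simulation and analysis.

Two sections, ``synth`` and ``analysis``, whose keys map onto
:class:`~reactfc.synth.SynthConfig` and
:class:`~reactfc.pipeline.AnalysisOptions`; the ``analysis.hrf`` subsection
maps onto :class:`~reactfc.hrf.HrfParams`. Unknown keys are rejected by
name before any computation starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .hrf import HrfParams
from .pipeline import AnalysisOptions
from .synth import SynthConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    synth: SynthConfig
    analysis: AnalysisOptions


def _build(cls, mapping: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] configuration: {exc}") from exc


def run_config_from_dict(raw: dict | None) -> RunConfig:
    raw = dict(raw or {})
    unknown = set(raw) - {"synth", "analysis"}
    if unknown:
        raise ConfigError(f"unknown top-level config section(s): {sorted(unknown)}")
    synth_raw = dict(raw.get("synth") or {})
    if "shape" in synth_raw:
        synth_raw["shape"] = tuple(synth_raw["shape"])
    analysis_raw = dict(raw.get("analysis") or {})
    hrf_raw = analysis_raw.pop("hrf", None)
    analysis = _build(AnalysisOptions, analysis_raw, "analysis")
    if hrf_raw:
        analysis.hrf = _build(HrfParams, dict(hrf_raw), "analysis.hrf")
    return RunConfig(synth=_build(SynthConfig, synth_raw, "synth"), analysis=analysis)


def load_run_config(path: str | None) -> RunConfig:
    """Load a YAML run config; a missing path yields all defaults."""
    if path is None:
        return run_config_from_dict({})
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return run_config_from_dict(raw)


def dump_run_config(config: RunConfig, path) -> None:
    """Write the resolved configuration next to the outputs it produced."""
    raw = {
        "synth": dataclasses.asdict(config.synth),
        "analysis": dataclasses.asdict(config.analysis),
    }
    raw["synth"]["shape"] = list(raw["synth"]["shape"])
    raw["synth"]["frame_blocks"] = [list(b) for b in raw["synth"]["frame_blocks"]]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
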