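"""Pipeline configuration: one YAML file with per-module sections,
validated with aggregated error reporting and hashed for provenance.

Every REDItools-derived threshold appears under its interpreted name
(e.g. ``min_rna_coverage`` for ``-c 10``); unknown keys are rejected to
guard against silent typos in threshold names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from editkit.detect import DetectConfig
from editkit.mirna import ScanConfig
from editkit.pileup import IngestConfig
from editkit.simulate import SimConfig

KNOWN_INPUT_KEYS = {
    "genome", "gtf", "pileups", "dna_pileup", "sams", "snp_vcfs", "snp_beds",
    "mirna_fasta", "stage_map", "gmt", "edges", "expression",
}


class ConfigError(ValueError):
    """Aggregated configuration problems; ``errors`` lists every one."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class PipelineConfig:
    outdir: str = "editkit_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    ingest: IngestConfig = field(default_factory=IngestConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    mirna: ScanConfig = field(default_factory=ScanConfig)
    annotation_flank: int = 5000
    context_width: int = 10
    alpha: float = 0.05
    min_stage_support: int = 1
    inputs: dict = field(default_factory=dict)

    def semantic_dict(self) -> dict:
        """Everything that affects results (log level and output path
        excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        d.pop("log_level")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_SECTIONS = {"sim": SimConfig, "ingest": IngestConfig, "detect": DetectConfig,
             "mirna": ScanConfig}
_TOP_FIELDS = {f.name for f in fields(PipelineConfig)}

# explicit bound checks with readable messages
_BOUNDS = {
    ("detect", "min_level"): (0.0, 1.0, "min_level must be in [0,1]"),
    ("detect", "max_level"): (0.0, 1.0, "max_level must be in [0,1]"),
    ("sim", "error_rate"): (0.0, 0.05, "error_rate must be in [0, 0.05]"),
    (None, "alpha"): (0.0, 1.0, "alpha must be in [0,1]"),
}


def _coerce(name: str, value, expected_type, errors: list[str], prefix: str = ""):
    label = f"{prefix}{name}"
    if expected_type is bool:
        if not isinstance(value, bool):
            errors.append(f"{label} must be a boolean")
            return None
        return value
    if expected_type is int:
        if isinstance(value, bool) or not isinstance(value, int):
            errors.append(f"{label} must be an integer")
            return None
        return value
    if expected_type is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            errors.append(f"{label} must be a number")
            return None
        return float(value)
    return value


def config_from_dict(data: dict) -> PipelineConfig:
    """Build and fully validate a :class:`PipelineConfig` from a mapping;
    raises :class:`ConfigError` listing *every* problem found."""
    errors: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError(["configuration must be a mapping"])
    cfg = PipelineConfig()

    for key in data:
        if key not in _TOP_FIELDS:
            errors.append(f"unknown key {key!r}")

    for f in fields(PipelineConfig):
        if f.name not in data or f.name in _SECTIONS or f.name == "inputs":
            continue
        val = _coerce(f.name, data[f.name], type(getattr(cfg, f.name)), errors)
        if val is not None:
            setattr(cfg, f.name, val)

    for section, klass in _SECTIONS.items():
        sub = data.get(section)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        obj = getattr(cfg, section)
        known = {sf.name for sf in fields(klass)}
        for key, value in sub.items():
            if key not in known:
                errors.append(f"unknown key {section}.{key!r}")
                continue
            cur = getattr(obj, key)
            expected = type(cur) if cur is not None else type(value)
            val = _coerce(key, value, expected, errors, prefix=f"{section}.")
            if val is not None:
                setattr(obj, key, val)

    inputs = data.get("inputs", {})
    if not isinstance(inputs, dict):
        errors.append("inputs must be a mapping")
    else:
        for key in inputs:
            if key not in KNOWN_INPUT_KEYS:
                errors.append(f"unknown key inputs.{key!r}")
        cfg.inputs = dict(inputs)

    for (section, name), (lo, hi, msg) in _BOUNDS.items():
        obj = getattr(cfg, section) if section else cfg
        v = getattr(obj, name)
        if not (lo <= v <= hi):
            errors.append(msg)
    if cfg.detect.min_level > cfg.detect.max_level:
        errors.append("min_level must not exceed max_level")

    # keep the simulator tied to the global seed unless explicitly set
    if "sim" not in data or "seed" not in (data.get("sim") or {}):
        cfg.sim.seed = cfg.seed

    for validator in (cfg.sim.validate, cfg.ingest.validate, cfg.detect.validate):
        try:
            validator()
        except ValueError as exc:
            errors.append(str(exc))

    if not cfg.simulate:
        for required in ("genome", "gtf", "pileups", "stage_map"):
            if required not in cfg.inputs:
                errors.append(f"inputs.{required} is required when simulate is false")

    if errors:
        raise ConfigError(errors)
    return cfg


def validate_config(path: str) -> PipelineConfig:
    """Load + validate a YAML pipeline configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = config_from_dict(data)
    # referenced files must exist at validation time
    import os

    missing = []
    for key, value in cfg.inputs.items():
        paths = (
            list(value.values()) if isinstance(value, dict)
            else value if isinstance(value, list) else [value]
        )
        for p in paths:
            if isinstance(p, str) and key != "stage_map" and not os.path.exists(p):
                missing.append(f"inputs.{key}: file not found: {p}")
    if missing:
        raise ConfigError(missing)
    return cfg
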