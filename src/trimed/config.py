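"""Configuration loading, validation and normalization (YAML)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from trimed.errors import ConfigError
from trimed.simulate import SimulationConfig


@dataclass
class AnalysisConfig:
    """Thresholds and switches for the analysis stages.

    Defaults follow standard genome-wide practice: p < 5e-8 instrument screen,
    LD clumping at r^2 > 0.01 within 10,000 kb, multiplicative random-effects
    IVW, Steiger then MR-PRESSO sensitivity filtering, a 0.05 concordance
    gate with no multiple-testing correction (Bonferroni available but off).
    """

    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0
    alpha: float = 0.05
    bonferroni: bool = False
    palindromic_eaf_window: float = 0.08
    ivw_model: str = "multiplicative_random"
    steiger: bool = True
    presso: bool = True
    presso_n_sim: int = 1000
    presso_alpha_outlier: float = 0.05
    suppress_weak: bool = False
    mc_draws: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ConfigError("p_threshold must be in (0, 1]")
        if not (0 <= self.r2_threshold <= 1):
            raise ConfigError("r2_threshold must be in [0, 1]")
        if self.window_kb <= 0:
            raise ConfigError("window_kb must be positive")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.ivw_model not in ("fixed", "multiplicative_random"):
            raise ConfigError(f"unknown ivw_model {self.ivw_model!r}")
        if self.presso_n_sim < 100:
            raise ConfigError("presso_n_sim must be at least 100")


@dataclass
class PipelineConfig:
    """Top-level configuration: the synthetic world plus analysis settings."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _build_section(cls, data: dict, section: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown keys in {section!r} section: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        # YAML 1.1 reads scientific notation without a dot ("5e-8") as a
        # string; coerce strings for numeric fields
        if isinstance(value, str) and known[key].type in ("float", "int"):
            try:
                value = float(value) if known[key].type == "float" else int(value)
            except ValueError as exc:
                raise ConfigError(f"{section}.{key}: not a number: {value!r}") from exc
        coerced[key] = value
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigError(f"invalid {section} configuration: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Schema: optional top-level mappings ``simulation`` and ``analysis`` whose
    keys mirror :class:`SimulationConfig` / :class:`AnalysisConfig` fields;
    omitted keys take their defaults, unknown keys are rejected with a
    field-level message.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - {"simulation", "analysis"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    sim = _build_section(SimulationConfig, raw.get("simulation") or {}, "simulation")
    ana = _build_section(AnalysisConfig, raw.get("analysis") or {}, "analysis")
    return PipelineConfig(simulation=sim, analysis=ana)


def normalize(config: PipelineConfig) -> dict:
    """Fully-expanded plain-dict form (defaults filled, tuples as lists)."""

    def _clean(obj):
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        return obj

    return {
        "simulation": _clean(dataclasses.asdict(config.simulation)),
        "analysis": _clean(dataclasses.asdict(config.analysis)),
    }


def write_config(config: PipelineConfig, path) -> None:
    """Serialize a normalized configuration; write(load(x)) == normalize(x)."""
    with open(path, "w") as fh:
        yaml.safe_dump(normalize(config), fh, sort_keys=True)
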