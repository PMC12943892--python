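"""Validated run configuration (YAML) for the end-to-end pipeline.

Pydantic models with ``extra="forbid"`` give strict schema checking; unknown
keys are rejected with a nearest-valid-key suggestion, and all errors are
aggregated into one human-readable report.
"""

from __future__ import annotations

import difflib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(Exception):
    """Aggregated configuration validation failure."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("\n".join(errors))


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StftBlock(_Block):
    sample_rate: float = 200.0
    window_ms: float = 64.0
    overlap_fraction: float = Field(0.5, ge=0.0, lt=1.0)
    window_shape: str = "sqrt_hann"


class McraBlock(_Block):
    alpha_s: float = Field(0.8, gt=0.0, lt=1.0)
    delta_ratio: float = Field(2.0, gt=1.0)
    alpha_p: float = Field(0.2, gt=0.0, lt=1.0)
    alpha_floor: float = Field(0.85, ge=0.0, lt=1.0)
    vmin_frames: int = Field(64, ge=1)
    pooling: str = "trace"


class GevdBlock(_Block):
    alpha_y: float = Field(0.95, ge=0.0, lt=1.0)
    subspace_policy: str = "eigenvalue-threshold"
    threshold_eps: float = Field(0.05, gt=0.0)
    fixed_count: int = Field(1, ge=1)


class GainBlock(_Block):
    mu_min: float = 1.0
    mu_max: float = 1201.0
    snr_high_db: float = 20.0
    snr_low_db: float = -5.0


class BandsBlock(_Block):
    edges: dict[str, tuple[float, float]] = {
        "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 14.0),
        "beta": (14.0, 31.0), "gamma": (31.0, 50.0),
    }


class FeaturesBlock(_Block):
    window_s: float = Field(1.0, gt=0.0)
    lds_ratio: float = Field(0.1, gt=0.0)
    pad_to_T: int | None = None


class BackboneBlock(_Block):
    filter_sizes: tuple[int, int, int] = (64, 128, 256)
    kernel_width: int = 5
    graph_heads: int = Field(4, ge=1)
    top_k: int = Field(10, ge=1)
    graph_dim: int = Field(32, ge=1)
    leaky_slope: float = Field(0.01, gt=0.0)


class AttentionBlock(_Block):
    dropout_rate: float = Field(0.1, ge=0.0, lt=1.0)
    label_smoothing: float = Field(0.1, ge=0.0, lt=1.0)


class TrainBlock(_Block):
    learning_rate: float = Field(0.001, gt=0.0)
    batch_size: int = Field(64, ge=1)
    epochs: int = Field(200, ge=1)
    n_classes: int = Field(3, ge=2)


class EvalBlock(_Block):
    protocol: str = "loso"


class SimulateBlock(_Block):
    n_channels: int = Field(62, ge=1)
    duration_s: float = Field(60.0, gt=0.0)
    target_snr_db: float = 0.0
    spike_rate: float = Field(0.5, ge=0.0)
    n_subjects: int = Field(9, ge=2)
    trials_per_subject: int = Field(6, ge=1)
    effect_size: float = 1.0
    subject_sigma: float = Field(0.3, ge=0.0)
    noise_sigma: float = Field(0.3, ge=0.0)


class IoBlock(_Block):
    workdir: str = "eegfuse_run"


class RunConfig(_Block):
    seed: int = 0
    stages: list[str] = ["simulate", "denoise", "features", "train", "evaluate"]
    io: IoBlock = IoBlock()
    stft: StftBlock = StftBlock()
    mcra: McraBlock = McraBlock()
    gevd: GevdBlock = GevdBlock()
    gain: GainBlock = GainBlock()
    bands: BandsBlock = BandsBlock()
    features: FeaturesBlock = FeaturesBlock()
    backbone: BackboneBlock = BackboneBlock()
    attention: AttentionBlock = AttentionBlock()
    train: TrainBlock = TrainBlock()
    eval: EvalBlock = EvalBlock()
    simulate: SimulateBlock = SimulateBlock()


_VALID_STAGES = ("simulate", "denoise", "features", "train", "evaluate")


def _suggest(bad_key: str, valid: list[str]) -> str:
    close = difflib.get_close_matches(bad_key, valid, n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def _friendly_errors(exc: ValidationError, model: type[BaseModel]) -> list[str]:
    msgs = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        if err["type"] == "extra_forbidden":
            parts = err["loc"]
            parent: type[BaseModel] | None = model
            for p in parts[:-1]:
                if parent is None:
                    break
                field = parent.model_fields.get(str(p))
                ann = field.annotation if field else None
                parent = ann if isinstance(ann, type) and issubclass(
                    ann, BaseModel) else None
            valid = list(parent.model_fields) if parent else []
            msgs.append(f"unknown key {loc!r}{_suggest(str(parts[-1]), valid)}")
        else:
            msgs.append(f"{loc}: {err['msg']}")
    return msgs


def validate_config(data: dict) -> RunConfig:
    """Validate a nested config dict; raise ConfigError with all problems."""
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_friendly_errors(exc, RunConfig)) from exc
    bad = [s for s in cfg.stages if s not in _VALID_STAGES]
    if bad:
        raise ConfigError(
            [f"unknown stage {s!r}{_suggest(s, list(_VALID_STAGES))}"
             for s in bad])
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"malformed YAML: {exc}"]) from exc
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])
    return validate_config(data)
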