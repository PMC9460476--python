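"""Run configuration: nested YAML sections mirroring the pipeline stages.

Every default equals the study's stated value where one exists: 300 ms
forward window, 1500 ms stride cap, 20 hidden nodes, Adam at 0.001, 100
epochs, 10% validation split, entropy coefficient 0.6/ln(5), retraining
every 2 trials, 50% day-1 initial split.  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as PydanticValidationError

from .errors import ConfigurationError


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_days: int = Field(default=4, ge=1)
    trials_per_day: int = Field(default=40, ge=1)
    days: list[int] = [1, 2, 3, 7]
    separation: float = Field(default=3.2, gt=0)
    shift_magnitudes: list[float] = [0.0, 2.5, 2.8, 3.0]
    cov_scales: list[float] = [1.0, 0.9, 0.85, 0.85]
    subject: str = "synthetic"


class SignalsSection(_Section):
    sampling_rate: float = Field(default=1000.0, gt=0)
    highpass_cutoff: float = Field(default=20.0, gt=0)
    highpass_order: int = Field(default=2, ge=1)
    forward_window_ms: float = Field(default=300.0, gt=0)
    backward_max_ms: float = Field(default=1500.0, gt=0)


class FeaturesSection(_Section):
    ar_order: int = Field(default=4, ge=1)
    deadband: float = Field(default=0.0, ge=0)


class ModelsSection(_Section):
    hidden: int = Field(default=20, ge=1)
    learning_rate: float = Field(default=1e-3, gt=0)
    max_epochs: int = Field(default=100, ge=1)
    patience: int = Field(default=3, ge=1)
    validation_fraction: float = Field(default=0.10, gt=0, lt=1)
    batch_size: int = Field(default=8, ge=1)


class AdaptSection(_Section):
    retrain_interval: int = Field(default=2, ge=1)
    pool_cap: int | None = Field(default=None, ge=1)


class EvaluateSection(_Section):
    train_fraction: float = Field(default=0.5, gt=0, lt=1)
    random_split: bool = False


class RunConfig(_Section):
    """Fully-resolved configuration of one run."""

    seed: int = 0
    simulate: SimulateSection = SimulateSection()
    signals: SignalsSection = SignalsSection()
    features: FeaturesSection = FeaturesSection()
    models: ModelsSection = ModelsSection()
    adapt: AdaptSection = AdaptSection()
    evaluate: EvaluateSection = EvaluateSection()

    def net_config(self, seed: int | None = None):
        from .models import NetConfig

        return NetConfig(
            hidden=self.models.hidden,
            learning_rate=self.models.learning_rate,
            max_epochs=self.models.max_epochs,
            patience=self.models.patience,
            validation_fraction=self.models.validation_fraction,
            batch_size=self.models.batch_size,
            seed=self.seed if seed is None else seed,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; an empty/missing file gives all
    defaults.  Unknown keys, type mismatches and constraint violations raise
    :class:`ConfigurationError` with the offending location."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**data)
    except PydanticValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def write_resolved(config: RunConfig, out_dir: str | Path) -> Path:
    """Echo the fully-resolved config (plus package version) next to outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"driftadapt_version": __version__, **config.model_dump()}
    target = out / "resolved_config.yaml"
    target.write_text(yaml.safe_dump(payload, sort_keys=False))
    return target
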