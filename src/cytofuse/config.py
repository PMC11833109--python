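"""Configuration objects for simulation, training and the pipeline.

All configs are plain dataclasses validated eagerly on construction;
an invalid field raises :class:`~cytofuse.errors.ConfigurationError`
naming the offending field.  Configs round-trip through YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

SCENARIOS = ("gfp_production", "thermal_stress", "glucose_deprivation")

#: Scenario presets scale the class-conditional morphology gap.  Glucose
#: deprivation produces a larger morphological shift than thermal stress,
#: mirroring the much higher separability of glucose-deprived cells.
SCENARIO_MORPH_SCALE = {
    "gfp_production": 1.0,
    "thermal_stress": 0.6,
    "glucose_deprivation": 1.5,
}


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic 3D-IFC dataset generator.

    The 3D side-scatter (SSC) volume sections each cell into
    ``image_depth`` slices (10 by default, matching the instrument's
    light-sheet sectioning); the 2D transmission image is a single
    brightfield-like view.  ``effect_size`` controls how far the
    positive class's morphological parameters (scattering-center rate,
    center intensity, cell-radius proxy) are shifted; at 0 the two
    class-conditional distributions are identical by construction.
    """

    n_cells: int = 200
    image_depth: int = 10
    image_height: int = 32
    image_width: int = 32
    trans_height: int = 32
    trans_width: int = 32
    scenario: str = "gfp_production"
    class_fraction: float = 0.5
    effect_size: float = 1.0
    noise_sd: float = 0.02
    cell_to_bead_ratio: float = 2.0
    bead_types: tuple[str, ...] = ("A", "T", "C")
    deletion_rate: float = 0.0
    displacement_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 0, "n_cells", "must be non-negative")
        _require(self.image_depth >= 1, "image_depth", "must be >= 1")
        for name in ("image_height", "image_width", "trans_height", "trans_width"):
            _require(getattr(self, name) >= 4, name, "must be >= 4 pixels")
        _require(self.scenario in SCENARIOS, "scenario",
                 f"must be one of {SCENARIOS}")
        _require(0.0 < self.class_fraction < 1.0, "class_fraction",
                 "must be strictly between 0 and 1")
        _require(self.effect_size >= 0.0, "effect_size", "must be non-negative")
        _require(self.noise_sd >= 0.0, "noise_sd", "must be non-negative")
        _require(self.cell_to_bead_ratio > 0.0, "cell_to_bead_ratio",
                 "must be positive")
        _require(len(self.bead_types) >= 2, "bead_types",
                 "needs at least 2 distinct bead labels")
        _require(len(set(self.bead_types)) == len(self.bead_types),
                 "bead_types", "labels must be distinct")
        _require(0.0 <= self.deletion_rate < 1.0, "deletion_rate",
                 "must be in [0, 1)")
        _require(0.0 <= self.displacement_rate < 1.0, "displacement_rate",
                 "must be in [0, 1)")
        # tuple-ify if a list came from YAML
        if not isinstance(self.bead_types, tuple):
            object.__setattr__(self, "bead_types", tuple(self.bead_types))


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite training objective.

    ``w1`` splits the reconstruction loss between the 2D and 3D
    modalities; ``w2`` splits the total loss between classification
    (cross-entropy) and reconstruction.  The 3D-only classifier has no
    2D input, so it is trained with ``w1 = 0``.
    """

    w1: float = 0.5
    w2: float = 0.5

    def __post_init__(self) -> None:
        _require(0.0 <= self.w1 <= 1.0, "w1", "must be in [0, 1]")
        _require(0.0 <= self.w2 <= 1.0, "w2", "must be in [0, 1]")


@dataclass(frozen=True)
class TrainingConfig:
    """Two-phase CAE training protocol.

    The first ``recon_only_epochs`` epochs minimize the reconstruction
    loss alone (the classification head is frozen); the remaining
    epochs minimize the weighted sum of cross-entropy and
    reconstruction losses.  Defaults follow the published protocol:
    150 epochs total with a 20-epoch reconstruction-only pre-phase,
    Adam, batch size 4.
    """

    total_epochs: int = 150
    recon_only_epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    latent_dim: int = 64
    conv_channels: tuple[int, ...] = (8, 16, 32)
    n_classes: int = 2

    def __post_init__(self) -> None:
        _require(self.total_epochs >= 1, "total_epochs", "must be >= 1")
        _require(0 <= self.recon_only_epochs <= self.total_epochs,
                 "recon_only_epochs", "must be in [0, total_epochs]")
        _require(self.batch_size >= 1, "batch_size", "must be >= 1")
        _require(self.learning_rate > 0, "learning_rate", "must be positive")
        _require(self.latent_dim >= 1, "latent_dim", "must be >= 1")
        _require(len(self.conv_channels) >= 1, "conv_channels",
                 "needs at least one level")
        _require(self.n_classes >= 2, "n_classes", "must be >= 2")
        if not isinstance(self.conv_channels, tuple):
            object.__setattr__(self, "conv_channels", tuple(self.conv_channels))
        if isinstance(self.loss_weights, dict):
            object.__setattr__(self, "loss_weights",
                               LossWeights(**self.loss_weights))


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline: simulate -> register -> gate -> train -> evaluate."""

    sim: SimConfig = field(default_factory=SimConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    gate_fraction: float = 0.10
    use_registration: bool = True
    cv_folds: int = 5
    seed: int = 0
    output_dir: str = "cytofuse_run"

    def __post_init__(self) -> None:
        _require(0.0 < self.gate_fraction < 1.0, "gate_fraction",
                 "must be in (0, 1)")
        _require(self.cv_folds >= 2, "cv_folds", "must be >= 2")
        if isinstance(self.sim, dict):
            object.__setattr__(self, "sim", SimConfig(**self.sim))
        if isinstance(self.training, dict):
            object.__setattr__(self, "training", TrainingConfig(**self.training))


def to_dict(cfg) -> dict:
    """Dataclass config -> plain JSON-serializable dict."""
    return dataclasses.asdict(cfg)


def config_hash(cfg) -> str:
    """Stable short hash of a config, for manifests."""
    payload = json.dumps(to_dict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path}: expected a mapping")
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(f"config file {path}: {exc}") from exc


def derive_seed(stage: str, seed: int) -> int:
    """Fan a global seed out to a stage-specific seed (< 2**31).

    Hash of stage name + global seed, so each stage is independently
    reproducible from the single pipeline seed.
    """
    digest = hashlib.sha256(f"{stage}:{seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
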