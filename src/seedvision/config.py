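"""Run configuration shared by the CLI stages.

A single YAML file holds every tunable of the pipeline; unset keys fall back
to the defaults below, unknown keys are rejected, and every value is checked
against its stage's precondition at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # segmentation
    threshold: str | int = "otsu"  # "otsu" or a fixed integer threshold
    morph_radius: int = 2
    min_area: int = 50
    # texture
    glcm_levels: int = 16
    glcm_distance: int = 1
    lsp_similarity_t: float = 10.0
    coarseness_kmax: int = 4
    # training
    learning_rate: float = 0.01
    mse_tolerance: float = 0.01
    max_epochs: int = 10_000
    # selection
    sffs_max_steps: int = 30
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.morph_radius >= 1, "morph_radius >= 1"),
            (self.min_area >= 1, "min_area >= 1"),
            (self.glcm_levels >= 2, "glcm_levels >= 2"),
            (self.glcm_distance >= 1, "glcm_distance >= 1"),
            (self.lsp_similarity_t >= 0, "lsp_similarity_t >= 0"),
            (self.coarseness_kmax >= 1, "coarseness_kmax >= 1"),
            (self.learning_rate > 0, "learning_rate > 0"),
            (self.mse_tolerance > 0, "mse_tolerance > 0"),
            (self.max_epochs >= 1, "max_epochs >= 1"),
            (self.sffs_max_steps >= 1, "sffs_max_steps >= 1"),
        ]
        for ok, constraint in checks:
            if not ok:
                raise ValueError(f"invalid config value: constraint {constraint!r} violated")
        if not (self.threshold == "otsu" or isinstance(self.threshold, int)):
            raise ValueError("invalid config value: threshold must be 'otsu' or an integer")

    def segment_kwargs(self) -> dict:
        if self.threshold == "otsu":
            thr = {"threshold_mode": "otsu"}
        else:
            thr = {"threshold_mode": "fixed", "fixed_t": float(self.threshold)}
        return {**thr, "morph_radius": self.morph_radius, "min_area": self.min_area}

    def feature_kwargs(self) -> dict:
        return {
            "glcm_levels": self.glcm_levels,
            "glcm_distance": self.glcm_distance,
            "lsp_similarity_t": self.lsp_similarity_t,
            "coarseness_kmax": self.coarseness_kmax,
        }

    def train_config(self, seed: int | None = None):
        from seedvision.bpnn import TrainConfig

        return TrainConfig(
            learning_rate=self.learning_rate,
            mse_tolerance=self.mse_tolerance,
            max_epochs=self.max_epochs,
            rng_seed=self.seed if seed is None else seed,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; defaults fill unset keys, unknown keys are errors."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    valid = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"unknown config key(s) {unknown}; valid keys: {sorted(valid)}")
    cfg = RunConfig(**raw)
    logger.info("effective config:\n%s", cfg.to_yaml())
    return cfg
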