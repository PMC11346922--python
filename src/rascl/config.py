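"""Experiment configuration: YAML schema, validation and per-stage views.

A single YAML file drives the whole pipeline.  Validation is a pre-flight
check run before any stage executes: every required block must be present
and no unknown keys are accepted, so a typo fails loudly with the offending
keys listed instead of silently using a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augmentation import AugmentationConfig
from .contrastive import ContrastiveConfig
from .exceptions import ConfigurationError
from .models import EncoderSpec, HeadSpec
from .phantoms import CohortConfig
from .training import FinetuneConfig, PretrainConfig

# block -> allowed keys (None marks a nested mapping validated separately)
_SCHEMA: dict[str, set[str]] = {
    "phantoms": {
        "n_ftmh", "n_erm", "n_challenge", "image_height", "image_width",
        "n_slices", "slice_spacing_um", "speckle_sigma", "slice_drift",
        "two_eye_prob",
    },
    "augmentation": {
        "noise_mu_range", "noise_var_range", "crop_area_range",
        "brightness_delta_range", "contrast_factor_range", "hflip_prob",
        "output_size", "interpolation",
    },
    "contrastive": {
        "max_offset", "temperature", "batch_pairs", "embedding_dim",
        "boundary_mode",
    },
    "encoder": {"architecture", "feature_dim", "initial_weights", "pool_grid"},
    "head": {"hidden_layers", "hidden_width"},
    "training": {"pretrain", "finetune", "baseline"},
    "splitting": {"n_replicates", "test_counts", "k_folds", "n_restarts", "n_swaps"},
    "evaluation": {"threshold", "bit_depth"},
}
_PRETRAIN_KEYS = {"epochs", "val_interval", "learning_rate", "slices_per_eye"}
_FINETUNE_KEYS = {
    "epochs", "val_interval", "learning_rate", "encoder_mode", "slices_per_eye",
    "augment", "n_aug_variants", "threshold", "class_weight",
}
_TOP_KEYS = set(_SCHEMA) | {"seed", "output_root"}


@dataclass
class ExperimentConfig:
    """Validated experiment settings with typed per-stage views."""

    raw: dict
    seed: int
    output_root: Path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "ExperimentConfig":
        if not isinstance(raw, dict):
            raise ConfigurationError("experiment config must be a mapping")
        problems = []
        unknown_top = sorted(set(raw) - _TOP_KEYS)
        if unknown_top:
            problems.append(f"unknown top-level keys: {unknown_top}")
        for block, allowed in _SCHEMA.items():
            if block not in raw:
                problems.append(f"missing block: {block}")
                continue
            sub = raw[block] or {}
            if not isinstance(sub, dict):
                problems.append(f"block {block} must be a mapping")
                continue
            unknown = sorted(set(sub) - allowed)
            if unknown:
                problems.append(f"block {block}: unknown keys {unknown}")
        if "training" in raw and isinstance(raw["training"], dict):
            for sub_name, keys in (("pretrain", _PRETRAIN_KEYS), ("finetune", _FINETUNE_KEYS)):
                sub = raw["training"].get(sub_name, {}) or {}
                unknown = sorted(set(sub) - keys)
                if unknown:
                    problems.append(f"training.{sub_name}: unknown keys {unknown}")
        if problems:
            raise ConfigurationError("config pre-flight failed: " + "; ".join(problems))
        seed = int(raw.get("seed", 0))
        root = Path(raw.get("output_root", "runs/experiment"))
        if base_dir is not None and not root.is_absolute():
            root = base_dir / root
        cfg = cls(raw=raw, seed=seed, output_root=root)
        # construct every view once so invalid values fail pre-flight too
        cfg.cohort_config().validate()
        cfg.augmentation_config().validate()
        cfg.contrastive_config().validate()
        cfg.encoder_spec().validate()
        cfg.head_spec(mode="projection").validate()
        cfg.pretrain_config().validate()
        cfg.finetune_config().validate()
        return cfg

    # -- typed views --------------------------------------------------------
    def cohort_config(self) -> CohortConfig:
        p = dict(self.raw["phantoms"])
        p.pop("n_challenge", None)
        if "slice_spacing_um" in p:
            v = p["slice_spacing_um"]
            p["slice_spacing_um"] = tuple(v) if isinstance(v, (list, tuple)) else (float(v),)
        return CohortConfig(**p)

    @property
    def n_challenge(self) -> int:
        return int(self.raw["phantoms"].get("n_challenge", 34))

    def augmentation_config(self) -> AugmentationConfig:
        a = dict(self.raw["augmentation"])
        for key in (
            "noise_mu_range", "noise_var_range", "crop_area_range",
            "brightness_delta_range", "contrast_factor_range", "output_size",
        ):
            if key in a:
                a[key] = tuple(a[key])
        return AugmentationConfig(**a)

    def contrastive_config(self) -> ContrastiveConfig:
        return ContrastiveConfig(**self.raw["contrastive"])

    def encoder_spec(self) -> EncoderSpec:
        e = dict(self.raw["encoder"])
        out = self.augmentation_config().output_size
        return EncoderSpec(input_size=(out[0], out[1], 1), **e)

    def head_spec(self, mode: str) -> HeadSpec:
        return HeadSpec(mode=mode, **self.raw["head"])

    def pretrain_config(self) -> PretrainConfig:
        return PretrainConfig(**(self.raw["training"].get("pretrain") or {}))

    def finetune_config(self) -> FinetuneConfig:
        f = dict(self.raw["training"].get("finetune") or {})
        f.setdefault("threshold", self.threshold)
        return FinetuneConfig(**f)

    @property
    def run_baseline(self) -> bool:
        return bool(self.raw["training"].get("baseline", True))

    @property
    def threshold(self) -> float:
        return float(self.raw["evaluation"].get("threshold", 0.5))

    @property
    def bit_depth(self) -> int:
        return int(self.raw["evaluation"].get("bit_depth", 8))

    def splitting(self) -> dict:
        s = dict(self.raw["splitting"])
        s.setdefault("n_replicates", 3)
        s.setdefault("test_counts", {"FTMH": 10, "ERM": 40})
        s.setdefault("k_folds", 8)
        s.setdefault("n_restarts", 50)
        s.setdefault("n_swaps", 500)
        return s
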