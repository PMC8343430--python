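"""Single-file YAML configuration for the pipeline.

The file has one section per stage (``synthetic``, ``selection``,
``anchors``, ``detector``, ``segmenter``, ``postprocess``, ``evaluation``)
plus a global ``seed``, ``out_dir`` and ``log_level``.  Unknown keys are
rejected so typos fail loudly, naming the section and field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "snap_out",
    "log_level": "INFO",
    "synthetic": {
        "n_scenes": 30,
        "height": 192,
        "width": 256,
        "nodule_count_mean": 12.0,
        "nodule_count_dispersion": 4.0,
        "taproot_zone_fraction": 0.5,
        "n_laterals": 4,
        "n_distractors": 1,
        "noise_sd": 6.0,
    },
    "selection": {
        "k": None,               # default: 20% of the dataset
        "downsample_height": 64,
        "downsample_width": 64,
        "latent_channels": 4,
        "pca_components": 16,
        "variance_target": None,
        "train_epochs": 15,
    },
    "anchors": {
        "method": "percentile",  # default | percentile | de
        "n_scales": 3,
        "n_ratios": 3,
        "base_sizes": [16.0],
        "strides": [8],
        "de_generations": 40,
        "de_population": 20,
    },
    "detector": {
        "arch": "tiny",
        "iterations": 300,
        "batch_size": 4,
        "learning_rate": 1.0e-3,
        "input_scale": 256,
        "score_threshold": 0.3,
        "nms_iou": 0.5,
    },
    "segmenter": {
        "base_width": 8,
        "iterations": 150,
        "batch_size": 4,
        "learning_rate": 1.0e-3,
        "threshold": 0.5,
    },
    "postprocess": {
        "r_dilate": 6.0,
        "scale_with_width": False,
        "masks": "predicted",    # predicted | ground_truth
    },
    "evaluation": {
        "iou_threshold": 0.5,
    },
}


@dataclass
class PipelineConfig:
    values: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULTS)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        cfg = cls()
        cfg._merge(user)
        return cfg

    def _merge(self, user: dict) -> None:
        for key, val in user.items():
            if key not in self.values:
                raise ValueError(f"unknown configuration section or field: {key!r}")
            if isinstance(self.values[key], dict):
                if not isinstance(val, dict):
                    raise ValueError(f"section {key!r} must be a mapping")
                for k2, v2 in val.items():
                    if k2 not in self.values[key]:
                        raise ValueError(f"unknown field {k2!r} in section {key!r}")
                    self.values[key][k2] = v2
            else:
                self.values[key] = val

    def __getitem__(self, key):
        return self.values[key]

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)

    @property
    def out_dir(self) -> Path:
        return Path(self.values["out_dir"])

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.values, sort_keys=True).encode()).hexdigest()[:16]
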