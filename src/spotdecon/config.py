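"""Run configuration: nested YAML blocks, validation, and seed fan-out.

One global seed is fanned out to per-module seeds through a splitmix64
derivation keyed by the module name, so each module stays independently
reproducible no matter how the others consume randomness.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["derive_seed", "RunConfig", "DEFAULT_CONFIG"]

_GOLDEN = 0x9E3779B97F4A7C15
_MASK = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + _GOLDEN) & _MASK
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK
    return x ^ (x >> 31)


def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic per-module seed below 2**31."""
    h = global_seed & _MASK
    for ch in label:
        h = _splitmix64(h ^ ord(ch))
    return h % (2 ** 31)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "runs",
    "simulator": {
        "n_cells": 2000, "n_genes": 200, "n_types": 4, "marker_fold": 8.0,
        "base_rate": 1.0, "n_spots": 500, "mu_cells": 10.0, "sigma_cells": 3.0,
        "mu_types": 3.0, "sigma_types": 1.0, "downsample_fraction": 1.0,
        "real_downsample_fraction": 0.1,
        "slide_rows": 16, "slide_cols": 16, "spacing_px": 60.0,
        "n_regions": 4, "image_margin_px": 80, "dominant_weight": 0.7,
    },
    "graph": {"k": 5, "hidden": 512},
    "sfe": {"scales": [150, 100, 50], "out_size": 224, "backend": "stub",
            "n_tokens": 16, "dim": 64, "heads": 4},
    "model": {"d_f": 256, "d_s": 128, "hidden": 512, "pos_dim": 64,
              "d_k": 64, "grl_coeff": 1.0},
    "training": {"learning_rate": 1e-3, "epochs": 300, "batch_size": 400,
                 "lambda1": 0.1, "lambda2": 0.1, "lambda3": 0.01,
                 "k_folds": 10, "n_top_genes": 3000},
    "metrics": {"target": "proportions"},
}


class RunConfig:
    """Validated nested configuration; unknown keys are rejected."""

    def __init__(self, overrides: dict | None = None):
        self.data = copy.deepcopy(DEFAULT_CONFIG)
        if overrides:
            self._merge(self.data, overrides, path="")

    @staticmethod
    def _merge(base: dict, over: dict, path: str) -> None:
        for key, val in over.items():
            if key not in base:
                raise KeyError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict):
                if not isinstance(val, dict):
                    raise TypeError(f"config block {path + key!r} must be a map")
                RunConfig._merge(base[key], val, path + key + ".")
            else:
                base[key] = val

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        return cls(yaml.safe_load(text) or {})

    def __getitem__(self, key: str):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def module_seed(self, module: str) -> int:
        return derive_seed(self.seed, module)

    def snapshot(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=False))
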