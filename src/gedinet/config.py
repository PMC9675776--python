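"""Run configuration with YAML loading.

Nested YAML keys (cv.iterations, forest.n_trees, ...) map onto the flat fields
below; unknown keys are an error so typos surface early.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml


@dataclass
class GediNetConfig:
    # association filter
    disease_types: frozenset[str] = frozenset({"disease"})
    semantic_types: frozenset[str] = frozenset({"Neoplastic Process", "Disease"})
    # group catalog
    min_group_size: int = 2
    max_group_size: int | None = None
    # differential-expression prefilter
    prefilter_alpha: float = 0.05
    prefilter_max_genes: int = 2000
    # scoring
    scoring_method: str = "ml"  # "ml" or "analytic"
    scoring_r: int = 5
    scoring_train_frac: float = 0.9
    scoring_undersample: bool = True
    use_absolute_t: bool = True
    # shared forest settings
    n_trees: int = 100
    criterion: str = "entropy"
    # outer Monte Carlo cross-validation
    iterations: int = 100
    train_frac: float = 0.9
    undersample: bool = True
    # modeling
    max_j: int = 10
    # master seed for every source of randomness
    seed: int = 0

    _YAML_MAP = {
        ("filter", "disease_types"): "disease_types",
        ("filter", "semantic_types"): "semantic_types",
        ("groups", "min_size"): "min_group_size",
        ("groups", "max_size"): "max_group_size",
        ("prefilter", "alpha"): "prefilter_alpha",
        ("prefilter", "max_genes"): "prefilter_max_genes",
        ("scoring", "method"): "scoring_method",
        ("scoring", "r"): "scoring_r",
        ("scoring", "train_frac"): "scoring_train_frac",
        ("scoring", "undersample"): "scoring_undersample",
        ("scoring", "use_absolute_t"): "use_absolute_t",
        ("forest", "n_trees"): "n_trees",
        ("forest", "criterion"): "criterion",
        ("cv", "iterations"): "iterations",
        ("cv", "train_frac"): "train_frac",
        ("cv", "undersample"): "undersample",
        ("modeling", "max_j"): "max_j",
        (None, "seed"): "seed",
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "GediNetConfig":
        kwargs = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                for subkey, subvalue in value.items():
                    attr = cls._YAML_MAP.get((key, subkey))
                    if attr is None:
                        raise KeyError(f"unknown config key {key}.{subkey}")
                    kwargs[attr] = subvalue
            else:
                attr = cls._YAML_MAP.get((None, key))
                if attr is None:
                    raise KeyError(f"unknown config key {key}")
                kwargs[attr] = value
        for name in ("disease_types", "semantic_types"):
            if name in kwargs:
                kwargs[name] = frozenset(kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "GediNetConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)
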