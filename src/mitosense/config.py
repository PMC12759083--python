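"""Run configuration: thresholds, mode flags and seeds.

Every threshold defaults to the published value where one exists (screen
category cuts -1 / -1.25 / +1, image threshold 80/255, mt-Keima spillover
0.10, proteomics |log2FC| cut 1.0).  Seeds are mandatory for stochastic
operations -- there is no silent default randomness in the CLI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from mitosense.errors import ConfigurationError

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # screen scoring
    bonferroni_mode: str = "standard"  # or "as_printed"
    aggregation: str = "best_guide_pair"  # or "mean"
    activator_lfc: float = -1.0
    activator_diff: float = -1.25
    facilitator_lfc: float = 1.0
    facilitator_diff: float = 1.0
    regulator_lfc: float = 1.0
    # flow statistics
    keima_spillover: float = 0.10
    bfp_cutoff: float = 1.0
    pink1_cutoff: float = 100.0
    mmp_cutoff: float = 0.5  # fold of the guide-negative reference level
    population_statistic: str = "mean"  # or "median"
    # image quantification
    image_threshold_lo: int = 80
    image_threshold_hi: int = 255
    coloc_n_rand: int = 20
    coloc_block_size: int = 5
    coloc_method: str = "block"  # or "pixel"
    # proteomics
    prot_lfc_cut: float = 1.0  # 0.5 for the whole-lysate LFQ experiments
    prot_equal_var: bool = True

    def __post_init__(self) -> None:
        if self.bonferroni_mode not in ("standard", "as_printed"):
            raise ConfigurationError(f"unknown bonferroni_mode {self.bonferroni_mode!r}")
        if self.aggregation not in ("best_guide_pair", "mean"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        if self.coloc_method not in ("block", "pixel"):
            raise ConfigurationError(f"unknown coloc_method {self.coloc_method!r}")
        if self.population_statistic not in ("mean", "median"):
            raise ConfigurationError(
                f"unknown population_statistic {self.population_statistic!r}"
            )
        if not 0.0 <= self.keima_spillover < 1.0:
            raise ConfigurationError("keima_spillover must be in [0, 1)")
        if not 0 <= self.image_threshold_lo <= self.image_threshold_hi <= 255:
            raise ConfigurationError("image threshold must satisfy 0 <= lo <= hi <= 255")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load a YAML config, filling defaults and rejecting unknown keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown config keys: {', '.join(sorted(unknown))}"
        )
    coerced = {}
    for key, value in raw.items():
        expected = _FIELD_TYPES[key]
        try:
            if expected == "int":
                if isinstance(value, bool) or not isinstance(value, int):
                    raise TypeError
                coerced[key] = int(value)
            elif expected == "float":
                if isinstance(value, bool) or not isinstance(value, (int, float)):
                    raise TypeError
                coerced[key] = float(value)
            elif expected == "bool":
                if not isinstance(value, bool):
                    raise TypeError
                coerced[key] = value
            else:
                if not isinstance(value, str):
                    raise TypeError
                coerced[key] = value
        except TypeError:
            raise ConfigurationError(
                f"{path}: key {key!r} expects {expected}, got {type(value).__name__}"
            ) from None
    return RunConfig(**coerced)
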