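"""Pipeline configuration: YAML in, validated dataclass out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one input source must be set: ``feature_table`` (a prebuilt
    subjects-by-parameters file; imaging stages are skipped), ``subjects``
    (per-subject acquired series + ROI mask files), or ``synthetic``
    (a generated cohort; the default).
    """

    seed: int = 0
    feature_table: str | None = None
    column_map: dict = field(default_factory=dict)
    subjects: list | None = None  # [{subject_id, group, age_years, sex,
    #   severity, series: {kind: path}, mask: path}, ...]
    synthetic: dict | None = None
    fit: dict = field(default_factory=dict)        # {fix_m0: bool}
    svm: dict = field(default_factory=dict)        # SVMConfig overrides
    univariate_parameters: tuple = ("MTR", "km", "T2", "T1", "ADC")
    min_combination_size: int = 2

    # synthetic defaults; grid kept modest so a full cohort run stays fast
    _SYNTHETIC_DEFAULTS = {
        "n_per_group": [9, 9],
        "grid_shape": [32, 64],
        "noise_sigma": 0.02,
        "follicle": False,
        "skip_imaging": False,
    }

    def __post_init__(self) -> None:
        sources = [s is not None
                   for s in (self.feature_table, self.subjects, self.synthetic)]
        if sum(sources) == 0:
            self.synthetic = {}
        elif sum(sources) > 1:
            raise ValueError(
                "config must set exactly one input source: feature_table, "
                "subjects, or synthetic")
        if self.synthetic is not None:
            merged = dict(self._SYNTHETIC_DEFAULTS)
            merged.update(self.synthetic)
            self.synthetic = merged
        if self.seed is None:
            raise ValueError("a seed is required (stochastic stages)")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)
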