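"""Synthetic two-group cohorts of per-subject ground-truth MR parameters.

The default cohort mirrors the study design: nine control and nine OI
subjects, with the demographics (ages, sexes, OI types and severities)
taken from the published patient-characteristics table. Per-subject
parameters are drawn from per-group normal distributions truncated at
zero; the default OI effect follows the murine osteogenesis-imperfecta
result that motivated the study — km 50% lower and T2 30% greater than
control — with the other three parameters unchanged between groups.

Group means for the human cohort are not published as numbers, so the
control means here are realistic ex-vivo dermis values, not a calibration
to the study's plots. The published per-group T2 standard deviations
(control 3.46 ms, OI 1.86 ms) are used for the T2 dispersions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "draw_cohort", "FEATURE_COLUMNS", "PARAM_COLUMNS"]

log = logging.getLogger(__name__)

#: canonical feature-table columns (file and in-memory layout)
FEATURE_COLUMNS = [
    "subject_id", "group", "age_years", "sex", "severity",
    "MTR", "km_per_s", "T2_ms", "T1_s", "ADC_mm2_per_s",
]

#: map from short parameter names to feature-table columns
PARAM_COLUMNS = {
    "MTR": "MTR",
    "km": "km_per_s",
    "T2": "T2_ms",
    "T1": "T1_s",
    "ADC": "ADC_mm2_per_s",
}

# published patient characteristics: (severity, age, sex) per OI subject
# and (age, sex) per control subject
_OI_DEMOGRAPHICS = [
    ("mild", 37, "M"), ("mild", 40, "M"),
    ("severe", 21, "M"), ("severe", 23, "F"),
    ("moderate", 25, "M"), ("moderate", 45, "M"), ("moderate", 17, "F"),
    ("moderate", 9, "M"), ("moderate", 3, "F"),
]
_CONTROL_DEMOGRAPHICS = [
    (3, "M"), (5, "M"), (8, "M"), (30, "F"), (33, "M"),
    (33, "M"), (46, "F"), (53, "M"), (55, "F"),
]

_CONTROL_MEANS = {"MTR": 0.55, "km": 2.0, "T2": 30.0, "T1": 1.2, "ADC": 1.0e-3}
_CONTROL_SDS = {"MTR": 0.05, "km": 0.35, "T2": 3.46, "T1": 0.12, "ADC": 1.2e-4}
# OI effect: km halved, T2 30% greater; other parameters unchanged
_OI_MEANS = {"MTR": 0.55, "km": 1.0, "T2": 39.0, "T1": 1.2, "ADC": 1.0e-3}
_OI_SDS = {"MTR": 0.05, "km": 0.25, "T2": 1.86, "T1": 0.12, "ADC": 1.2e-4}


@dataclass
class CohortSpec:
    """Per-group parameter distributions and subject demographics."""

    n_per_group: tuple = (9, 9)  # (control, OI)
    control_means: dict = field(default_factory=lambda: dict(_CONTROL_MEANS))
    control_sds: dict = field(default_factory=lambda: dict(_CONTROL_SDS))
    oi_means: dict = field(default_factory=lambda: dict(_OI_MEANS))
    oi_sds: dict = field(default_factory=lambda: dict(_OI_SDS))
    seed: int | None = None

    def __post_init__(self) -> None:
        for n in self.n_per_group:
            if n < 2:
                raise ValueError(
                    "need >= 2 subjects per group (leave-one-out requires "
                    "at least one training member per class)")
        for sds in (self.control_sds, self.oi_sds):
            if any(s < 0 for s in sds.values()):
                raise ValueError("SDs must be non-negative")


def _truncated_normal(rng, mean, sd, size):
    """Normal draws redrawn until positive (parameters are physical)."""
    if sd == 0:
        return np.full(size, float(mean))
    x = rng.normal(mean, sd, size=size)
    bad = x <= 0
    n_redraw = 0
    while np.any(bad):
        n_redraw += int(bad.sum())
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = x <= 0
    if n_redraw:
        log.info("truncated-normal draw: %d redraws at zero", n_redraw)
    return x


def draw_cohort(spec: CohortSpec, seed=None) -> pd.DataFrame:
    """Draw one synthetic cohort as a feature table.

    Returns a DataFrame with :data:`FEATURE_COLUMNS`: one row per subject,
    group labels ``control``/``OI``, demographics recycled from the study
    design when the group size is nine, and the five MR parameters drawn
    from the group distributions (truncated at zero). Reproducible under a
    fixed seed.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed

    rows = []
    for group, n, means, sds in (
        ("control", spec.n_per_group[0], spec.control_means, spec.control_sds),
        ("OI", spec.n_per_group[1], spec.oi_means, spec.oi_sds),
    ):
        draws = {p: _truncated_normal(rng, means[p], sds[p], n)
                 for p in PARAM_COLUMNS}
        for i in range(n):
            if group == "OI":
                sev, age, sex = _OI_DEMOGRAPHICS[i % len(_OI_DEMOGRAPHICS)]
            else:
                age, sex = _CONTROL_DEMOGRAPHICS[i % len(_CONTROL_DEMOGRAPHICS)]
                sev = "NA"
            rows.append({
                "subject_id": f"{group}_{i + 1:02d}",
                "group": group,
                "age_years": float(age),
                "sex": sex,
                "severity": sev,
                "MTR": draws["MTR"][i],
                "km_per_s": draws["km"][i],
                "T2_ms": draws["T2"][i],
                "T1_s": draws["T1"][i],
                "ADC_mm2_per_s": draws["ADC"][i],
            })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
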