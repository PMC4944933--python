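"""Dermal ROI propagation and reduction of parameter maps to features.

The dermis ROI (drawn on the T2 map in the original workflow, or taken
from the phantom label map here) is copied unchanged to every other
parameter map of the same sample; each map is then reduced to the
arithmetic mean over in-ROI pixels, excluding pixels whose fit did not
converge. The per-subject means of the five parameters form the feature
table used for classification and group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FEATURE_COLUMNS, PARAM_COLUMNS
from .fitting import ParameterMap

__all__ = ["ROIMask", "propagate_roi", "roi_mean", "build_feature_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROIMask:
    """Boolean mask on the image grid labeling one compartment."""

    mask: np.ndarray
    label: str = "dermis"
    source: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError(f"ROI mask {self.label!r} is empty")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple:
        return self.mask.shape


def propagate_roi(mask: ROIMask, maps: list) -> list:
    """Bind one ROI mask to each map, verifying grid alignment.

    Returns ``[(mask, map), ...]``; a shape mismatch raises so that a
    mask drawn on one grid is never silently applied to another.
    """
    bound = []
    for pmap in maps:
        if pmap.shape != mask.shape:
            raise ValueError(
                f"ROI grid {mask.shape} does not match map {pmap.name!r} "
                f"grid {pmap.shape}")
        bound.append((mask, pmap))
    return bound


def roi_mean(pmap: ParameterMap, mask: ROIMask) -> float:
    """Arithmetic mean of a map over in-mask converged pixels.

    Non-converged pixels are excluded, not imputed; if more than 10% of
    the in-mask pixels are excluded a warning is logged. Raises if no
    converged pixel remains.
    """
    if pmap.shape != mask.shape:
        raise ValueError("mask and map grids differ")
    inroi = mask.mask
    ok = inroi & pmap.converged
    n_excl = int(inroi.sum() - ok.sum())
    if n_excl and n_excl > 0.10 * inroi.sum():
        log.warning("ROI %s on %s: %d/%d pixels excluded (non-converged)",
                    mask.label, pmap.name, n_excl, int(inroi.sum()))
    if not ok.any():
        raise ValueError(
            f"no converged pixels inside ROI {mask.label!r} for map "
            f"{pmap.name!r}")
    return float(pmap.values[ok].mean())


def build_feature_table(map_sets: dict, masks: dict, metadata: pd.DataFrame
                        ) -> pd.DataFrame:
    """Assemble the cohort feature table from per-subject map sets.

    Parameters
    ----------
    map_sets : dict
        ``subject_id -> {parameter name -> ParameterMap}``; all five of
        MTR, km, T2, T1, ADC must be present per subject.
    masks : dict
        ``subject_id -> ROIMask`` (the dermis ROI of that sample).
    metadata : DataFrame
        Indexed by subject_id with columns group, age_years, sex, severity.

    Returns
    -------
    DataFrame with :data:`~qmriskin.cohort.FEATURE_COLUMNS`, one row per
    subject, ordered by subject_id.
    """
    rows = []
    for sid in sorted(map_sets):
        maps = map_sets[sid]
        missing = [p for p in PARAM_COLUMNS if p not in maps]
        if missing:
            raise KeyError(
                f"subject {sid!r} is missing parameter map(s): "
                f"{', '.join(missing)}")
        if sid not in masks:
            raise KeyError(f"subject {sid!r} has no ROI mask")
        mask = masks[sid]
        propagate_roi(mask, [maps[p] for p in PARAM_COLUMNS])
        md = metadata.loc[sid]
        row = {
            "subject_id": sid,
            "group": md["group"],
            "age_years": float(md["age_years"]),
            "sex": md.get("sex", "NA"),
            "severity": md.get("severity", "NA"),
        }
        for param, col in PARAM_COLUMNS.items():
            row[col] = roi_mean(maps[param], mask)
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
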