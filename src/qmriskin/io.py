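"""Feature-table readers/writers and report emission.

The feature-table reader accepts CSV or XLSX with a config-driven column
map so that externally deposited tables (whose header names may differ)
can be adapted without code changes. Reports mirror the univariate and
multivariate classification tables: one CSV row per parameter or
combination with train/test sensitivity, specificity and accuracy, both
half-up-rounded to two decimals and at full precision, plus a JSON
per-fold audit trail.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import FEATURE_COLUMNS, PARAM_COLUMNS

__all__ = ["read_feature_table", "write_feature_table", "round_half_up",
           "write_reports"]

_MR_COLUMNS = list(PARAM_COLUMNS.values())
_VALID_GROUPS = {"control", "OI"}
_VALID_SEVERITIES = {"mild", "moderate", "severe", "NA"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.665 -> 0.67), as printed reports do."""
    x = float(x)
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def read_feature_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a subjects-by-parameters feature table.

    Parameters
    ----------
    path : str or Path
        CSV or XLSX file, one row per subject.
    column_map : dict, optional
        ``{file column -> canonical column}`` applied before validation;
        canonical columns are :data:`~qmriskin.cohort.FEATURE_COLUMNS`.
        Short parameter names (MTR, km, T2, T1, ADC) are also accepted as
        canonical targets.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    df = df.rename(columns=PARAM_COLUMNS)  # accept short parameter names

    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    # sex/severity are optional metadata; everything else is required
    hard = [c for c in missing if c not in ("sex", "severity")]
    if hard:
        raise ValueError(f"feature table missing column(s): {', '.join(hard)}")
    for c in missing:
        df[c] = "NA"
    # pandas parses the literal "NA" as missing; both mean "not applicable"
    for c in ("sex", "severity"):
        df[c] = df[c].fillna("NA").astype(str)

    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce").astype(float)
    for col in _MR_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "subject_id"].tolist()
            raise ValueError(
                f"non-numeric or missing {col!r} for subject(s): {bad}")
        df[col] = vals.astype(float)
    bad_groups = set(df["group"].unique()) - _VALID_GROUPS
    if bad_groups:
        raise ValueError(f"unknown group label(s): {sorted(bad_groups)}")
    bad_sev = set(df["severity"].astype(str)) - _VALID_SEVERITIES
    if bad_sev:
        raise ValueError(f"unknown severity label(s): {sorted(bad_sev)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id rows")
    return df[FEATURE_COLUMNS].reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".xlsx":
        table.to_excel(path, index=False)
    else:
        table.to_csv(path, index=False)
    return path


_METRIC_KEYS = ["train_sensitivity", "train_specificity", "train_accuracy",
                "test_sensitivity", "test_specificity", "test_accuracy"]


def _report_frame(metrics_list) -> pd.DataFrame:
    rows = []
    for m in metrics_list:
        row = m.as_row()
        out = {"parameters": row["parameters"]}
        for k in _METRIC_KEYS:
            out[k] = round_half_up(row[k], 2)
            out[k + "_full"] = row[k]
        rows.append(out)
    cols = (["parameters"] + _METRIC_KEYS
            + [k + "_full" for k in _METRIC_KEYS])
    return pd.DataFrame(rows, columns=cols)


def write_reports(results: dict, outdir) -> dict:
    """Write classification report CSVs and the per-fold audit JSON.

    ``results`` maps ``"univariate"`` and/or ``"multivariate"`` to lists of
    :class:`~qmriskin.classify.ClassificationMetrics`. Empty lists produce
    headered, empty CSVs. Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    audit = {}
    for key in ("univariate", "multivariate"):
        metrics_list = results.get(key, [])
        frame = _report_frame(metrics_list)
        p = outdir / f"{key}_classification.csv"
        frame.to_csv(p, index=False)
        paths[key] = p
        audit[key] = [
            {"parameters": list(m.parameters), "method": m.method,
             "folds": m.folds}
            for m in metrics_list
        ]
    audit_path = outdir / "fold_assignments.json"
    audit_path.write_text(json.dumps(audit, indent=1, default=float))
    paths["audit"] = audit_path
    return paths
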