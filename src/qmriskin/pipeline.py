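"""End-to-end driver: simulate (or load) -> fit -> ROI means -> classify.

The pipeline runs the same stages regardless of input source:

1. obtain a per-subject feature table — from a file, from acquired series
   fitted pixel-wise and reduced over the dermis ROI, or from a fully
   synthetic cohort imaged through phantom simulation;
2. univariate Mahalanobis leave-one-out classification per parameter;
3. RBF-SVM leave-one-out classification for every parameter combination;
4. group statistics (t-tests, age correlations, severity ANOVA);
5. report CSVs plus a JSON audit of per-fold assignments.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` so stages are independently reproducible.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .classify import (SVMConfig, enumerate_combinations, loo_univariate,
                       svm_loo)
from .cohort import PARAM_COLUMNS, CohortSpec, draw_cohort
from .config import PipelineConfig
from .fitting import fit_map, mtr_map
from .phantom import PhantomSpec, TissueParameters, make_phantom, simulate_series
from .protocols import PROTOCOL_KINDS, default_protocol
from .roi import ROIMask, build_feature_table, roi_mean
from .series import read_series, read_label_map
from .stats import anova_severity, pearson_age_corr, ttest_groups

__all__ = ["run_pipeline", "simulate_subject", "fit_subject"]

log = logging.getLogger(__name__)


def simulate_subject(row: pd.Series, grid_shape, noise_sigma, seed,
                     follicle=False):
    """Phantom + four noisy series for one cohort row.

    The subject's five drawn parameters become the dermis compartment;
    bath/epidermis (and optionally a follicle blob) keep their defaults.
    """
    dermis = TissueParameters(
        t1_s=row["T1_s"], t2_ms=row["T2_ms"], km_per_s=row["km_per_s"],
        adc_mm2_per_s=row["ADC_mm2_per_s"], a=1.0, c=0.0,
        mss_over_m0=1.0 - row["MTR"],
    )
    from .phantom import DEFAULT_COMPARTMENTS

    compartments = dict(DEFAULT_COMPARTMENTS)
    compartments["dermis"] = dermis
    follicle_spec = None
    if follicle:
        rows = grid_shape[0]
        d0, d1 = int(round(0.45 * rows)), rows  # default dermis extent
        r0 = (d0 + d1) // 2
        ar = max((d1 - d0) // 6, 1)
        follicle_spec = (r0, grid_shape[1] // 3, ar, 2 * ar)
    spec = PhantomSpec(grid_shape=tuple(grid_shape), noise_sigma=noise_sigma,
                       compartments=compartments, follicle=follicle_spec)
    label_map, names, truth = make_phantom(spec)
    rng = np.random.default_rng(seed)
    series = {kind: simulate_series(truth, default_protocol(kind),
                                    noise_sigma=noise_sigma, seed=rng)
              for kind in PROTOCOL_KINDS}
    dermis_mask = ROIMask(np.isin(label_map, [names.index("dermis")]),
                          label="dermis", source=str(row["subject_id"]))
    return series, dermis_mask, truth


def fit_subject(series: dict, mask: ROIMask, fix_m0: bool = False) -> dict:
    """Fit the five parameter maps of one subject inside its dermis ROI."""
    maps = {}
    for kind in ("cpmg", "satrec", "diffusion"):
        pm = fit_map(series[kind], mask=mask.mask)
        maps[{"cpmg": "T2", "satrec": "T1", "diffusion": "ADC"}[kind]] = pm
    mt_fit = fit_map(series["mt"], mask=mask.mask, fix_m0=fix_m0)
    maps["km"] = mt_fit
    maps["MTR"] = mtr_map(mt_fit=mt_fit)
    return maps


def _stats_block(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for p in PARAM_COLUMNS:
        r = ttest_groups(table, p, "group")
        rows.append({"test": "ttest_group", "parameter": p,
                     "statistic": r.statistic, "df": r.df, "p": r.p_value,
                     "effect": r.effect})
        if table["sex"].nunique() == 2:
            r = ttest_groups(table, p, "sex")
            rows.append({"test": "ttest_sex", "parameter": p,
                         "statistic": r.statistic, "df": r.df, "p": r.p_value,
                         "effect": r.effect})
        for g in ("control", "OI"):
            r = pearson_age_corr(table, p, g)
            rows.append({"test": f"pearson_age_{g}", "parameter": p,
                         "statistic": r.statistic, "df": r.df, "p": r.p_value,
                         "effect": r.effect})
        try:
            r = anova_severity(table, p)
            rows.append({"test": "anova_severity", "parameter": p,
                         "statistic": r.statistic, "df": r.df, "p": r.p_value,
                         "effect": r.effect})
        except ValueError:
            pass  # no severity strata in this table
    return pd.DataFrame(rows)


def _feature_table_from_subjects(cfg: PipelineConfig) -> pd.DataFrame:
    map_sets, masks, meta_rows = {}, {}, []
    for sub in cfg.subjects:
        sid = sub["subject_id"]
        series = {k: read_series(p) for k, p in sub["series"].items()}
        labels, names = read_label_map(sub["mask"])
        if names and "dermis" in names:
            m = labels == names.index("dermis")
        else:
            m = labels > 0
        mask = ROIMask(m, label="dermis", source=str(sub["mask"]))
        map_sets[sid] = fit_subject(series, mask,
                                    fix_m0=cfg.fit.get("fix_m0", False))
        masks[sid] = mask
        meta_rows.append({
            "subject_id": sid, "group": sub["group"],
            "age_years": sub.get("age_years", float("nan")),
            "sex": sub.get("sex", "NA"),
            "severity": sub.get("severity", "NA")})
    meta = pd.DataFrame(meta_rows).set_index("subject_id", drop=False)
    return build_feature_table(map_sets, masks, meta)


def _feature_table_synthetic(cfg: PipelineConfig):
    syn = cfg.synthetic
    ss = np.random.SeedSequence(cfg.seed)
    cohort_seed, *subject_seeds = ss.spawn(1 + 2 * syn["n_per_group"][0]
                                           + 2 * syn["n_per_group"][1])
    spec_kwargs = {k: syn[k] for k in
                   ("control_means", "control_sds", "oi_means", "oi_sds")
                   if k in syn}
    spec = CohortSpec(n_per_group=tuple(syn["n_per_group"]), **spec_kwargs)
    truth_table = draw_cohort(spec, seed=np.random.default_rng(cohort_seed))
    if syn["skip_imaging"]:
        return truth_table, truth_table.copy()

    map_sets, masks = {}, {}
    for i, (_, row) in enumerate(truth_table.iterrows()):
        t0 = time.perf_counter()
        series, mask, _ = simulate_subject(
            row, syn["grid_shape"], syn["noise_sigma"],
            seed=np.random.default_rng(subject_seeds[i]),
            follicle=syn["follicle"])
        map_sets[row["subject_id"]] = fit_subject(
            series, mask, fix_m0=cfg.fit.get("fix_m0", False))
        masks[row["subject_id"]] = mask
        log.info("subject %s imaged+fitted in %.1fs", row["subject_id"],
                 time.perf_counter() - t0)
    meta = truth_table.set_index("subject_id", drop=False)
    table = build_feature_table(map_sets, masks, meta)
    return truth_table, table


def run_pipeline(cfg: PipelineConfig, outdir=None) -> dict:
    """Execute the configured pipeline; optionally write all artifacts.

    Returns a dict with the feature table, classification metrics
    (univariate per parameter, multivariate per combination), the group
    statistics frame, and — for synthetic runs — the ground-truth cohort
    table.
    """
    truth_table = None
    if cfg.feature_table is not None:
        table = qio.read_feature_table(cfg.feature_table, cfg.column_map)
        stage = "feature_table"
    elif cfg.subjects is not None:
        table = _feature_table_from_subjects(cfg)
        stage = "subjects"
    else:
        truth_table, table = _feature_table_synthetic(cfg)
        stage = "synthetic"
    log.info("feature table ready (%s): %d subjects", stage, len(table))

    univariate = [loo_univariate(table, p) for p in cfg.univariate_parameters]
    svm_cfg = SVMConfig(**cfg.svm)
    combos = enumerate_combinations(tuple(PARAM_COLUMNS),
                                    cfg.min_combination_size)
    multivariate = [svm_loo(table, combo, svm_cfg) for combo in combos]
    stats_frame = _stats_block(table)

    results = {
        "table": table,
        "truth_table": truth_table,
        "univariate": univariate,
        "multivariate": multivariate,
        "stats": stats_frame,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qio.write_feature_table(table, outdir / "feature_table.csv")
        if truth_table is not None:
            qio.write_feature_table(truth_table, outdir / "cohort_truth.csv")
        qio.write_reports({"univariate": univariate,
                           "multivariate": multivariate}, outdir)
        stats_frame.to_csv(outdir / "group_stats.csv", index=False)
    return results
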