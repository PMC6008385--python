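"""End-to-end cohort analysis: time series -> report tables.

Chains the stages in study order: motion QC and denoising, Pearson
connectivity, sparsity-thresholded graph metrics with AUC reduction,
covariate-adjusted group statistics, the abnormal-connectivity composite,
and clinical correlations.  The same function drives the CLI, the test
suite's replicate studies, and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess as pp
from .connectivity import fc_matrix, ConnectivityMatrix
from .metrics import metric_curves, DEFAULT_GRID, NODAL_METRICS
from .stats import (compare_groups_metric, compare_edgewise, compare_nodal,
                    abnormal_fc_score, correlate_clinical)
from .synthetic import Cohort

__all__ = ["CohortAnalysis", "analyze_cohort"]

GLOBAL_AUC_METRICS = ("cp", "lp", "gamma", "lambda", "sigma", "eglob",
                      "eloc")


@dataclass
class CohortAnalysis:
    """All per-subject and group-level outputs of one cohort run."""

    records: pd.DataFrame                   # included subjects only
    qc: pd.DataFrame
    labels: list[str]
    grid: np.ndarray
    fc_stack: np.ndarray                    # n_subjects x N x N
    global_auc: pd.DataFrame                # subjects x global metrics
    nodal_auc: dict[str, pd.DataFrame]      # metric -> subjects x nodes
    largest_component: pd.DataFrame         # subjects x sparsity
    global_tests: pd.DataFrame
    edge_table: pd.DataFrame
    nodal_table: pd.DataFrame
    composite: pd.Series | None
    significant_edges: list[tuple[str, str]]
    correlations: pd.DataFrame

    def fc_of(self, subject_id: str) -> ConnectivityMatrix:
        i = list(self.records["subject_id"]).index(subject_id)
        return ConnectivityMatrix(self.fc_stack[i], self.labels)


def _clinical_correlations(analysis_vars: dict[str, np.ndarray],
                           mask: np.ndarray,
                           pairs: list[tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for xn, yn in pairs:
        x, y = analysis_vars.get(xn), analysis_vars.get(yn)
        if x is None or y is None:
            continue
        try:
            r, p, n = correlate_clinical(x[mask], y[mask])
        except ValueError:
            r, p, n = np.nan, np.nan, int(mask.sum())
        rows.append({"x": xn, "y": yn, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def analyze_cohort(cohort: Cohort, grid=None, *, n_random: int = 0,
                   swaps_per_edge: int = 100, seed: int = 0,
                   covariates: tuple[str, ...] = ("age", "bmi", "education"),
                   apply_qc: bool = True, apply_preprocess: bool = True,
                   include_betweenness: bool = True,
                   include_eloc: bool = True, rank: str = "signed",
                   alpha: float = 0.05) -> CohortAnalysis:
    """Run the full analysis on an in-memory cohort.

    ``n_random = 0`` (default) skips the degree-preserving null, leaving
    gamma/lambda/sigma AUCs as NaN; pass ``n_random >= 1`` to normalize
    against the rewired ensemble.  ``include_betweenness`` and
    ``include_eloc`` let replicate studies skip the two most expensive
    metrics when they are not under test.  Deterministic given ``seed``.
    """
    if grid is None:
        grid = DEFAULT_GRID
    labels = cohort.node_labels
    rec = cohort.records.copy()

    qc = pp.qc_report({sid: cohort.motion[sid] for sid in rec["subject_id"]})
    if apply_qc:
        included = set(qc.loc[qc["decision"] == "include", "subject_id"])
        rec = rec[rec["subject_id"].isin(included)].reset_index(drop=True)
    sids = list(rec["subject_id"])

    fc_stack = np.empty((len(sids), len(labels), len(labels)))
    for i, sid in enumerate(sids):
        ts = cohort.timeseries[sid]
        if apply_preprocess:
            ts = pp.denoise(ts, cohort.tr, motion=cohort.motion[sid],
                            nuisance=cohort.nuisance[sid])
        fc_stack[i] = fc_matrix(ts, labels).values

    seeds = np.random.SeedSequence(seed).spawn(len(sids))
    glob_rows, lcc_rows = [], []
    nodal_acc: dict[str, list[pd.Series]] = {m: [] for m in NODAL_METRICS}
    for i, sid in enumerate(sids):
        curves = metric_curves(
            ConnectivityMatrix(fc_stack[i], labels), grid,
            n_random=n_random, seed=seeds[i],
            swaps_per_edge=swaps_per_edge, rank=rank,
            include_betweenness=include_betweenness,
            include_eloc=include_eloc)
        g_auc = curves.global_auc()
        glob_rows.append(g_auc[list(GLOBAL_AUC_METRICS)])
        lcc_rows.append(curves.global_metrics["largest_component"])
        n_auc = curves.nodal_auc()
        for m in NODAL_METRICS:
            nodal_acc[m].append(n_auc[m])

    idx = pd.Index(sids, name="subject_id")
    global_auc = pd.DataFrame(glob_rows, index=idx)
    largest_component = pd.DataFrame(lcc_rows, index=idx)
    nodal_auc = {m: pd.DataFrame(nodal_acc[m], index=idx)
                 for m in NODAL_METRICS
                 if np.isfinite(pd.DataFrame(nodal_acc[m]).to_numpy()).any()}

    tested = global_auc.dropna(axis=1, how="all")
    global_tests = compare_groups_metric(tested, rec, covariates=covariates)
    edge_table = compare_edgewise(fc_stack, labels, rec,
                                  covariates=covariates, alpha=alpha)
    nodal_input = {m: df for m, df in nodal_auc.items()
                   if m in ("degree", "betweenness", "efficiency")}
    nodal_table = compare_nodal(nodal_input, rec, covariates=covariates,
                                alpha=alpha)

    sig = edge_table[edge_table["significant"]]
    significant_edges = [(r.region1, r.region2) for r in sig.itertuples()]
    if significant_edges:
        composite = pd.Series(
            [abnormal_fc_score(ConnectivityMatrix(fc_stack[i], labels),
                               significant_edges)
             for i in range(len(sids))], index=idx, name="abnormal_fc")
    else:
        composite = None

    # clinical correlations within group 1 (the patient group)
    groups = rec["group"].to_numpy()
    mask = groups == groups[0]
    analysis_vars = {f"{m}_auc": global_auc[m].to_numpy()
                     for m in global_auc.columns}
    if composite is not None:
        analysis_vars["abnormal_fc"] = composite.to_numpy()
    for var in ("moca", "delayed_memory", "nadir_sao2", "ahi", "ess"):
        if var in rec.columns:
            analysis_vars[var] = rec[var].to_numpy(dtype=float)
    pairs = [("abnormal_fc", "cp_auc"), ("abnormal_fc", "lp_auc"),
             ("abnormal_fc", "eglob_auc"), ("abnormal_fc", "moca"),
             ("cp_auc", "moca"), ("cp_auc", "delayed_memory")]
    correlations = _clinical_correlations(analysis_vars, mask, pairs)

    return CohortAnalysis(
        records=rec, qc=qc, labels=labels, grid=np.asarray(grid, float),
        fc_stack=fc_stack, global_auc=global_auc, nodal_auc=nodal_auc,
        largest_component=largest_component, global_tests=global_tests,
        edge_table=edge_table, nodal_table=nodal_table,
        composite=composite, significant_edges=significant_edges,
        correlations=correlations)
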