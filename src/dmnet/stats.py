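"""Group-level statistics for connectivity and network metrics.

Implements the statistical surface of a two-group (patients vs controls)
DMN study: two-sample t-tests from published summary statistics,
covariate residualization (age, BMI, education), edgewise Fisher-z
connectivity comparison, nodal-metric comparison with Bonferroni
correction, the abnormal-connectivity composite score, and clinical
Pearson correlations.

Conventions (stated once, used everywhere):

* t statistics are pooled-variance two-sample t with ``df = n1 + n2 - 2``
  (identical to Welch when group sizes and variances match; a Welch
  variant is available by flag);
* positive t means group 1 > group 2;
* covariate residualization is fitted on the pooled sample of both
  groups, so group-specific covariate slopes cannot enter the contrast;
* edgewise tests run on Fisher-z transformed correlations (variance
  stabilized) while the composite score averages raw correlation
  coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "summary_ttest",
    "clinical_summary_table",
    "summary_ttest_table",
    "residualize",
    "groups_ttest",
    "compare_groups_metric",
    "compare_edgewise",
    "compare_nodal",
    "abnormal_fc_score",
    "correlate_clinical",
]


@dataclass
class SummaryStats:
    """Printed group summary: mean, standard deviation, group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def summary_ttest(a: SummaryStats, b: SummaryStats
                  ) -> tuple[float, int, float]:
    """Pooled two-sample t-test from summary statistics alone.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``.  Lets published
    group mean/SD tables be re-tested without subject-level data.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both groups have zero variance")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    t = (a.mean - b.mean) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def clinical_summary_table() -> pd.DataFrame:
    """Packaged published clinical group summaries (severe OSA vs good
    sleepers, n = 46 per group), with the published t values.

    ``t_recomputable = 1`` marks rows whose printed t is pinned to within
    +/-0.03 by the two-decimal printed summaries; the oxygen-desaturation
    row, for instance, is not (its printed t is inconsistent with its
    printed mean/SD, most likely a typesetting slip).
    """
    with resources.files("dmnet.data").joinpath(
            "osa_clinical_summary.csv").open() as fh:
        return pd.read_csv(fh)


def summary_ttest_table(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the two-sample t for every row of a clinical summary
    table (columns mean/sd/n per group); adds ``t`` and ``p`` columns."""
    if table is None:
        table = clinical_summary_table()
    out = table.copy()
    res = [summary_ttest(SummaryStats(r.mean_osa, r.sd_osa, int(r.n_osa)),
                         SummaryStats(r.mean_gs, r.sd_gs, int(r.n_gs)))
           for r in table.itertuples()]
    out["t"] = [r[0] for r in res]
    out["df"] = [r[1] for r in res]
    out["p"] = [r[2] for r in res]
    return out


# ---------------------------------------------------------------------------
# covariate adjustment and group contrasts
# ---------------------------------------------------------------------------

def residualize(values, covariates) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept, covariates].

    The fit uses the pooled sample (all subjects, both groups); residuals
    are orthogonal to every covariate.  Collinear covariate columns are
    dropped with a warning.
    """
    y = np.asarray(values, dtype=np.float64)
    X = np.asarray(covariates, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, np.newaxis]
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("values and covariates disagree on n")
    if n <= X.shape[1] + 1:
        raise ValueError("need more subjects than covariates + 1")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        keep = [0]
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, keep + [j]]) > len(keep):
                keep.append(j)
        dropped = sorted(set(range(design.shape[1])) - set(keep))
        warnings.warn(f"dropping collinear covariate column(s) "
                      f"{[j - 1 for j in dropped]}", RuntimeWarning)
        design = design[:, keep]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def _ttest_matrix(Y: np.ndarray, mask: np.ndarray, welch: bool = False
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled (or Welch) two-sample t for every column of ``Y`` at once."""
    A, B = Y[mask], Y[~mask]
    n1, n2 = len(A), len(B)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 subjects")
    v1 = A.var(axis=0, ddof=1)
    v2 = B.var(axis=0, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1)
                         + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = np.full_like(v1, float(n1 + n2 - 2))
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(se2)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def groups_ttest(values, group_mask, welch: bool = False
                 ) -> tuple[float, float, float]:
    """Two-sample t on raw per-subject values.

    ``group_mask`` is True for group 1; positive t means group 1 > group 2.
    Returns ``(t, df, p)``; pooled-variance by default, Welch by flag.
    """
    y = np.asarray(values, dtype=np.float64)
    m = np.asarray(group_mask, dtype=bool)
    t, df, p = _ttest_matrix(y[:, np.newaxis], m, welch=welch)
    return float(t[0]), float(df[0]), float(p[0])


def compare_groups_metric(auc_table: pd.DataFrame, records: pd.DataFrame,
                          covariates: tuple[str, ...] = ("age", "bmi",
                                                         "education"),
                          group_col: str = "group",
                          group1: str | None = None,
                          welch: bool = False) -> pd.DataFrame:
    """Covariate-adjusted group comparison of per-subject metric AUCs.

    ``auc_table`` is indexed by subject_id with one column per metric;
    ``records`` supplies group labels and covariates.  Subjects missing a
    metric are excluded pairwise.  ``group1`` names the group whose
    excess is reported as positive t (default: the group of the first
    record — patients first in generated cohorts); with ``group1`` held
    fixed, relabeling the groups flips every t.
    """
    rec = records.set_index("subject_id").loc[auc_table.index]
    groups = rec[group_col].to_numpy()
    g1 = group1 if group1 is not None else groups[0]
    mask = groups == g1
    X = rec[list(covariates)].to_numpy() if covariates else None
    rows = []
    for metric in auc_table.columns:
        y = auc_table[metric].to_numpy(dtype=float)
        finite = np.isfinite(y)
        if finite.sum() < 4:
            rows.append({"metric": metric, "t": np.nan, "df": np.nan,
                         "p": np.nan})
            continue
        yy, mm = y[finite], mask[finite]
        if X is not None:
            yy = residualize(yy, X[finite])
        t, df, p = groups_ttest(yy, mm, welch=welch)
        rows.append({"metric": metric, "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows).set_index("metric")
    out["direction"] = np.where(out["t"] > 0, f"{g1} > other",
                                f"{g1} < other")
    return out


def compare_edgewise(fc_stack: np.ndarray, labels, records: pd.DataFrame,
                     covariates: tuple[str, ...] = ("age", "bmi",
                                                    "education"),
                     alpha: float = 0.05, fisher_z: bool = True,
                     group_col: str = "group",
                     group1: str | None = None) -> pd.DataFrame:
    """Per-edge group comparison of connectivity.

    ``fc_stack`` is (n_subjects, N, N) of Pearson r in the subject order
    of ``records``.  Each unordered node pair is Fisher-z transformed
    (|r| = 1 entries are clipped to 1 - 1e-7 with a warning), residualized
    on the covariates over the pooled sample, and compared by two-sample
    t.  Returns C(N, 2) rows: region1, region2, t, p, significant
    (p < alpha, uncorrected).
    """
    F = np.asarray(fc_stack, dtype=np.float64)
    n_sub, n, _ = F.shape
    rec = records.reset_index(drop=True)
    if len(rec) != n_sub:
        raise ValueError("records and fc_stack disagree on subject count")
    groups = rec[group_col].to_numpy()
    mask = groups == (group1 if group1 is not None else groups[0])
    iu, ju = np.triu_indices(n, k=1)
    E = F[:, iu, ju]                       # subjects x edges
    if fisher_z:
        clipped = np.abs(E) >= 1.0
        if clipped.any():
            warnings.warn(f"clipping {int(clipped.sum())} |r| >= 1 "
                          "entries before Fisher z", RuntimeWarning)
            E = np.clip(E, -1 + 1e-7, 1 - 1e-7)
        E = np.arctanh(E)
    if covariates:
        X = rec[list(covariates)].to_numpy()
        design = np.column_stack([np.ones(len(rec)), X])
        coef, *_ = np.linalg.lstsq(design, E, rcond=None)
        E = E - design @ coef
    t, _, p = _ttest_matrix(E, mask)
    out = pd.DataFrame({"region1": np.asarray(labels)[iu],
                        "region2": np.asarray(labels)[ju],
                        "t": t, "p": p})
    out["significant"] = out["p"] < alpha
    return out


def compare_nodal(nodal_auc: dict[str, pd.DataFrame], records: pd.DataFrame,
                  covariates: tuple[str, ...] = ("age", "bmi", "education"),
                  alpha: float = 0.05, group_col: str = "group",
                  group1: str | None = None) -> pd.DataFrame:
    """Group comparison of nodal-metric AUCs with Bonferroni correction.

    ``nodal_auc`` maps metric name -> DataFrame (subjects x nodes).  For
    each node and metric family a residualized t-test is run; the
    Bonferroni multiplier is the number of nodes (applied per metric
    family, capped at 1).  Emits both the uncorrected and the corrected
    significance flag.
    """
    rows = []
    for metric, table in nodal_auc.items():
        n_nodes = table.shape[1]
        res = compare_groups_metric(table, records, covariates=covariates,
                                    group_col=group_col, group1=group1)
        for node in table.columns:
            p_raw = res.loc[node, "p"]
            rows.append({
                "node": node, "metric": metric,
                "t": res.loc[node, "t"], "p_raw": p_raw,
                "p_bonf": min(1.0, p_raw * n_nodes)
                if np.isfinite(p_raw) else np.nan,
            })
    out = pd.DataFrame(rows)
    out["sig_uncorrected"] = out["p_raw"] < alpha
    out["sig_bonferroni"] = out["p_bonf"] < alpha
    return out


def abnormal_fc_score(fc, significant_edges) -> float:
    """Mean raw correlation over a set of edges for one subject.

    The composite "abnormal connectivity" score: the unweighted average of
    the subject's raw Pearson r over the edges that showed a significant
    group difference.
    """
    edges = list(significant_edges)
    if not edges:
        raise ValueError("significant edge set is empty")
    values = getattr(fc, "values", fc)
    labels = getattr(fc, "labels", None)
    total = 0.0
    for a, b in edges:
        if isinstance(a, str):
            if labels is None:
                raise ValueError("edge names given but matrix has no labels")
            a, b = labels.index(a), labels.index(b)
        total += values[a, b]
    return float(total / len(edges))


def correlate_clinical(x, y) -> tuple[float, float, int]:
    """Pearson correlation with two-sided t-based p; pairwise-complete.

    Returns ``(r, p, n)`` over the subjects with both values finite.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(len(x))
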