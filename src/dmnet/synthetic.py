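"""Synthetic two-group cohorts with known connectivity ground truth.

Every downstream stage of the pipeline (denoising, connectivity, graph
metrics, group statistics) is exercised against cohorts generated here,
where the true group difference is known by construction and therefore
recoverable.  The generative model is deliberately minimal:

* Each group has a target 20-node correlation matrix built from a
  two-module (anterior/posterior DMN) block structure; the affected group
  receives a signed correlation change ``delta`` on a specified edge set
  (default: 8 posterior-module pairs, attenuated by 0.25, mirroring the
  decreased posterior connectivity reported in severe obstructive sleep
  apnea).
* Regional signals are Gaussian lag-1 autoregressive processes whose
  innovation correlation equals the target matrix, plus a linear drift
  and shared nuisance signals (white matter / CSF / global proxies) that
  the preprocessing stage is expected to remove.
* Head motion is a bounded random walk over the 6 rigid-body parameters;
  the step amplitude controls how often the motion-QC exclusion rule
  fires.
* Clinical variables are drawn from the published group summaries of the
  severe-OSA / good-sleeper comparison (see ``data/osa_clinical_summary``)
  and the MoCA score is, within the patient group, correlated with each
  subject's realized connectivity over the affected edges so that the
  clinical-correlation stage has a recoverable signal.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .connectivity import load_roi_table
from .metrics import BinaryGraph

__all__ = [
    "GroundTruthSpec",
    "build_group_covariances",
    "simulate_subject_timeseries",
    "simulate_motion",
    "simulate_clinical",
    "generate_benchmark_graph",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "DEFAULT_AFFECTED_EDGES",
]

#: Default affected edge set: posterior-module pairs (PCC-HF, PCC-Rsp,
#: HF-Rsp) whose attenuation emulates decreased posterior DMN coupling.
DEFAULT_AFFECTED_EDGES = (
    ("PCC.L", "HF.L"), ("PCC.L", "HF.R"), ("PCC.R", "HF.L"),
    ("PCC.R", "HF.R"), ("PCC.L", "Rsp.L"), ("HF.L", "Rsp.L"),
    ("HF.R", "Rsp.L"), ("HF.R", "Rsp.R"),
)

PD_EIG_FLOOR = 1e-6


def _default_modules() -> tuple[list[str], list[str]]:
    roi = load_roi_table()
    return list(roi["name"]), list(roi["module"])


@dataclass
class GroundTruthSpec:
    """Ground-truth connectivity structure for a two-group cohort.

    ``module_assignment`` maps each node to a module label; within-module
    edges get ``base_within_r``, between-module edges ``base_between_r``.
    Group 2 differs from group 1 by ``delta`` added to ``affected_edges``.
    """

    n_nodes: int = 20
    node_labels: Sequence[str] | None = None
    module_assignment: Sequence[str] | None = None
    base_within_r: float = 0.45
    base_between_r: float = 0.15
    affected_edges: Sequence[tuple] = DEFAULT_AFFECTED_EDGES
    delta: float = -0.25
    ar_coef: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.node_labels is None or self.module_assignment is None:
            if self.n_nodes == 20:
                labels, modules = _default_modules()
                if self.node_labels is None:
                    self.node_labels = labels
                if self.module_assignment is None:
                    self.module_assignment = modules
            else:
                if self.node_labels is None:
                    self.node_labels = [f"n{i}" for i in range(self.n_nodes)]
                if self.module_assignment is None:
                    half = self.n_nodes // 2
                    self.module_assignment = (
                        ["A"] * half + ["B"] * (self.n_nodes - half))
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length must equal n_nodes")
        if len(self.module_assignment) != self.n_nodes:
            raise ValueError("module_assignment length must equal n_nodes")
        for r in (self.base_within_r, self.base_between_r):
            if not 0 < abs(r) < 1 and r != 0:
                raise ValueError("base correlations must lie in (-1, 1)")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        hi = max(abs(self.base_within_r), abs(self.base_between_r))
        if hi + abs(self.delta) >= 1:
            raise ValueError("|base +/- delta| must stay below 1")
        self.affected_edges = [tuple(e) for e in self.affected_edges]

    def edge_indices(self) -> list[tuple[int, int]]:
        """Affected edges as sorted (i, j) index pairs."""
        labels = list(self.node_labels)
        out = []
        for a, b in self.affected_edges:
            i = labels.index(a) if isinstance(a, str) else int(a)
            j = labels.index(b) if isinstance(b, str) else int(b)
            if i == j:
                raise ValueError(f"self-edge in affected_edges: {(a, b)}")
            out.append((min(i, j), max(i, j)))
        return out


def _nearest_pd_correlation(C: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor, then re-normalize to unit diag."""
    w, V = np.linalg.eigh(C)
    if w.min() >= PD_EIG_FLOOR:
        return C
    w = np.clip(w, PD_EIG_FLOOR, None)
    C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    return (C + C.T) / 2.0


def build_group_covariances(spec: GroundTruthSpec
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Target correlation matrices for the two groups.

    Group 1 uses the base block structure; group 2 adds ``delta`` on the
    affected edges.  Both are repaired to positive definiteness by
    eigenvalue clipping (floor 1e-6) followed by diagonal re-normalization
    — naive delta injection can break PD — and an error is raised, listing
    the offending eigenvalues, if the repair fails.
    """
    mods = np.asarray(spec.module_assignment)
    same = mods[:, None] == mods[None, :]
    C1 = np.where(same, spec.base_within_r, spec.base_between_r)
    np.fill_diagonal(C1, 1.0)
    C2 = C1.copy()
    for i, j in spec.edge_indices():
        C2[i, j] += spec.delta
        C2[j, i] = C2[i, j]
    if np.any(np.abs(C2[~np.eye(spec.n_nodes, dtype=bool)]) >= 1):
        raise ValueError("delta pushes an affected correlation outside (-1, 1)")
    out = []
    for C in (C1, C2):
        C = _nearest_pd_correlation(C)
        w = np.linalg.eigvalsh(C)
        if w.min() <= 0:
            raise ValueError(
                f"correlation matrix not positive definite after repair; "
                f"offending eigenvalues: {w[w <= 0].tolist()}")
        out.append(C)
    return out[0], out[1]


def _ar1_series(L: np.ndarray, T: int, ar_coef: float,
                rng: np.random.Generator, burnin: int = 50) -> np.ndarray:
    """Lag-1 AR process with innovation covariance L @ L.T, unit variance."""
    n = L.shape[0]
    z = rng.standard_normal((T + burnin, n)) @ L.T
    if ar_coef:
        z = lfilter([1.0], [1.0, -ar_coef], z, axis=0)
        z = z * np.sqrt(1.0 - ar_coef ** 2)  # back to unit stationary var
    return z[burnin:]


def simulate_motion(T: int, rng: np.random.Generator,
                    step_mm: float = 0.05, bound: float = 1.8) -> np.ndarray:
    """Bounded random walk over 6 rigid-body parameters (T x 6).

    Steps are iid Gaussian with SD ``step_mm`` (mm for translations,
    degrees for rotations); the walk reflects at ``+/- bound`` so the
    max-displacement QC rule only fires when the bound exceeds it.  The
    step amplitude directly drives the mean relative RMS displacement.
    """
    steps = rng.normal(0.0, step_mm, size=(T, 6))
    walk = np.cumsum(steps, axis=0)
    # reflect into [-bound, bound]
    period = 4.0 * bound
    walk = np.mod(walk + bound, period)
    walk = np.where(walk > 2 * bound, period - walk, walk) - bound
    return walk


@dataclass
class SubjectSim:
    """One simulated subject: signals plus its contaminants."""

    timeseries: np.ndarray       # T x N, drift + nuisance injected
    motion: np.ndarray           # T x 6
    nuisance: np.ndarray         # T x 3 (WM, CSF, global proxies)
    clean: np.ndarray            # T x N, before contamination


def simulate_subject_timeseries(cov: np.ndarray, T: int, tr: float = 2.0,
                                ar_coef: float = 0.3,
                                drift_amp: float = 1.0,
                                nuisance_amp: float = 0.5,
                                motion_step_mm: float = 0.05,
                                seed=None) -> SubjectSim:
    """Simulate one subject's T x N regional signals.

    The innovation correlation of the lag-1 AR process equals ``cov`` (so
    the stationary correlation matrix also equals ``cov``); a per-node
    linear drift with slope SD ``drift_amp`` and three shared smooth
    nuisance signals with loading SD ``nuisance_amp`` are then added.
    Same seed, same output, bit for bit.
    """
    cov = np.asarray(cov, dtype=np.float64)
    n = cov.shape[0]
    if T < 2 * n:
        raise ValueError(f"need T >= 2*n_nodes = {2 * n}, got {T}")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive definite") from exc
    rng = np.random.default_rng(seed)
    clean = _ar1_series(L, T, ar_coef, rng)
    x = clean.copy()
    t01 = np.linspace(-0.5, 0.5, T)
    slopes = rng.normal(0.0, drift_amp, size=n)
    x = x + np.outer(t01, slopes)
    # smooth nuisance processes (heavily autocorrelated AR(1))
    nuis = lfilter([1.0], [1.0, -0.95], rng.standard_normal((T, 3)), axis=0)
    nuis = (nuis - nuis.mean(axis=0)) / nuis.std(axis=0)
    loadings = rng.normal(0.0, nuisance_amp, size=(3, n))
    x = x + nuis @ loadings
    motion = simulate_motion(T, rng, step_mm=motion_step_mm)
    return SubjectSim(timeseries=x, motion=motion, nuisance=nuis, clean=clean)


def simulate_clinical(metric_values, target_r: float, mean: float = 0.0,
                      sd: float = 1.0, seed=None) -> np.ndarray:
    """Clinical vector with expected correlation ``target_r`` to a metric.

    Construction: ``y = r * z(metric) + sqrt(1 - r^2) * noise`` rescaled
    to the requested mean/SD, so the population correlation with the
    metric is exactly ``target_r`` (and the sample correlation converges
    to it).  ``target_r = +/-1`` returns an exact affine transform.
    """
    x = np.asarray(metric_values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if not -1 <= target_r <= 1:
        raise ValueError("|target_r| must be <= 1")
    sx = x.std()
    if sx == 0:
        raise ValueError("metric values have zero variance")
    z = (x - x.mean()) / sx
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(x))
    y = target_r * z + np.sqrt(max(0.0, 1.0 - target_r ** 2)) * noise
    return mean + sd * y


def generate_benchmark_graph(kind: str, n: int | None = None,
                             k: int | None = None, p: float | None = None,
                             seed=None) -> BinaryGraph:
    """Named benchmark graphs used as metric fixtures.

    Kinds: ``complete``, ``star``, ``path``, ``ring_lattice`` (each node
    linked to its k nearest neighbors, k even), ``small_world`` (ring
    lattice with rewiring probability p), ``erdos_renyi``,
    ``two_disjoint_edges``.
    """
    import networkx as nx

    if kind == "complete":
        G = nx.complete_graph(n)
    elif kind == "star":
        G = nx.star_graph(n - 1)
    elif kind == "path":
        G = nx.path_graph(n)
    elif kind == "ring_lattice":
        if k is None or k % 2:
            raise ValueError("ring_lattice requires even k")
        G = nx.watts_strogatz_graph(n, k, 0.0)
    elif kind == "small_world":
        if k is None or k % 2:
            raise ValueError("small_world requires even k")
        G = nx.watts_strogatz_graph(n, k, p, seed=seed)
    elif kind == "erdos_renyi":
        G = nx.gnp_random_graph(n, p, seed=seed)
    elif kind == "two_disjoint_edges":
        G = nx.Graph([(0, 1), (2, 3)])
        G.add_nodes_from(range(4))
    else:
        raise ValueError(f"unknown benchmark graph kind {kind!r}")
    A = nx.to_numpy_array(G, nodelist=sorted(G.nodes()), dtype=np.uint8)
    return BinaryGraph(A)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _clinical_summary() -> pd.DataFrame:
    from importlib import resources

    with resources.files("dmnet.data").joinpath(
            "osa_clinical_summary.csv").open() as fh:
        return pd.read_csv(fh).set_index("variable")


#: (lo, hi) clamps keeping sampled clinical values in their valid ranges.
_CLINICAL_BOUNDS = {
    "bmi": (15.0, 50.0),
    "ahi": {"OSA": (30.0, 130.0), "GS": (0.0, 4.9)},
    "nadir_sao2": (30.0, 100.0),
    "moca": (0.0, 30.0),
    "delayed_memory": (0.0, 5.0),
    "ess": (0.0, 24.0),
}


@dataclass
class Cohort:
    """An in-memory two-group cohort: manifest plus per-subject arrays."""

    records: pd.DataFrame                  # one row per subject
    timeseries: dict[str, np.ndarray]      # subject_id -> T x N
    motion: dict[str, np.ndarray]          # subject_id -> T x 6
    nuisance: dict[str, np.ndarray]        # subject_id -> T x 3
    spec: GroundTruthSpec
    cov_group1: np.ndarray
    cov_group2: np.ndarray
    tr: float

    @property
    def node_labels(self) -> list[str]:
        return list(self.spec.node_labels)

    def subject_ids(self) -> list[str]:
        return list(self.records["subject_id"])


def generate_cohort(n_per_group: int = 46, n_volumes: int = 230,
                    tr: float = 2.0, spec: GroundTruthSpec | None = None,
                    seed: int = 0, drift_amp: float = 1.0,
                    nuisance_amp: float = 0.5, motion_step_mm: float = 0.05,
                    moca_coupling_r: float = -0.37,
                    match_covariates: bool = True,
                    group_names: tuple[str, str] = ("OSA", "GS")) -> Cohort:
    """Generate a two-group cohort with known ground truth.

    Group 1 (default label OSA) receives the delta-modified correlation
    structure; group 2 (GS) the base structure.  Defaults mirror the study
    design this package re-implements: 46 subjects per group, 230 retained
    volumes at TR = 2 s, 20 DMN nodes.  Clinical indices (AHI, nadir SaO2,
    MoCA, delayed memory, ESS) are drawn per group from the packaged
    published summaries; the MoCA score is additionally coupled (within
    the patient group) to each subject's realized mean correlation over
    the affected edges at ``moca_coupling_r``.

    With ``match_covariates=True`` (default) the three adjustment
    covariates — age, BMI, education — are drawn from the same
    distribution in both groups.  This makes them zero-effect nuisance
    variables, so covariate regression leaves the true group contrast
    intact; an independently sampled *group-separated* covariate would
    instead act as a pure confound and absorb part of the known effect,
    defeating the generator's purpose of providing recoverable truth
    (in real cohorts BMI relates to disease severity rather than being
    an independent coin-flip, so adjustment does not annihilate the
    effect there).  ``match_covariates=False`` draws BMI from the
    published group-specific summaries instead, for confound studies.
    """
    if spec is None:
        spec = GroundTruthSpec(seed=seed)
    cov2_base, cov1_delta = build_group_covariances(spec)
    # group 1 = affected (delta applied), group 2 = base
    root = np.random.SeedSequence(seed)
    summ = _clinical_summary()
    g1, g2 = group_names

    records = []
    ts, motion, nuisance = {}, {}, {}
    affected = spec.edge_indices()
    composite_truth: dict[str, float] = {}
    subj_seed_rng = np.random.default_rng(root.spawn(1)[0])
    clin_rng = np.random.default_rng(root.spawn(2)[1])

    for group, cov in ((g1, cov1_delta), (g2, cov2_base)):
        for i in range(n_per_group):
            sid = f"{group}{i + 1:03d}"
            sseed = int(subj_seed_rng.integers(0, 2 ** 31 - 1))
            sim = simulate_subject_timeseries(
                cov, n_volumes, tr=tr, ar_coef=spec.ar_coef,
                drift_amp=drift_amp, nuisance_amp=nuisance_amp,
                motion_step_mm=motion_step_mm, seed=sseed)
            ts[sid] = sim.timeseries
            motion[sid] = sim.motion
            nuisance[sid] = sim.nuisance
            if group == g1 and moca_coupling_r != 0:
                # couple clinical scores to the connectivity the analysis
                # will actually observe: composite on the denoised series
                from .preprocess import denoise

                clean = denoise(sim.timeseries, tr, motion=sim.motion,
                                nuisance=sim.nuisance)
                R = np.corrcoef(clean, rowvar=False)
                composite_truth[sid] = float(
                    np.mean([R[i_, j_] for i_, j_ in affected]))
            records.append({"subject_id": sid, "group": group,
                            "seed": sseed})
    rec = pd.DataFrame(records)

    # clinical covariates, drawn per group from the published summaries
    def draw(var: str, group: str, size: int) -> np.ndarray:
        if var == "age":
            mean, sd = 40.0, 9.0
        elif var == "education":
            mean, sd = 12.0, 3.0
        elif var == "bmi" and match_covariates:
            mean, sd = 25.3, 3.0    # pooled across the published groups
        else:
            row = summ.loc[var]
            col = "osa" if group == g1 else "gs"
            mean, sd = row[f"mean_{col}"], row[f"sd_{col}"]
        x = clin_rng.normal(mean, sd, size=size)
        bounds = _CLINICAL_BOUNDS.get(var)
        if isinstance(bounds, dict):
            bounds = bounds.get("OSA" if group == g1 else "GS")
        if bounds is not None:
            x = np.clip(x, *bounds)
        return x

    for var in ("age", "bmi", "education", "ahi", "nadir_sao2",
                "delayed_memory", "ess"):
        vals = np.empty(len(rec))
        for group in (g1, g2):
            m = (rec["group"] == group).to_numpy()
            vals[m] = draw(var, group, int(m.sum()))
        rec[var] = np.round(vals, 2)

    # MoCA: coupled to realized affected-edge connectivity within group 1
    moca = np.empty(len(rec))
    for group in (g1, g2):
        m = (rec["group"] == group).to_numpy()
        row = summ.loc["moca"]
        col = "osa" if group == g1 else "gs"
        mean, sd = row[f"mean_{col}"], row[f"sd_{col}"]
        if group == g1 and moca_coupling_r != 0 and int(m.sum()) >= 3:
            comp = np.array([composite_truth[s]
                             for s in rec.loc[m, "subject_id"]])
            cseed = int(clin_rng.integers(0, 2 ** 31 - 1))
            moca[m] = simulate_clinical(comp, -abs(moca_coupling_r)
                                        if moca_coupling_r < 0
                                        else moca_coupling_r,
                                        mean=mean, sd=sd, seed=cseed)
        else:
            moca[m] = clin_rng.normal(mean, sd, size=int(m.sum()))
    rec["moca"] = np.round(np.clip(moca, 0, 30), 2)

    cols = ["subject_id", "group", "age", "bmi", "education", "ahi",
            "nadir_sao2", "moca", "delayed_memory", "ess", "seed"]
    return Cohort(records=rec[cols], timeseries=ts, motion=motion,
                  nuisance=nuisance, spec=spec, cov_group1=cov1_delta,
                  cov_group2=cov2_base, tr=tr)


# ---------------------------------------------------------------------------
# on-disk format: one TSV per subject + manifest + ground truth
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = cohort.node_labels
    for sid in cohort.subject_ids():
        pd.DataFrame(cohort.timeseries[sid], columns=labels).to_csv(
            outdir / f"ts_{sid}.tsv", sep="\t", index=False,
            float_format="%.8g")
        np.savetxt(outdir / f"motion_{sid}.txt", cohort.motion[sid],
                   fmt="%.8g")
        pd.DataFrame(cohort.nuisance[sid],
                     columns=["wm", "csf", "global"]).to_csv(
            outdir / f"nuisance_{sid}.tsv", sep="\t", index=False,
            float_format="%.8g")
    cohort.records.to_csv(outdir / "subjects.csv", index=False)
    truth = {
        "spec": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                 for k, v in asdict(cohort.spec).items()},
        "tr": cohort.tr,
        "cov_group1": np.round(cohort.cov_group1, 10).tolist(),
        "cov_group2": np.round(cohort.cov_group2, 10).tolist(),
    }
    truth["spec"]["affected_edges"] = [list(e)
                                       for e in cohort.spec.affected_edges]
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return outdir


def read_cohort(indir) -> Cohort:
    indir = Path(indir)
    rec = pd.read_csv(indir / "subjects.csv")
    with open(indir / "ground_truth.json") as fh:
        truth = json.load(fh)
    spec_kw = dict(truth["spec"])
    spec_kw["affected_edges"] = [tuple(e) for e in spec_kw["affected_edges"]]
    spec = GroundTruthSpec(**spec_kw)
    ts, motion, nuisance = {}, {}, {}
    for sid in rec["subject_id"]:
        ts[sid] = pd.read_csv(indir / f"ts_{sid}.tsv", sep="\t").to_numpy()
        motion[sid] = np.loadtxt(indir / f"motion_{sid}.txt")
        nuisance[sid] = pd.read_csv(indir / f"nuisance_{sid}.tsv",
                                    sep="\t").to_numpy()
    return Cohort(records=rec, timeseries=ts, motion=motion,
                  nuisance=nuisance, spec=spec,
                  cov_group1=np.array(truth["cov_group1"]),
                  cov_group2=np.array(truth["cov_group2"]),
                  tr=truth["tr"])
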