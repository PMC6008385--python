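"""Shared fixtures: small benchmark graphs and the replicate studies.

The two session-scoped replicate studies (null and effect cohorts at the
default study size, 46+46 subjects x 230 volumes x 20 nodes) are the
expensive backbone of the recovery and type-I tests; they are computed
once and shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from dmnet import (GroundTruthSpec, analyze_cohort, generate_benchmark_graph,
                   generate_cohort)

N_NULL_REPS = 200
N_NULL_SIGMA_REPS = 50
N_EFFECT_REPS = 100

AFFECTED = [("PCC.L", "HF.L"), ("PCC.L", "HF.R"), ("PCC.R", "HF.L"),
            ("PCC.R", "HF.R"), ("PCC.L", "Rsp.L"), ("HF.L", "Rsp.L"),
            ("HF.R", "Rsp.L"), ("HF.R", "Rsp.R")]


@pytest.fixture(scope="session")
def star4():
    return generate_benchmark_graph("star", n=4)


@pytest.fixture(scope="session")
def complete4():
    return generate_benchmark_graph("complete", n=4)


@pytest.fixture(scope="session")
def triangle_pendant():
    A = np.zeros((4, 4))
    for i, j in [(0, 1), (0, 2), (1, 2), (0, 3)]:
        A[i, j] = A[j, i] = 1
    return A


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast 6-subject cohort for plumbing tests."""
    return generate_cohort(n_per_group=3, n_volumes=60, seed=11)


@dataclass
class ReplicateStudy:
    """Per-replicate group-test results across simulated cohorts."""

    global_t: pd.DataFrame        # reps x metric (t statistics)
    global_p: pd.DataFrame        # reps x metric
    edge_sig_rate: np.ndarray     # mean uncorrected flag rate per rep
    edge_sig_affected: np.ndarray     # flag rate on affected edges per rep
    edge_sig_unaffected: np.ndarray   # flag rate on unaffected edges per rep
    edge_t_affected_mean: np.ndarray  # mean t over affected edges per rep
    nodal_fwe: dict[str, np.ndarray]  # metric family -> any-Bonferroni flag


def _run_replicates(n_reps, delta, seed0, *, n_random=0, swaps_per_edge=0,
                    betweenness=False) -> ReplicateStudy:
    t_rows, p_rows = [], []
    e_rate, e_aff, e_unaff, e_t_aff = [], [], [], []
    fwe: dict[str, list[bool]] = {}
    for rep in range(n_reps):
        spec = GroundTruthSpec(delta=delta, seed=seed0 + rep)
        cohort = generate_cohort(spec=spec, seed=seed0 + rep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = analyze_cohort(cohort, n_random=n_random,
                               swaps_per_edge=swaps_per_edge,
                               include_eloc=False,
                               include_betweenness=betweenness,
                               seed=seed0 + rep)
        t_rows.append(a.global_tests["t"])
        p_rows.append(a.global_tests["p"])
        et = a.edge_table
        aff = {tuple(sorted(e)) for e in AFFECTED}
        is_aff = np.array([tuple(sorted((r1, r2))) in aff
                           for r1, r2 in zip(et["region1"], et["region2"])])
        e_rate.append(et["significant"].mean())
        e_aff.append(et.loc[is_aff, "significant"].mean())
        e_unaff.append(et.loc[~is_aff, "significant"].mean())
        e_t_aff.append(et.loc[is_aff, "t"].mean())
        if betweenness:
            nt = a.nodal_table
            for fam in nt["metric"].unique():
                fwe.setdefault(fam, []).append(
                    bool(nt.loc[nt["metric"] == fam,
                                "sig_bonferroni"].any()))
    return ReplicateStudy(
        global_t=pd.DataFrame(t_rows).reset_index(drop=True),
        global_p=pd.DataFrame(p_rows).reset_index(drop=True),
        edge_sig_rate=np.array(e_rate),
        edge_sig_affected=np.array(e_aff),
        edge_sig_unaffected=np.array(e_unaff),
        edge_t_affected_mean=np.array(e_t_aff),
        nodal_fwe={k: np.array(v) for k, v in fwe.items()})


@pytest.fixture(scope="session")
def null_study():
    """200 delta = 0 cohorts: raw global metrics, edgewise and nodal tests."""
    return _run_replicates(N_NULL_REPS, 0.0, 50_000, betweenness=True)


@pytest.fixture(scope="session")
def null_sigma_study():
    """50 delta = 0 cohorts including the rewired-null small-world AUCs.

    The null ensemble is tiny (2 rewired graphs, 1 swap per edge): under
    delta = 0 both groups share the same ensemble-noise distribution, so
    the test's type-I behavior does not depend on ensemble quality.
    """
    return _run_replicates(N_NULL_SIGMA_REPS, 0.0, 70_000, n_random=2,
                           swaps_per_edge=1)


@pytest.fixture(scope="session")
def effect_study():
    """100 cohorts with the 8 posterior edges attenuated by 0.25."""
    return _run_replicates(N_EFFECT_REPS, -0.25, 90_000)
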