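"""Run configuration, result writers and the plain-text report.

All tabular artifacts are headered TSV/CSV; graphs export as BrainNet
.node/.edge text files.  Every output directory receives a serialized
copy of the validated run configuration plus its hash, so any numeric
artifact is reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["RunConfig", "write_report", "load_config"]


@dataclass
class RunConfig:
    """Validated knobs for a pipeline run."""

    sparsity_lo: float = 0.05
    sparsity_hi: float = 0.50
    sparsity_step: float = 0.01
    n_random: int = 100
    swaps_per_edge: int = 100
    edge_rank: str = "signed"
    covariates: tuple[str, ...] = ("age", "bmi", "education")
    alpha: float = 0.05
    seed: int = 0
    apply_qc: bool = True
    apply_preprocess: bool = True
    include_betweenness: bool = True
    include_eloc: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.sparsity_lo < self.sparsity_hi <= 1:
            raise ValueError("need 0 < sparsity_lo < sparsity_hi <= 1")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be positive")
        if self.edge_rank not in ("signed", "abs"):
            raise ValueError("edge_rank must be 'signed' or 'abs'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_random < 0 or self.swaps_per_edge < 0:
            raise ValueError("n_random and swaps_per_edge must be >= 0")
        self.covariates = tuple(self.covariates)

    def grid(self) -> np.ndarray:
        n = int(round((self.sparsity_hi - self.sparsity_lo)
                      / self.sparsity_step)) + 1
        return np.round(self.sparsity_lo
                        + np.arange(n) * self.sparsity_step, 10)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        d = self.to_dict()
        d["config_hash"] = self.hash()
        with open(outdir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config file, validating every field."""
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    data.pop("config_hash", None)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**data)


def write_report(analysis, outdir, config: RunConfig | None = None) -> Path:
    """Write all group-level tables plus a human-readable summary.

    Missing sections (e.g. no significant edges, hence no composite) are
    marked MISSING in the text report rather than silently dropped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is not None:
        config.write(outdir)

    analysis.qc.to_csv(outdir / "qc.csv", index=False)
    analysis.global_auc.to_csv(outdir / "global_auc.csv")
    for metric, table in analysis.nodal_auc.items():
        table.to_csv(outdir / f"nodal_auc_{metric}.csv")
    analysis.largest_component.to_csv(outdir / "largest_component.csv")
    analysis.global_tests.to_csv(outdir / "global_tests.csv")
    analysis.edge_table.to_csv(outdir / "edge_tests.csv", index=False)
    analysis.nodal_table.to_csv(outdir / "nodal_tests.csv", index=False)
    analysis.correlations.to_csv(outdir / "correlations.csv", index=False)
    if analysis.composite is not None:
        analysis.composite.to_csv(outdir / "abnormal_fc.csv")

    lines = ["# DMN graph-analysis report", ""]
    if config is not None:
        lines += [f"config hash: {config.hash()}", ""]
    n1 = int((analysis.records["group"]
              == analysis.records["group"].iloc[0]).sum())
    lines += [
        f"subjects analyzed: {len(analysis.records)} "
        f"(group 1 n={n1}); excluded by motion QC: "
        f"{int((analysis.qc['decision'] == 'exclude').sum())}",
        f"sparsity grid: {analysis.grid[0]:.2f}..{analysis.grid[-1]:.2f} "
        f"({len(analysis.grid)} levels)",
        "",
        "## Global metric AUC group tests",
        analysis.global_tests.to_string(),
        "",
        "## Edgewise connectivity tests",
        f"{len(analysis.edge_table)} edges tested; "
        f"{int(analysis.edge_table['significant'].sum())} significant "
        "(uncorrected)",
        "",
        "## Nodal metric tests",
        f"{int(analysis.nodal_table['sig_uncorrected'].sum())} node-metric "
        "pairs significant uncorrected; "
        f"{int(analysis.nodal_table['sig_bonferroni'].sum())} after "
        "Bonferroni",
        "",
        "## Abnormal-connectivity composite",
        ("MISSING (no significant edges in this cohort)"
         if analysis.composite is None else
         f"computed over {len(analysis.significant_edges)} edges; "
         f"group-1 mean = "
         f"{analysis.composite.iloc[:n1].mean():.4f}"),
        "",
        "## Clinical correlations (within group 1)",
        (analysis.correlations.to_string(index=False)
         if len(analysis.correlations) else "MISSING"),
        "",
        "## Largest connected component (group mean over subjects)",
        pd.DataFrame({
            "sparsity": analysis.grid,
            "mean_size": analysis.largest_component.mean(axis=0).to_numpy(),
        }).to_string(index=False),
        "",
    ]
    (outdir / "report.txt").write_text("\n".join(lines))
    return outdir
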