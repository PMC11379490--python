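"""End-to-end driver: simulate/ingest -> QC -> score -> integrate -> match -> evaluate.

Every source of randomness derives from the single ``seed`` in
:class:`PipelineConfig`; running the same config twice produces an identical
report.  Each stage's outputs, the effective configuration and the seed are
written into the run directory.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .case_control import (
    DEFAULT_MATCH_COVARIATES,
    fit_propensity,
    match,
    select_cases,
    smd_table,
)
from .clinical_scores import qrisk2_passthrough
from .evaluation_stats import evaluate_assessment, percentile_enrichment
from .genotype_qc import QCThresholds, apply_qc
from .integrated_risk import IRTConfig, assess
from .prs_engine import compute_pcs, fit_ancestry_model, score_prs, standardize_prs
from .synthetic_cohort import (
    SimulationConfig,
    simulate_cohort,
    simulate_genotypes,
    simulate_weights,
)

log = logging.getLogger("cvdprs")

__all__ = ["PipelineConfig", "run_pipeline", "run_in_memory"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full run.

    Either ``simulate`` is set (synthetic mode) or the three input paths
    (genotypes, weights, phenotypes) point at existing files.
    """

    seed: int = 0
    outdir: str | None = None
    simulate: SimulationConfig | None = None
    genotypes_path: str | None = None
    weights_path: str | None = None
    phenotypes_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    irt: IRTConfig = field(default_factory=IRTConfig)
    n_pcs: int = 2
    match_ratio: int = 2
    caliper_sd: float = 0.2
    match_covariates: tuple[str, ...] = DEFAULT_MATCH_COVARIATES
    write_outputs: bool = True

    def __post_init__(self) -> None:
        if self.simulate is None:
            for p in (self.genotypes_path, self.weights_path, self.phenotypes_path):
                if p is None:
                    raise ValueError("need either a simulate config or all three input paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_in_memory(config: PipelineConfig) -> dict:
    """Run all stages and return {stage outputs + report} without touching disk."""
    t0 = time.time()
    if config.simulate is not None:
        sim = config.simulate.replace(seed=config.seed)
        gm = simulate_genotypes(sim)
        weights = simulate_weights(gm, seed=config.seed + 10)
        table = simulate_cohort(sim, gm, weights)
    else:
        gm = cio.read_genotypes(config.genotypes_path)
        weights = cio.read_weights(config.weights_path)
        table = cio.read_participants(config.phenotypes_path)

    gm_qc, qc_report = apply_qc(gm, config.qc)
    log.info("QC: %d -> %d variants", qc_report.n_input, qc_report.n_surviving)

    raw, flagged = score_prs(gm_qc, weights)
    pcs = compute_pcs(gm_qc, k=config.n_pcs, seed=config.seed) if config.n_pcs else None
    ok = np.isfinite(raw)
    model = fit_ancestry_model(raw[ok], pcs[ok] if pcs is not None else None, config.n_pcs)
    std = standardize_prs(raw, pcs, model)

    clin = qrisk2_passthrough(table)
    table = table.copy()
    table["qrisk2"] = clin
    table["prs_z"] = std.prs_z

    assessment, excluded = assess(table, std.prs_z, config.irt)
    merged = table.merge(assessment.drop(columns=["clinical_pct"]), on="id")

    cases, case_counts = select_cases(merged)
    pool = merged.loc[~merged["event"].astype(bool)]
    propensity = fit_propensity(merged, config.match_covariates)
    design = match(
        cases, pool, propensity, ratio=config.match_ratio,
        caliper_sd=config.caliper_sd, seed=config.seed + 20,
    )
    design.smd_before = smd_table(merged, cases["id"], pool["id"], config.match_covariates)
    design.smd_after = smd_table(merged, design.case_ids, design.control_ids, config.match_covariates)

    controls = merged.set_index("id").loc[design.control_ids].reset_index()
    case_assess = merged.loc[merged["event"].astype(bool)]
    report = evaluate_assessment(case_assess, controls)
    enr = percentile_enrichment(
        case_assess["prs_z"].to_numpy(), merged["prs_z"].to_numpy()
    )
    report.update(
        {
            "seed": config.seed,
            "n_subjects": len(merged),
            "n_controls_matched": len(design.control_ids),
            "achieved_ratio": design.achieved_ratio,
            "event_type_counts": case_counts,
            "qc": qc_report.to_dict()["counts"],
            "n_prs_flagged": len(flagged),
            "n_excluded_missing_prs": len(excluded),
            "prs_mean_cases": float(case_assess["prs_z"].mean()),
            "prs_mean_controls": float(controls["prs_z"].mean()),
            "smd_max_after": float(design.smd_after.max()),
            "enrichment_folds": dict(zip(enr["cut"].astype(str), enr["fold"])),
        }
    )
    report["runtime_s"] = round(time.time() - t0, 3)
    return {
        "genotypes": gm_qc,
        "weights": weights,
        "table": merged,
        "qc_report": qc_report,
        "design": design,
        "assessment": assessment,
        "report": report,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages, persisting per-stage outputs; returns the run directory."""
    outdir = Path(config.outdir or "cvdprs_run")
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    cio.dump_yaml(cfg_dict, outdir / "config.yaml")

    res = run_in_memory(config)
    cio.write_participants(res["table"], outdir / "cohort_assessed.csv", cfg_dict)
    cio.write_weights(res["weights"], outdir / "weights.tsv", cfg_dict)
    with (outdir / "qc_report.json").open("w") as fh:
        json.dump(res["qc_report"].to_dict(), fh, indent=2)
    res["design"].to_frame().to_csv(outdir / "matched_design.csv", index=False)
    pd.DataFrame(
        {"before": res["design"].smd_before, "after": res["design"].smd_after}
    ).to_csv(outdir / "smd.csv")
    with (outdir / "report.json").open("w") as fh:
        json.dump(res["report"], fh, indent=2, default=float)
    log.info("pipeline complete: %s", outdir)
    return outdir
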