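"""End-to-end orchestration: data -> selection -> purge -> refit -> report.

The pipeline mirrors the modeling procedure the package implements:
build the full quadratic candidate design, select the largest
all-significant term set with robust stepwise search, purge outliers
cyclically on that structure, refit on the purged records, and attach
robust inference, holdout performance measures and the assumption
diagnostics.  The report is a plain dict, JSON-serializable, and every
number in it is recomputable from the input data, the config and the
seed (both echoed in the report).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dataset import Dataset, build_design
from .diagnostics import mc_jarque_bera, run_mhtra
from .fitting import (
    DEFAULT_REL_TOL,
    adequacy_anova,
    error_nullity_test,
    fit_design,
    performance_measures,
    predicted_residuals,
)
from .outliers import run_codpa
from .predict import FinalModel
from .stepwise import run_msra

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("saltreg")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Thresholds and conventions for one pipeline run."""

    alpha: float = 0.05               # significance level for slope tests
    max_fdr: float = 0.30             # BH false-discovery rate for outlier cycles
    max_cycles: int = 25
    rel_tol: float = DEFAULT_REL_TOL  # SVD truncation threshold
    tss: str = "centered"             # "auto" | "centered" | "uncentered"
    n_mc: int = 10_000                # pseudo-realities for the normality test
    seed: int = 0
    ci_level: float = 0.50
    alpha_het: float = 0.05
    r2_ceiling: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.max_fdr < 1 or not 0 < self.ci_level < 1:
            raise ValueError("alpha, max_fdr and ci_level must be in (0, 1)")
        if self.tss not in ("auto", "centered", "uncentered"):
            raise ValueError("tss must be auto, centered or uncentered")


def run_pipeline(dataset: Dataset, config: RunConfig | None = None) -> dict:
    """Run the full modeling procedure and return the JSON-ready report."""
    config = config or RunConfig()
    report: dict = {"version": __version__, "config": asdict(config)}
    stage = "selection"
    try:
        selected, trace = run_msra(dataset, alpha=config.alpha, rel_tol=config.rel_tol)
        report["selected_terms"] = [t.name for t in selected]
        report["msra_trace"] = trace.to_dicts()
        report["msra_phase_counts"] = list(trace.phase_counts)
        for s in trace.steps:
            log.info("MSRA phase %d: %s %s", s.phase, s.action, [t.name for t in s.terms])
        if not selected:
            raise ValueError("no term is ever significant; nothing to model")

        stage = "outlier_screen"
        purged, cycle_reports = run_codpa(
            dataset, selected, max_fdr=config.max_fdr,
            max_cycles=config.max_cycles, rel_tol=config.rel_tol,
        )
        report["codpa_cycles"] = [r.to_dict() for r in cycle_reports]
        report["codpa_flags_per_cycle"] = [len(r.flagged_ids) for r in cycle_reports if r.flagged_ids]
        report["n_initial"] = dataset.n
        report["n_retained"] = purged.n
        for r in cycle_reports:
            log.info("CODPA cycle %d: flagged %d of %d", r.cycle_index, len(r.flagged_ids), r.n_before)

        stage = "refit"
        fit = fit_design(build_design(purged, selected), rel_tol=config.rel_tol)
        report["final_fit"] = fit.to_dict()
        report["measures"] = performance_measures(fit, tss=config.tss).to_dict()
        # both TSS conventions logged so printed-scale R2 values are diagnosable
        report["measures_centered"] = performance_measures(fit, tss="centered").to_dict()
        report["measures_uncentered"] = performance_measures(fit, tss="uncentered").to_dict()
        report["adequacy_anova_p"] = adequacy_anova(fit, tss="auto")
        report["error_nullity_p"] = error_nullity_test(fit)
        report["final_model"] = FinalModel.from_fit(
            fit, provenance=f"pipeline seed={config.seed}"
        ).to_dict()

        stage = "diagnostics"
        mhtra = run_mhtra(
            purged, fit, alpha_het=config.alpha_het,
            r2_ceiling=config.r2_ceiling, rel_tol=config.rel_tol,
        )
        mcjb = mc_jarque_bera(predicted_residuals(fit), n_mc=config.n_mc, seed=config.seed)
        report["mhtra"] = mhtra.to_dict()
        report["mc_jarque_bera"] = mcjb.to_dict()
    except Exception as exc:
        report["failed_stage"] = stage
        raise PipelineError(stage, exc) from exc
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default), encoding="utf-8")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
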