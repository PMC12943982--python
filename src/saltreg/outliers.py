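"""Cyclic outlier purging with FDR control (fit -> flag -> purge -> repeat).

Each cycle fits the working model on the current records, converts every
record's externally studentized (deletion) residual into an exact-null
t(n - p - 1) p-value, applies the Benjamini-Hochberg step-up procedure
at the configured false-discovery rate across all current records, and
removes every flagged record at once.  Cycling stops when a cycle flags
nothing, when a purge would leave too few records to refit, or at the
cycle cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import Dataset, Term, build_design
from .fitting import DEFAULT_REL_TOL, FitError, FitResult, fit_design

__all__ = [
    "OutlierCycleReport",
    "studentized_pvalues",
    "benjamini_hochberg",
    "run_codpa",
]


def studentized_pvalues(fit: FitResult) -> np.ndarray:
    """Exact-null outlier p-values from externally studentized residuals.

    Uses the closed-form deletion identity for the leave-one-out residual
    SD, so no refitting is needed:

        s_(i)^2 = ((n-p) s^2 - e_i^2/(1-h_ii)) / (n - p - 1)
        r_i     = e_i / (s_(i) sqrt(1 - h_ii))

    and r_i ~ t(n - p - 1) under the null of no outlier.  A record whose
    leverage is numerically 1 is flagged unconditionally (p = 0).
    """
    n, p = fit.n, fit.p
    if n <= p + 1:
        raise FitError("externally studentized residuals need n > p + 1")
    e, h = fit.resid, fit.hat
    sse = float(e @ e)
    # numerically exact fit: no record can be an outlier
    scale = max(1.0, float(np.abs(fit.design.response).max()))
    if sse <= n * (fit.rel_tol * scale) ** 2:
        return np.ones(n)
    pvals = np.ones(n)
    for i in range(n):
        if h[i] >= 1.0 - fit.rel_tol:
            pvals[i] = 0.0
            continue
        s_i_sq = (sse - e[i] ** 2 / (1.0 - h[i])) / (n - p - 1)
        if s_i_sq <= 0:
            pvals[i] = 0.0 if e[i] != 0 else 1.0
            continue
        r = e[i] / np.sqrt(s_i_sq * (1.0 - h[i]))
        pvals[i] = 2.0 * stats.t.sf(abs(r), n - p - 1)
    return pvals


def benjamini_hochberg(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Step-up BH rejection mask at FDR level q over m = len(pvalues) tests."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) / m) * q)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


@dataclass
class OutlierCycleReport:
    cycle_index: int
    flagged_ids: list[int]
    bh_threshold: float         # largest rejected p-value (0 if none)
    flagged_pvalues: list[float]
    n_before: int

    def to_dict(self) -> dict:
        return {
            "cycle_index": self.cycle_index,
            "flagged_ids": self.flagged_ids,
            "bh_threshold": self.bh_threshold,
            "flagged_pvalues": self.flagged_pvalues,
            "n_before": self.n_before,
        }


def run_codpa(
    dataset: Dataset,
    terms: list[Term],
    max_fdr: float = 0.30,
    max_cycles: int = 25,
    rel_tol: float = DEFAULT_REL_TOL,
) -> tuple[Dataset, list[OutlierCycleReport]]:
    """Purge outliers by cyclic BH screening on a fixed model structure.

    Returns the purged dataset and one report per completed cycle
    (including the terminal cycle that flags nothing).
    """
    if not 0 < max_fdr < 1:
        raise ValueError("max_fdr must be in (0, 1)")
    current = dataset
    reports: list[OutlierCycleReport] = []
    p = len(terms)

    for cycle in range(1, max_cycles + 1):
        if current.n <= p + 1:
            break
        fit = fit_design(build_design(current, terms), rel_tol=rel_tol)
        pvals = studentized_pvalues(fit)
        reject = benjamini_hochberg(pvals, max_fdr)
        flagged = np.flatnonzero(reject)
        ids = [current.record_ids[i] for i in flagged]
        reports.append(
            OutlierCycleReport(
                cycle_index=cycle,
                flagged_ids=ids,
                bh_threshold=float(pvals[flagged].max()) if flagged.size else 0.0,
                flagged_pvalues=[float(pvals[i]) for i in flagged],
                n_before=current.n,
            )
        )
        if not flagged.size:
            break
        if current.n - flagged.size <= p + 1:
            # purging would leave too few records to refit; keep current state
            reports[-1].flagged_ids = []
            reports[-1].flagged_pvalues = []
            break
        current = current.drop(ids)

    return current, reports
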