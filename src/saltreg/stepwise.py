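"""Three-phase stepwise term selection driven by robust (HC3) t-tests.

The goal is the term set of maximum cardinality in which every slope is
statistically significant under HC3 standard errors.  The search runs in
three phases:

1. *Backward elimination* — starting from all candidate terms, refit and
   drop the single term with the largest non-significant p-value, one
   step at a time, until every remaining slope is significant.
2. *Re-entry* — each previously removed term is tentatively added back
   (in canonical order) and kept only if the refitted model is again
   all-significant.
3. *Exchange* — each (retained, removed) pair is tentatively swapped;
   the swap is kept only if the result is all-significant and either
   larger or more decisively significant (strictly larger minimum |t|).

Phases 2 and 3 repeat until a full pass changes nothing.  Every accepted
change is one recorded step, so the audit trail mirrors the phase step
counts the procedure reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import Dataset, DesignMatrix, Term, build_design, full_quadratic_terms, select_terms
from .fitting import DEFAULT_REL_TOL, FitResult, fit_design

__all__ = ["SelectionStep", "SelectionTrace", "robust_slope_pvalues", "run_msra"]


def robust_slope_pvalues(fit: FitResult) -> np.ndarray:
    """Two-sided p-value per slope from t = slope / HC3 SD on t(n - p)."""
    if fit.dof <= 0:
        from .fitting import FitError

        raise FitError(f"no residual degrees of freedom (n={fit.n}, p={fit.p})")
    sds = fit.slope_sds
    pvals = np.empty(fit.p)
    for j, (b, sd) in enumerate(zip(fit.slopes, sds)):
        if sd == 0:
            pvals[j] = 1.0 if b == 0 else 0.0
        else:
            pvals[j] = 2.0 * stats.t.sf(abs(b / sd), fit.dof)
    return pvals


@dataclass
class SelectionStep:
    phase: int                      # 1, 2 or 3
    action: str                     # "remove" | "add" | "swap"
    terms: list[Term]               # the term(s) acted on
    p_values: dict[str, float]      # robust p-values before the action

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "action": self.action,
            "terms": [t.name for t in self.terms],
            "p_values": self.p_values,
        }


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    @property
    def phase_counts(self) -> tuple[int, int, int]:
        return tuple(sum(1 for s in self.steps if s.phase == k) for k in (1, 2, 3))

    def to_dicts(self) -> list[dict]:
        return [s.to_dict() for s in self.steps]


def _canonical_sort(terms: list[Term]) -> list[Term]:
    order = {t: k for k, t in enumerate(full_quadratic_terms())}
    return sorted(terms, key=order.__getitem__)


def _pvalue_map(fit: FitResult, pvals: np.ndarray) -> dict[str, float]:
    return {t.name: float(p) for t, p in zip(fit.terms, pvals)}


def run_msra(
    dataset: Dataset,
    alpha: float = 0.05,
    candidates: list[Term] | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
    max_passes: int = 50,
) -> tuple[list[Term], SelectionTrace]:
    """Modified stepwise search for the largest all-significant term set.

    Returns the selected terms (canonical order; possibly empty) and the
    step-by-step trace.  Deterministic: ties on the largest p-value are
    broken by removing the term that comes later in canonical order.
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    full = build_design(dataset, _canonical_sort(candidates) if candidates else None)

    current: list[Term] = list(full.terms)
    removed: list[Term] = []
    trace = SelectionTrace()

    def refit(terms: list[Term]) -> tuple[FitResult, np.ndarray]:
        fit = fit_design(select_terms(full, terms), rel_tol=rel_tol)
        return fit, robust_slope_pvalues(fit)

    # Phase 1: backward elimination.
    while current:
        fit, pvals = refit(current)
        insig = np.flatnonzero(pvals > alpha)
        if insig.size == 0:
            break
        # largest p; later canonical position wins ties
        worst_p = pvals[insig].max()
        tied = [int(j) for j in insig if pvals[j] == worst_p]
        j = tied[-1]
        victim = current[j]
        trace.steps.append(SelectionStep(1, "remove", [victim], _pvalue_map(fit, pvals)))
        current = [t for t in current if t != victim]
        removed.append(victim)

    def all_significant(pvals: np.ndarray) -> bool:
        return pvals.size > 0 and bool(np.all(pvals < alpha))

    # Phases 2-3, repeated until a full pass is quiet.
    for _ in range(max_passes):
        changed = False

        # Phase 2: re-entry.
        for cand in _canonical_sort(removed):
            trial = _canonical_sort(current + [cand])
            fit, pvals = refit(trial)
            if all_significant(pvals):
                trace.steps.append(SelectionStep(2, "add", [cand], _pvalue_map(fit, pvals)))
                current = trial
                removed = [t for t in removed if t != cand]
                changed = True

        # Phase 3: exchange.
        if current:
            _, cur_pvals = refit(current)
            cur_fit, _ = refit(current)
            cur_min_t = _min_abs_t(cur_fit)
            for t_in in list(current):
                accepted = False
                for t_out in _canonical_sort(removed):
                    trial = _canonical_sort([t for t in current if t != t_in] + [t_out])
                    fit, pvals = refit(trial)
                    if all_significant(pvals) and (
                        len(trial) > len(current) or _min_abs_t(fit) > cur_min_t
                    ):
                        trace.steps.append(
                            SelectionStep(3, "swap", [t_in, t_out], _pvalue_map(fit, pvals))
                        )
                        removed = [t for t in removed if t != t_out] + [t_in]
                        current = trial
                        cur_fit, _ = refit(current)
                        cur_min_t = _min_abs_t(cur_fit)
                        changed = True
                        accepted = True
                        break
                if accepted:
                    continue

        if not changed:
            break

    return _canonical_sort(current), trace


def _min_abs_t(fit: FitResult) -> float:
    sds = fit.slope_sds
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(np.where(sds > 0, fit.slopes / sds, np.inf))
    return float(t.min()) if t.size else -np.inf
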