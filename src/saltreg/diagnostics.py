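"""Post-fit assumption checks: heteroskedasticity and error normality.

The heteroskedasticity check is a White-style auxiliary regression: the
squared predicted residuals of the working model are regressed on the
full quadratic polynomial in the four raw predictors, and the auxiliary
model's overall-F p-value and adjusted R2 decide the verdict.  Constant
error variance implies the auxiliary model explains nothing.

Normality of the errors is tested with a Monte-Carlo-calibrated
Jarque-Bera statistic: the null distribution is simulated by drawing
standard-normal pseudo-samples of the same size, which makes the test
exact for small n instead of relying on the chi-square asymptotics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import Dataset, build_design, full_quadratic_terms
from .fitting import (
    DEFAULT_REL_TOL,
    FitResult,
    adequacy_anova,
    fit_design,
    performance_measures,
    predicted_residuals,
)

__all__ = ["MhtraResult", "McJbResult", "run_mhtra", "mc_jarque_bera", "jarque_bera_stat"]


@dataclass
class MhtraResult:
    anova_p: float
    aux_r2_adj: float
    verdict: str  # "homoskedastic" | "heteroskedastic"
    alpha_het: float
    r2_ceiling: float

    def to_dict(self) -> dict:
        return {
            "anova_p": self.anova_p,
            "aux_r2_adj": self.aux_r2_adj,
            "verdict": self.verdict,
            "alpha_het": self.alpha_het,
            "r2_ceiling": self.r2_ceiling,
        }


@dataclass
class McJbResult:
    jb_stat: float
    p_value: float
    n_mc: int
    seed: int

    def to_dict(self) -> dict:
        return {"jb_stat": self.jb_stat, "p_value": self.p_value, "n_mc": self.n_mc, "seed": self.seed}


def run_mhtra(
    dataset: Dataset,
    fit: FitResult,
    alpha_het: float = 0.05,
    r2_ceiling: float = 0.05,
    rel_tol: float = DEFAULT_REL_TOL,
) -> MhtraResult:
    """White-style heteroskedasticity test on squared predicted residuals.

    ``dataset`` must hold exactly the records the fit was computed on.
    Verdict is homoskedastic iff the auxiliary overall-F p-value is at
    least ``alpha_het`` and the auxiliary adjusted R2 is below
    ``r2_ceiling``.
    """
    if dataset.n != fit.n:
        raise ValueError("dataset and fit cover different record sets")
    aux_y = predicted_residuals(fit) ** 2
    if np.ptp(aux_y) == 0:
        # constant squared residuals carry no heteroskedasticity signal
        return MhtraResult(1.0, 0.0, "homoskedastic", alpha_het, r2_ceiling)
    aux_design = build_design(dataset, full_quadratic_terms())
    aux_design.response = aux_y
    aux_fit = fit_design(aux_design, rel_tol=rel_tol)
    anova_p = adequacy_anova(aux_fit)
    aux_r2_adj = performance_measures(aux_fit).r2_adj
    homo = anova_p >= alpha_het and aux_r2_adj < r2_ceiling
    return MhtraResult(
        anova_p=float(anova_p),
        aux_r2_adj=float(aux_r2_adj),
        verdict="homoskedastic" if homo else "heteroskedastic",
        alpha_het=alpha_het,
        r2_ceiling=r2_ceiling,
    )


def jarque_bera_stat(x: np.ndarray) -> float:
    """JB = n/6 * (skew^2 + (excess kurtosis)^2 / 4)."""
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        raise ValueError("constant sample: skewness/kurtosis undefined")
    n = x.size
    skew = stats.skew(x, bias=True)
    exkurt = stats.kurtosis(x, fisher=True, bias=True)
    return float(n / 6.0 * (skew**2 + exkurt**2 / 4.0))


def mc_jarque_bera(residuals: np.ndarray, n_mc: int = 10_000, seed: int = 0) -> McJbResult:
    """Monte-Carlo Jarque-Bera normality test.

    The p-value uses the add-one estimator (1 + #{JB* >= JB}) / (1 + n_mc),
    so it is never exactly zero and lies in (0, 1].
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 8:
        raise ValueError("need at least 8 residuals")
    if n_mc < 100:
        raise ValueError("need n_mc >= 100 pseudo-realities")
    jb = jarque_bera_stat(residuals)
    rng = np.random.default_rng(seed)
    n = residuals.size
    exceed = 0
    # chunked so memory stays flat for large n_mc
    chunk = max(1, min(n_mc, 2_000_000 // n))
    done = 0
    while done < n_mc:
        k = min(chunk, n_mc - done)
        sims = rng.standard_normal((k, n))
        sk = stats.skew(sims, axis=1, bias=True)
        ku = stats.kurtosis(sims, axis=1, fisher=True, bias=True)
        jb_null = n / 6.0 * (sk**2 + ku**2 / 4.0)
        exceed += int(np.count_nonzero(jb_null >= jb))
        done += k
    p = (1 + exceed) / (1 + n_mc)
    return McJbResult(jb_stat=jb, p_value=float(p), n_mc=n_mc, seed=seed)
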