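"""Response-surface prediction from a fitted quadratic model.

Given a final model (slopes, their HC3 covariance S, residual SD and
degrees of freedom), the engine computes the conditional mean of shoot
dry weight at any (SPAD, Gs, K+) point, the variance of the predicted
mean via the quadratic form x'Sx, and t-based confidence intervals.
Scenario grids sweep one input while holding the other two at fixed
levels, producing the tables behind the response-surface figures, and
the parabola optima (the Gs and K+ values that maximize predicted SDW)
fall out in closed form because the model has no cross terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Term
from .fitting import FitResult

__all__ = [
    "FinalModel",
    "ScenarioSpec",
    "published_model",
    "predict_mean",
    "predict_variance",
    "confidence_interval",
    "scenario_grid",
    "parabola_optimum",
    "figure_spec",
]

#: Sweep-variable aliases -> predictor index (1-based).
_VAR_INDEX = {"spad": 1, "gs": 2, "na": 3, "k": 4}


@dataclass
class FinalModel:
    """A fitted model ready for prediction: terms, slopes, covariance, dof."""

    terms: list[Term]
    slopes: np.ndarray
    cov: np.ndarray           # HC3 covariance of the slopes
    resid_sd: float           # g/plant
    dof: int
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.terms)
        if self.slopes.shape != (p,) or self.cov.shape != (p, p):
            raise ValueError("slopes/cov dimensions do not match the term list")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")

    @classmethod
    def from_fit(cls, fit: FitResult, provenance: str = "pipeline") -> "FinalModel":
        return cls(
            terms=list(fit.terms),
            slopes=fit.slopes.copy(),
            cov=fit.hc3_cov.copy(),
            resid_sd=fit.resid_sd,
            dof=fit.dof,
            provenance=provenance,
        )

    def observation_vector(self, spad: float, gs: float, k: float, na: float = 0.0) -> np.ndarray:
        """Evaluate the model's terms at one raw input point."""
        preds = np.array([[spad, gs, na, k]], dtype=float)
        return np.array([t.evaluate(preds)[0] for t in self.terms])

    def to_dict(self) -> dict:
        return {
            "terms": [t.name for t in self.terms],
            "slopes": self.slopes.tolist(),
            "cov": self.cov.tolist(),
            "resid_sd": self.resid_sd,
            "dof": self.dof,
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_dict(cls, obj: dict) -> "FinalModel":
        try:
            return cls(
                terms=[Term.parse(t) for t in obj["terms"]],
                slopes=np.asarray(obj["slopes"], dtype=float),
                cov=np.asarray(obj["cov"], dtype=float),
                resid_sd=float(obj["resid_sd"]),
                dof=int(obj["dof"]),
                provenance=obj.get("provenance", "json"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed model JSON: {exc}") from None

    @classmethod
    def load(cls, path: str | Path) -> "FinalModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def published_model_dict() -> dict:
    """Raw bundled reference-model JSON, including the reported slope SDs
    and slope correlations used for consistency checks."""
    text = resources.files("saltreg.data").joinpath("published_model.json").read_text("utf-8")
    return json.loads(text)


def published_model() -> FinalModel:
    """The bundled reference model (reported slopes, HC3 covariance, nu=119)."""
    return FinalModel.from_dict(published_model_dict())


def predict_mean(model: FinalModel, spad: float, gs: float, k: float, na: float = 0.0) -> float:
    """Conditional mean SDW (g/plant) at one raw input point."""
    return float(model.observation_vector(spad, gs, k, na) @ model.slopes)


def predict_variance(model: FinalModel, x: np.ndarray) -> float:
    """Variance of the predicted mean: the quadratic form x'Sx (clipped at 0)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.terms),):
        raise ValueError(f"observation vector must have length {len(model.terms)}")
    v = float(x @ model.cov @ x)
    return max(v, 0.0)


def confidence_interval(
    model: FinalModel,
    x: np.ndarray,
    level: float = 0.50,
    prediction: bool = False,
) -> tuple[float, float]:
    """t-based interval for the mean response at x.

    With ``prediction=True`` the residual variance is added, widening the
    band to cover a new observation rather than the mean.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mean = float(np.asarray(x, dtype=float) @ model.slopes)
    var = predict_variance(model, x)
    if prediction:
        var += model.resid_sd**2
    half = stats.t.ppf((1 + level) / 2, model.dof) * np.sqrt(var)
    return (mean - half, mean + half)


@dataclass
class ScenarioSpec:
    """One response-surface sweep: vary one input, fix the other two."""

    sweep: str                                  # "spad" | "gs" | "k"
    start: float
    stop: float
    step: float
    fixed: dict[str, list[float]] = field(default_factory=dict)
    level: float = 0.50

    def __post_init__(self) -> None:
        if self.sweep not in ("spad", "gs", "k"):
            raise ValueError("sweep variable must be spad, gs or k")
        if self.step <= 0 or self.stop < self.start:
            raise ValueError("empty or invalid sweep range")
        expected = {"spad", "gs", "k"} - {self.sweep}
        if set(self.fixed) != expected:
            raise ValueError(f"fixed levels required for {sorted(expected)}")

    def sweep_values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


#: The five published figure grids: (sweep, start, stop, step, fixed levels).
_FIGURE_SPECS = {
    1: ("spad", 10, 50, 1, {"k": [50, 100, 200], "gs": [10, 30, 50, 70, 90]}),
    2: ("k", 10, 300, 5, {"spad": [20, 30, 40], "gs": [10, 30, 50, 70, 90]}),
    3: ("gs", 10, 90, 2, {"spad": [20, 30, 40], "k": [20, 50, 100, 200, 300]}),
    4: ("gs", 10, 90, 2, {"k": [50, 100, 200], "spad": [10, 20, 30, 40, 50]}),
    5: ("k", 10, 300, 5, {"gs": [30, 60, 90], "spad": [10, 20, 30, 40, 50]}),
}


def figure_spec(number: int, level: float = 0.50) -> ScenarioSpec:
    """Preset scenario grid for figure 1..5."""
    if number not in _FIGURE_SPECS:
        raise ValueError("figure number must be 1..5")
    sweep, start, stop, step, fixed = _FIGURE_SPECS[number]
    return ScenarioSpec(sweep, start, stop, step, {k: list(v) for k, v in fixed.items()}, level)


def scenario_grid(model: FinalModel, spec: ScenarioSpec) -> pd.DataFrame:
    """Prediction table: one row per (sweep value x fixed-level combination)."""
    sweep_vals = spec.sweep_values()
    if sweep_vals.size == 0:
        raise ValueError("empty sweep range")
    fixed_names = sorted(spec.fixed)
    rows = []
    for v1 in spec.fixed[fixed_names[0]]:
        for v2 in spec.fixed[fixed_names[1]]:
            point = {fixed_names[0]: v1, fixed_names[1]: v2}
            for sv in sweep_vals:
                point[spec.sweep] = float(sv)
                x = model.observation_vector(point["spad"], point["gs"], point["k"])
                mean = float(x @ model.slopes)
                var = predict_variance(model, x)
                lo, hi = confidence_interval(model, x, spec.level)
                rows.append(
                    {
                        "sweep_var": spec.sweep,
                        "sweep_value": float(sv),
                        fixed_names[0]: v1,
                        fixed_names[1]: v2,
                        "mean_sdw_g": mean,
                        "var": var,
                        "ci_lo": lo,
                        "ci_hi": hi,
                    }
                )
    return pd.DataFrame(rows)


def parabola_optimum(model: FinalModel, variable: str) -> float:
    """Input value maximizing predicted SDW along one variable.

    Valid when that variable's quadratic coefficient is negative; with no
    cross terms the optimum -linear/(2*quadratic) is independent of the
    other inputs.
    """
    idx = _VAR_INDEX[variable]
    coeff = dict(zip(model.terms, model.slopes))
    quad = coeff.get(Term("square", (idx,)), 0.0)
    lin = coeff.get(Term("linear", (idx,)), 0.0)
    if quad >= 0:
        raise ValueError(f"no interior maximum: quadratic coefficient for {variable} is {quad}")
    return float(-lin / (2.0 * quad))


def plot_scenario(model: FinalModel, spec: ScenarioSpec, path: str | Path) -> None:
    """Optional rendered figure: one panel per first fixed level, one curve
    per second fixed level, dashed confidence bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = scenario_grid(model, spec)
    fixed_names = sorted(spec.fixed)
    panels = spec.fixed[fixed_names[0]]
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, v1 in zip(axes, panels):
        sub = table[table[fixed_names[0]] == v1]
        for v2, grp in sub.groupby(fixed_names[1]):
            (line,) = ax.plot(grp["sweep_value"], grp["mean_sdw_g"], label=f"{fixed_names[1]}={v2:g}")
            ax.plot(grp["sweep_value"], grp["ci_lo"], "--", lw=0.8, color=line.get_color())
            ax.plot(grp["sweep_value"], grp["ci_hi"], "--", lw=0.8, color=line.get_color())
        ax.set_title(f"{fixed_names[0]} = {v1:g}")
        ax.set_xlabel(spec.sweep)
    axes[0].set_ylabel("predicted SDW (g/plant)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
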