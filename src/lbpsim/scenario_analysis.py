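"""Dose-response smoothing and intervention-equivalence analysis.

Cumulative YLDs averted are smoothed against the intervention level
with ordinary least squares — linear in the level for the ergonomic and
exercise families (whose effect is proportional to coverage), linear in
ln(level) for the weight-loss family (whose effect is logarithmic in
BMI units per year).  The fitted lines yield per-unit effects with 95%
confidence intervals and, inverted, the intervention level required to
avert a specified number of YLDs (the equivalence analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DoseResponseFit",
    "EquivalenceResult",
    "fit_dose_response",
    "per_unit_effect",
    "solve_equivalence",
    "equivalence_plot_data",
    "plot_equivalence",
]


@dataclass
class DoseResponseFit:
    """OLS smoothing of cumulative YLDs averted against intervention level.

    ``form`` is ``"linear"`` (regressor = level) or ``"log"``
    (regressor = ln(level)).  ``cov`` is the 2x2 covariance of
    (intercept, slope); confidence limits use the t distribution with
    the residual degrees of freedom.
    """

    form: str
    slope: float
    intercept: float
    cov: np.ndarray
    r_squared: float
    df_resid: int
    levels: np.ndarray
    responses: np.ndarray

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    def _tcrit(self, alpha: float = 0.05) -> float:
        if self.df_resid <= 0:
            return float("nan")
        return float(stats.t.ppf(1 - alpha / 2, self.df_resid))

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        h = self._tcrit(alpha) * self.slope_se
        return self.slope - h, self.slope + h

    def predict(self, level) -> np.ndarray:
        x = np.log(level) if self.form == "log" else np.asarray(level, float)
        return self.intercept + self.slope * x


@dataclass
class EquivalenceResult:
    """Intervention levels averting a common YLD target, with 95% CIs."""

    target_ylds: float
    levels: dict[str, tuple[float, float, float]]  # name -> (est, lcl, ucl)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, self.target_ylds, est, lcl, ucl)
            for name, (est, lcl, ucl) in self.levels.items()
        ]
        return pd.DataFrame(
            rows, columns=["intervention", "target_ylds", "level", "lcl", "ucl"]
        )


def fit_dose_response(
    levels, responses, form: str = "linear"
) -> DoseResponseFit:
    """Fit cumulative YLDs averted against level (or its natural log)."""
    levels = np.asarray(levels, float)
    responses = np.asarray(responses, float)
    if levels.size < 3:
        raise ValueError("need at least 3 scenario points")
    if form not in ("linear", "log"):
        raise ValueError("form must be 'linear' or 'log'")
    if form == "log":
        if np.any(levels <= 0):
            raise ValueError("log form requires strictly positive levels")
        x = np.log(levels)
    else:
        x = levels
    X = sm.add_constant(x)
    res = sm.OLS(responses, X).fit()
    return DoseResponseFit(
        form=form,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        cov=np.asarray(res.cov_params()),
        r_squared=float(res.rsquared),
        df_resid=int(res.df_resid),
        levels=levels,
        responses=responses,
    )


def per_unit_effect(
    fit: DoseResponseFit, unit: float = 1.0, alpha: float = 0.05
) -> tuple[float, float, float]:
    """YLDs averted per ``unit`` of intervention, with its CI.

    For a log-form fit the unit is in ln(level) (e.g. 0.1 log-BMI
    units); for linear fits it is in level units (e.g. 1% coverage).
    """
    lcl, ucl = fit.slope_ci(alpha)
    return fit.slope * unit, lcl * unit, ucl * unit


def _invert(fit: DoseResponseFit, target: float, alpha: float = 0.05):
    """Level averting ``target`` YLDs, delta-method CI from the fit."""
    if fit.slope <= 0:
        raise ValueError("cannot invert a non-positive dose-response slope")
    a, b = fit.intercept, fit.slope
    x = (target - a) / b
    # gradient of x wrt (a, b)
    g = np.array([-1.0 / b, -x / b])
    if fit.form == "log":
        level = float(np.exp(x))
        g = g * level  # chain rule through exp
    else:
        level = float(x)
    se = float(np.sqrt(g @ fit.cov @ g))
    h = stats.t.ppf(1 - alpha / 2, fit.df_resid) * se if fit.df_resid > 0 else np.nan
    return level, level - h, level + h


def solve_equivalence(
    fits: dict[str, DoseResponseFit], target_ylds: float, alpha: float = 0.05,
    warn_extrapolation: bool = True,
) -> EquivalenceResult:
    """Solve each intervention's level averting ``target_ylds``.

    Inverts the fitted line (or log-line); warns when the target lies
    outside the fitted response range.
    """
    import warnings

    levels = {}
    for name, fit in fits.items():
        if warn_extrapolation and not (
            fit.responses.min() <= target_ylds <= fit.responses.max()
        ):
            warnings.warn(
                f"{name}: target {target_ylds:,.0f} YLDs lies outside the "
                "fitted scenario range; extrapolating",
                stacklevel=2,
            )
        levels[name] = _invert(fit, target_ylds, alpha)
    return EquivalenceResult(target_ylds=float(target_ylds), levels=levels)


def equivalence_plot_data(
    fits: dict[str, DoseResponseFit], targets
) -> pd.DataFrame:
    """One row per target: the level of every intervention averting it."""
    frames = []
    for t in targets:
        res = solve_equivalence(fits, t, warn_extrapolation=False)
        row = {"target_ylds": t}
        for name, (est, lcl, ucl) in res.levels.items():
            row[name] = est
            row[f"{name}_lcl"] = lcl
            row[f"{name}_ucl"] = ucl
        frames.append(row)
    cols = ["target_ylds"]
    for name in fits:
        cols += [name, f"{name}_lcl", f"{name}_ucl"]
    return pd.DataFrame(frames, columns=cols)


def plot_equivalence(
    fits: dict[str, DoseResponseFit], targets, x_intervention: str, ax=None
):
    """Equivalence plot: coverage interventions against the BMI axis."""
    import matplotlib.pyplot as plt

    table = equivalence_plot_data(fits, targets)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = table[x_intervention]
    for name in fits:
        if name == x_intervention:
            continue
        ax.plot(x, table[name], "o-", label=name)
        for _, r in table.iterrows():
            ax.annotate(
                f"{r['target_ylds']/1000:.0f}", (r[x_intervention], r[name]),
                textcoords="offset points", xytext=(4, 4), fontsize=8,
            )
    ax.set_xlabel(f"{x_intervention} level")
    ax.set_ylabel("coverage (%)")
    ax.legend()
    return ax
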