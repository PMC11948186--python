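"""Longitudinal evoked-vs-resting comparison.

A linear mixed-effects model with a restricted cubic spline time basis
(four knots at the 5th/35th/65th/95th percentiles of week), condition and
condition-by-time interaction as fixed effects, and a per-animal random
intercept for the repeated-measures structure.  Two significance readouts
are reported separately:

* a likelihood-ratio test for any condition effect (main + interaction),
* the per-week CI-overlap rule — a week is flagged only if the two
  conditions' 1.96 SE bands around the fitted curves are disjoint
  (touching bands count as overlapping, hence not significant).

Time effects on their own are assessed with one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import SplineBasis

__all__ = [
    "rcs_basis",
    "fit_condition_time_model",
    "ci_overlap_significance",
    "anova_tukey",
    "ConditionTimeFit",
]

KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


def rcs_basis(x, knot_quantiles=KNOT_QUANTILES, knots=None):
    """Restricted cubic spline basis (Harrell parameterization), 4 knots.

    For knots t1 < t2 < t3 < t4 the design columns are x and

        C_j(x) = [(x-t_j)+^3 - (x-t3)+^3 (t4-t_j)/(t4-t3)
                  + (x-t4)+^3 (t3-t_j)/(t4-t3)] / (t4-t1)^2,  j = 1, 2

    which is cubic inside [t1, t4] and exactly linear outside it.
    """
    x = np.asarray(x, dtype=float).ravel()
    if knots is None:
        knots = np.quantile(x, knot_quantiles)
    knots = np.asarray(knots, dtype=float)
    if knots.size != 4 or np.any(np.diff(knots) <= 0):
        raise ValueError("need 4 strictly increasing knots")
    t1, t2, t3, t4 = knots
    scale = (t4 - t1) ** 2

    def transform(xn):
        xn = np.asarray(xn, dtype=float).ravel()
        cols = [xn]
        for tj in (t1, t2):
            term = (
                np.maximum(xn - tj, 0.0) ** 3
                - np.maximum(xn - t3, 0.0) ** 3 * (t4 - tj) / (t4 - t3)
                + np.maximum(xn - t4, 0.0) ** 3 * (t3 - tj) / (t4 - t3)
            )
            cols.append(term / scale)
        return np.column_stack(cols)

    return SplineBasis(knots=knots, transform=transform)


@dataclass
class ConditionTimeFit:
    """Fitted condition-by-time model with per-condition curves and SEs."""

    basis: SplineBasis
    params: np.ndarray
    cov_params: np.ndarray
    loglike: float
    loglike_reduced: float
    lr_stat: float
    lr_df: int
    lr_p: float
    weeks: np.ndarray
    curves: dict  # condition -> fitted values over weeks
    ses: dict  # condition -> SE of fitted values over weeks
    conditions: tuple = ("resting", "evoked")
    used_fallback: bool = False
    flags: list = field(default_factory=list)


def _design(weeks, is_evoked, basis):
    s = basis.transform(weeks)
    n = len(weeks)
    cond = np.asarray(is_evoked, dtype=float)
    x = np.column_stack([np.ones(n), s, cond, cond[:, None] * s])
    return x


def _fit_mixed(endog, exog, groups):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        try:
            res = model.fit(reml=False, method="bfgs", maxiter=200)
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="powell", maxiter=500)
    return res


def fit_condition_time_model(table: pd.DataFrame, basis: SplineBasis | None = None):
    """Fit the spline x condition mixed model to a longitudinal table.

    ``table`` needs columns animal, week, condition ("resting"/"evoked"),
    value.  The model is

        value ~ 1 + rcs(week) + evoked + evoked:rcs(week) + (1 | animal)

    fitted by maximum likelihood (so the LR test on the condition terms is
    valid).  A singular mixed fit falls back to OLS with animal-clustered
    robust covariance, flagged on the result.
    """
    required = {"animal", "week", "condition", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table.duplicated(["animal", "week", "condition"]).any():
        raise ValueError("duplicated (animal, week, condition) rows")
    if table["animal"].nunique() < 2:
        raise ValueError("need at least 2 animals")
    if table["week"].nunique() < 4:
        raise ValueError("need at least 4 distinct weeks")

    weeks_col = table["week"].to_numpy(dtype=float)
    if basis is None:
        basis = rcs_basis(weeks_col)
    is_evoked = (table["condition"] == "evoked").to_numpy()
    y = table["value"].to_numpy(dtype=float)
    groups = table["animal"].to_numpy()

    x_full = _design(weeks_col, is_evoked, basis)
    x_reduced = x_full[:, : 1 + basis.transform([0.0]).shape[1]]  # drop condition terms
    n_cond_terms = x_full.shape[1] - x_reduced.shape[1]

    flags = []
    used_fallback = False
    try:
        res_full = _fit_mixed(y, x_full, groups)
        res_red = _fit_mixed(y, x_reduced, groups)
        params = np.asarray(res_full.fe_params)
        cov = np.asarray(res_full.cov_params())[: params.size, : params.size]
        ll_full, ll_red = float(res_full.llf), float(res_red.llf)
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
            raise np.linalg.LinAlgError("non-finite mixed-model fit")
    except (np.linalg.LinAlgError, ValueError) as err:
        import statsmodels.api as sm

        flags.append(f"mixed model failed ({err}); cluster-robust OLS fallback")
        used_fallback = True
        res_full = sm.OLS(y, x_full).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
        res_red = sm.OLS(y, x_reduced).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
        params = np.asarray(res_full.params)
        cov = np.asarray(res_full.cov_params())
        ll_full, ll_red = float(res_full.llf), float(res_red.llf)

    lr_stat = max(2.0 * (ll_full - ll_red), 0.0)
    lr_p = float(stats.chi2.sf(lr_stat, n_cond_terms))

    weeks_grid = np.unique(weeks_col)
    curves, ses = {}, {}
    for cond, flag in (("resting", 0), ("evoked", 1)):
        xg = _design(weeks_grid, np.full(weeks_grid.size, flag), basis)
        curves[cond] = xg @ params
        ses[cond] = np.sqrt(np.einsum("ij,jk,ik->i", xg, cov, xg))

    return ConditionTimeFit(
        basis=basis,
        params=params,
        cov_params=cov,
        loglike=ll_full,
        loglike_reduced=ll_red,
        lr_stat=float(lr_stat),
        lr_df=int(n_cond_terms),
        lr_p=lr_p,
        weeks=weeks_grid,
        curves=curves,
        ses=ses,
        used_fallback=used_fallback,
        flags=flags,
    )


def ci_overlap_significance(fit: ConditionTimeFit, z=1.96):
    """Per-week flags: True where the two conditions' z*SE bands are disjoint.

    Touching intervals count as overlapping (not significant) — strictly
    more conservative than a pointwise z-test on the difference.
    """
    lo_e = fit.curves["evoked"] - z * fit.ses["evoked"]
    hi_e = fit.curves["evoked"] + z * fit.ses["evoked"]
    lo_r = fit.curves["resting"] - z * fit.ses["resting"]
    hi_r = fit.curves["resting"] + z * fit.ses["resting"]
    return (lo_e > hi_r) | (lo_r > hi_e)


def anova_tukey(groups, labels=None, alpha=0.05):
    """One-way ANOVA with Tukey HSD post-hoc comparisons.

    ``groups`` is a sequence of 1-D samples (or a mapping label -> sample).
    Returns ``(F, p, tukey_table)`` where the table has one row per pair with
    the studentized-range-adjusted p-value.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        groups = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        groups = [np.asarray(g, dtype=float) for g in groups]
        if labels is None:
            labels = [f"g{i}" for i in range(len(groups))]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    f_stat, p = stats.f_oneway(*groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    labs = np.concatenate([[lab] * len(g) for lab, g in zip(labels, groups)])
    tk = pairwise_tukeyhsd(values, labs, alpha=alpha)
    table = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return float(f_stat), float(p), table
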