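"""Age-by-group divergence and heterogeneity battery on the Brain-PAD table.

Implements the full trajectory analysis: HC-based age-bias correction,
the linear age x group interaction model (covarying sex and scanner),
piecewise regression with a knot at 40 years, natural-cubic-spline fits
with an omnibus group test, LOESS smooths for visualization, quantile
regression, the Brown-Forsythe variance test, binned dispersion and
ribbon summaries, and the sensitivity suite (age trimming, inverse
probability weighting, leave-one-out influence, robust refit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.anova import anova_lm

PAD_COLUMNS = ["id", "group", "age", "brain_pad"]
_HC = "HC"


@dataclass
class ModelFitResult:
    """Coefficient table plus named contrasts for one fitted model."""

    name: str
    coef: pd.DataFrame  # index: term; columns: estimate, se, stat, p
    contrasts: dict = field(default_factory=dict)
    n: int = 0
    extra: dict = field(default_factory=dict)


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PAD_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PAD table missing column(s): {', '.join(missing)}")
    if not np.all(np.isfinite(table["age"])):
        raise ValueError("ages must be finite")
    return table.copy()


def _covariate_terms(table: pd.DataFrame) -> str:
    """Sex/scanner adjustment terms, omitting single-level covariates."""
    terms = []
    for cov in ("sex", "scanner"):
        if cov in table.columns and table[cov].nunique() > 1:
            terms.append(f"C({cov})")
    return (" + " + " + ".join(terms)) if terms else ""


def _check_rank(res) -> None:
    exog = res.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [name for name, d in zip(res.model.exog_names, diag)
                   if d < 1e-8 * diag.max()]
        raise ValueError(f"design is rank deficient; aliased column(s): {aliased}")


def _scalar(x) -> float:
    return float(np.asarray(x).reshape(-1)[0])


def _coef_frame(res) -> pd.DataFrame:
    return pd.DataFrame({
        "estimate": res.params, "se": res.bse,
        "stat": res.tvalues, "p": res.pvalues,
    })


# ---------------------------------------------------------------------------
# age-bias correction


def age_bias_correct(table: pd.DataFrame, method: str = "residual"
                     ) -> tuple[pd.DataFrame, dict]:
    """HC-based age-bias correction of Brain-PAD.

    ``residual`` fits brain_pad ~ alpha + beta*age on HC and subtracts the
    fitted line from every subject. ``rescale`` fits predicted age ~
    alpha + beta*age on HC and inverts that calibration (predicted' =
    (predicted - alpha)/beta), which additionally undoes the regression-
    toward-the-mean attenuation of offsets in held-out groups. Both leave
    HC residuals with ~zero mean and ~zero age correlation.
    """
    table = _check_table(table)
    hc = table[table["group"] == _HC]
    if len(hc) < 3 or np.isclose(hc["age"].std(), 0.0):
        raise ValueError("need >= 3 HC rows with age variance for bias correction")
    out = table.copy()
    if method == "residual":
        beta, alpha = np.polyfit(hc["age"], hc["brain_pad"], 1)
        out["brain_pad"] = table["brain_pad"] - (alpha + beta * table["age"])
    elif method == "rescale":
        pred_hc = hc["brain_pad"] + hc["age"]
        beta, alpha = np.polyfit(hc["age"], pred_hc, 1)
        if beta <= 0.05:
            raise ValueError(
                f"degenerate HC calibration slope {beta:.3f}; cannot rescale")
        pred = table["brain_pad"] + table["age"]
        out["brain_pad"] = (pred - alpha) / beta - table["age"]
    else:
        raise ValueError(f"unknown method {method!r}")
    return out, {"alpha": float(alpha), "beta": float(beta), "method": method}


# ---------------------------------------------------------------------------
# mean-trajectory models


def fit_interaction(table: pd.DataFrame) -> ModelFitResult:
    """OLS of brain_pad ~ age x group (HC reference), covarying sex/scanner.

    Contrasts: patient intercept and age-slope contrasts versus HC, and
    the direct BD-SZ slope contrast (Wald chi2).
    """
    table = _check_table(table)
    groups = set(table["group"])
    formula = (f"brain_pad ~ age * C(group, Treatment('{_HC}'))"
               + _covariate_terms(table))
    res = smf.ols(formula, data=table).fit()
    _check_rank(res)
    contrasts = {}
    for g in sorted(groups - {_HC}):
        icpt = f"C(group, Treatment('{_HC}'))[T.{g}]"
        slope = f"age:C(group, Treatment('{_HC}'))[T.{g}]"
        for label, term in ((f"{g}_intercept_vs_HC", icpt),
                            (f"{g}_slope_vs_HC", slope)):
            tt = res.t_test(term)
            contrasts[label] = {
                "estimate": _scalar(tt.effect), "se": _scalar(tt.sd),
                "stat": _scalar(tt.tvalue), "p": _scalar(tt.pvalue)}
    if {"BD", "SZ"} <= groups:
        term = (f"age:C(group, Treatment('{_HC}'))[T.BD] - "
                f"age:C(group, Treatment('{_HC}'))[T.SZ]")
        wt = res.wald_test(term, use_f=False, scalar=True)
        contrasts["BD_minus_SZ_slope"] = {
            "estimate": _scalar(res.t_test(term).effect),
            "chi2": _scalar(wt.statistic) * 1.0, "p": _scalar(wt.pvalue)}
    return ModelFitResult(name="interaction", coef=_coef_frame(res),
                          contrasts=contrasts, n=int(res.nobs),
                          extra={"results": res})


def fit_piecewise(table: pd.DataFrame, knot: float = 40.0) -> ModelFitResult:
    """Continuous piecewise-linear age model with a knot, by group.

    Uses basis (age, max(0, age - knot)) interacted with group; reports
    per-group pre- and post-knot slopes and BD-SZ slope contrasts.
    """
    table = _check_table(table)
    empty = [g for g, sub in table.groupby("group")
             if not ((sub["age"] < knot).any() and (sub["age"] > knot).any())]
    if empty:
        raise ValueError(
            f"no observations on both sides of the knot ({knot}) in group(s): "
            f"{empty}")
    table = table.assign(age_post=np.maximum(0.0, table["age"] - knot))
    formula = (f"brain_pad ~ (age + age_post) * C(group, Treatment('{_HC}'))"
               + _covariate_terms(table))
    res = smf.ols(formula, data=table).fit()
    _check_rank(res)
    groups = sorted(set(table["group"]))
    contrasts = {}
    for g in groups:
        inter = "" if g == _HC else (
            f" + age:C(group, Treatment('{_HC}'))[T.{g}]")
        inter_post = "" if g == _HC else (
            f" + age_post:C(group, Treatment('{_HC}'))[T.{g}]")
        pre = res.t_test(f"age{inter}")
        post = res.t_test(f"age{inter} + age_post{inter_post}")
        extra = res.t_test(f"age_post{inter_post}")
        contrasts[f"{g}_pre_knot_slope"] = {
            "estimate": _scalar(pre.effect), "se": _scalar(pre.sd),
            "p": _scalar(pre.pvalue)}
        contrasts[f"{g}_post_knot_slope"] = {
            "estimate": _scalar(post.effect), "se": _scalar(post.sd),
            "p": _scalar(post.pvalue)}
        contrasts[f"{g}_post_knot_extra_slope"] = {
            "estimate": _scalar(extra.effect), "se": _scalar(extra.sd),
            "p": _scalar(extra.pvalue)}
    if {"BD", "SZ"} <= set(groups):
        for what, base in (("pre", "age"), ("post_extra", "age_post")):
            term = (f"{base}:C(group, Treatment('{_HC}'))[T.BD] - "
                    f"{base}:C(group, Treatment('{_HC}'))[T.SZ]")
            wt = res.wald_test(term, use_f=False, scalar=True)
            contrasts[f"BD_minus_SZ_{what}_slope"] = {
                "chi2": _scalar(wt.statistic), "p": _scalar(wt.pvalue)}
    return ModelFitResult(name="piecewise", coef=_coef_frame(res),
                          contrasts=contrasts, n=int(res.nobs),
                          extra={"results": res, "knot": knot})


def fit_spline(table: pd.DataFrame, df: int = 4,
               n_grid: int = 50) -> ModelFitResult:
    """Natural cubic spline on age, interacted with group.

    Emits fitted group mean curves with pointwise 95% intervals on an age
    grid and an omnibus F-test of any group difference (full vs
    age-spline-only nested model).
    """
    table = _check_table(table)
    if df < 3:
        raise ValueError("df must be >= 3")
    if (table.groupby("group").size() <= df).any():
        raise ValueError("each group needs n > df")
    cov = _covariate_terms(table)
    full = smf.ols(
        f"brain_pad ~ cr(age, df={df}) * C(group, Treatment('{_HC}'))" + cov,
        data=table).fit()
    reduced = smf.ols(f"brain_pad ~ cr(age, df={df})" + cov, data=table).fit()
    an = anova_lm(reduced, full)
    f_stat = float(an["F"].iloc[1])
    p_omni = float(an["Pr(>F)"].iloc[1])

    ages = np.linspace(table["age"].min(), table["age"].max(), n_grid)
    curves = []
    ref = {}
    for covname in ("sex", "scanner"):
        if covname in table.columns:
            ref[covname] = table[covname].mode().iloc[0]
    for g in sorted(set(table["group"])):
        newdata = pd.DataFrame({"age": ages, "group": g, **ref})
        pr = full.get_prediction(newdata).summary_frame(alpha=0.05)
        curves.append(pd.DataFrame({
            "group": g, "age": ages, "fit": pr["mean"].to_numpy(),
            "lo": pr["mean_ci_lower"].to_numpy(),
            "hi": pr["mean_ci_upper"].to_numpy()}))
    return ModelFitResult(
        name="spline", coef=_coef_frame(full),
        contrasts={"omnibus_group": {"F": f_stat, "p": p_omni}},
        n=int(full.nobs),
        extra={"curves": pd.concat(curves, ignore_index=True), "df": df,
               "results": full})


def loess_smooth(x, y, span: float = 0.75, eval_x=None) -> pd.DataFrame:
    """Tricube-weighted local linear smooth (visualization only).

    Plain LOESS (no robustness iterations) so the value at any point is
    exactly the tricube-weighted local least-squares fit there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if span * x.size < 2:
        raise ValueError(f"span {span} covers fewer than 2 points")
    if eval_x is None:
        eval_x = np.sort(x)
    eval_x = np.asarray(eval_x, dtype=float)
    fitted = lowess(y, x, frac=span, it=0, xvals=eval_x)
    return pd.DataFrame({"x": eval_x, "fit": fitted})


def quantile_fit(table: pd.DataFrame,
                 taus=(0.25, 0.5, 0.75)) -> dict[float, ModelFitResult]:
    """Quantile regression of brain_pad on the age x group design.

    Reports per-group age slopes (check-loss minimization) at each tau.
    """
    table = _check_table(table)
    if (table.groupby("group").size() < 20).any():
        raise ValueError("need n >= 20 per group for stable quantile estimates")
    mod = smf.quantreg(
        f"brain_pad ~ age * C(group, Treatment('{_HC}'))", data=table)
    out = {}
    for tau in taus:
        res = mod.fit(q=tau)
        contrasts = {}
        for g in sorted(set(table["group"])):
            term = "age" if g == _HC else (
                f"age + age:C(group, Treatment('{_HC}'))[T.{g}]")
            tt = res.t_test(term)
            contrasts[f"{g}_age_slope"] = {
                "estimate": _scalar(tt.effect), "se": _scalar(tt.sd),
                "p": _scalar(tt.pvalue)}
        out[tau] = ModelFitResult(name=f"quantile_{tau}", coef=_coef_frame(res),
                                  contrasts=contrasts, n=int(res.nobs))
    return out


# ---------------------------------------------------------------------------
# heterogeneity


def brown_forsythe(*groups) -> tuple[float, float]:
    """Brown-Forsythe equality-of-variance test.

    One-way ANOVA on absolute deviations from each group's median;
    W on (k-1, N-k) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    devs = [np.abs(a - np.median(a)) for a in arrays]
    w, p = stats.f_oneway(*devs)
    if np.isnan(w):  # all deviations identical -> no variance anywhere
        return 0.0, 1.0
    return float(w), float(p)


def dispersion_profile(table: pd.DataFrame, bin_width: float = 10.0,
                       min_n: int = 5) -> pd.DataFrame:
    """Per-group SD of age-detrended Brain-PAD residuals in age bins.

    Each group is linearly detrended on age first; bins with fewer than
    ``min_n`` subjects are flagged as suppressed.
    """
    table = _check_table(table)
    lo = np.floor(table["age"].min() / bin_width) * bin_width
    hi = table["age"].max()
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    for g, sub in table.groupby("group"):
        if len(sub) >= 3 and sub["age"].std() > 0:
            beta, alpha = np.polyfit(sub["age"], sub["brain_pad"], 1)
            resid = sub["brain_pad"] - (alpha + beta * sub["age"])
        else:
            resid = sub["brain_pad"] - sub["brain_pad"].mean()
        idx = np.clip(np.digitize(sub["age"], edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            r = resid[idx == b]
            rows.append({
                "group": g, "bin_lo": edges[b], "bin_hi": edges[b + 1],
                "n": int(r.size),
                "sd": float(r.std(ddof=1)) if r.size >= 2 else np.nan,
                "suppressed": bool(r.size < min_n)})
    return pd.DataFrame(rows)


def ribbon_summary(table: pd.DataFrame, bin_width: float = 5.0,
                   min_n: int = 5) -> pd.DataFrame:
    """Per-group median, IQR and 10-90% band of Brain-PAD in age bins."""
    table = _check_table(table)
    lo = np.floor(table["age"].min() / bin_width) * bin_width
    hi = table["age"].max()
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    for g, sub in table.groupby("group"):
        idx = np.clip(np.digitize(sub["age"], edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            v = sub["brain_pad"][idx == b].to_numpy()
            if v.size == 0:
                continue
            p10, q1, med, q3, p90 = np.percentile(v, [10, 25, 50, 75, 90])
            rows.append({
                "group": g, "bin_lo": edges[b], "bin_hi": edges[b + 1],
                "n": int(v.size), "p10": p10, "q1": q1, "median": med,
                "q3": q3, "p90": p90, "suppressed": bool(v.size < min_n)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity analyses


def ipw_weights(table: pd.DataFrame, bin_width: float = 5.0) -> np.ndarray:
    """Inverse-probability weights balancing each group's age distribution
    toward the pooled one (binned density ratio, normalized to mean 1)."""
    table = _check_table(table)
    ages = table["age"].to_numpy()
    lo = np.floor(ages.min() / bin_width) * bin_width
    edges = np.arange(lo, ages.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(ages, edges) - 1, 0, len(edges) - 2)
    n = len(table)
    pooled = np.bincount(idx, minlength=len(edges) - 1) / n
    w = np.empty(n)
    for g in set(table["group"]):
        sel = (table["group"] == g).to_numpy()
        gdens = np.bincount(idx[sel], minlength=len(edges) - 1) / sel.sum()
        ratio = np.where(gdens > 0, pooled / np.where(gdens > 0, gdens, 1.0), 0.0)
        w[sel] = ratio[idx[sel]]
    return w / w.mean()


def sensitivity_suite(table: pd.DataFrame, trim: tuple[float, float] = (20, 50),
                      ipw_bin: float = 5.0,
                      influence_threshold: float | None = None) -> dict:
    """Robustness battery around the interaction model.

    (a) age trimming to ``trim``; (b) inverse-probability-weighted refit;
    (c) leave-one-out influence on the age x group coefficients, flagging
    |delta beta| above ``influence_threshold`` (default 2/sqrt(n) of the
    coefficient SE, a DFBETA-style cut); (d) Huber M-estimation refit
    (tuning constant 1.345).
    """
    table = _check_table(table).reset_index(drop=True)
    base = fit_interaction(table)
    base_res = base.extra["results"]
    slope_terms = [t for t in base.coef.index if t.startswith("age:")]

    # (a) age trimming
    trimmed = table[(table["age"] >= trim[0]) & (table["age"] <= trim[1])]
    gone = set(table["group"]) - set(trimmed["group"])
    if gone:
        raise ValueError(f"trim window {trim} empties group(s): {sorted(gone)}")
    trim_fit = fit_interaction(trimmed)
    trim_shift = {t: float(trim_fit.coef.loc[t, "estimate"]
                           - base.coef.loc[t, "estimate"])
                  for t in slope_terms}

    # (b) inverse probability weighting
    w = ipw_weights(table, bin_width=ipw_bin)
    formula = (f"brain_pad ~ age * C(group, Treatment('{_HC}'))"
               + _covariate_terms(table))
    ipw_res = smf.wls(formula, data=table, weights=w).fit()
    ipw_coef = _coef_frame(ipw_res)

    # (c) leave-one-out influence on the interaction slopes
    n = len(table)
    base_beta = base.coef.loc[slope_terms, "estimate"].to_numpy()
    se = base.coef.loc[slope_terms, "se"].to_numpy()
    thresh = (influence_threshold if influence_threshold is not None
              else 2.0 / np.sqrt(n))
    deltas = np.empty((n, len(slope_terms)))
    for i in range(n):
        res_i = smf.ols(formula, data=table.drop(index=i)).fit()
        deltas[i] = [res_i.params.get(t, np.nan) for t in slope_terms] - base_beta
    flagged = np.where((np.abs(deltas) > thresh * se).any(axis=1))[0]
    loo = pd.DataFrame(deltas, columns=slope_terms)
    loo.insert(0, "id", table["id"].to_numpy())

    # (d) robust (Huber M-estimation) refit
    rlm_res = smf.rlm(formula, data=table,
                      M=sm.robust.norms.HuberT(t=1.345)).fit()
    robust_coef = pd.DataFrame({"estimate": rlm_res.params, "se": rlm_res.bse})

    return {
        "base": base,
        "trimmed": trim_fit,
        "trim_slope_shift": trim_shift,
        "ipw_weights": w,
        "ipw_coef": ipw_coef,
        "loo_delta": loo,
        "loo_flagged_ids": table.loc[flagged, "id"].tolist(),
        "robust_coef": robust_coef,
        "base_results": base_res,
    }
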