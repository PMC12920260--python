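"""Brain-PAD and model-performance metrics, with group comparisons.

Brain-PAD (brain-predicted age difference) is predicted age minus
chronological age; positive values indicate an older-appearing brain.
Group contrasts use one-way ANOVA with Tukey HSD adjusted pairwise
comparisons and pooled-SD Cohen's d effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

PREDICTIONS_COLUMNS = ["id", "group", "true_age", "predicted_age", "brain_pad",
                       "sex", "scanner"]


@dataclass
class GroupMetrics:
    """Per-group accuracy and Brain-PAD summary (one row of a Table-3 analogue)."""

    group: str
    n: int
    mae: float
    pearson_r: float
    r2: float
    r2_corr: float  # squared-correlation convention, reported alongside
    pad_mean: float
    pad_sd: float

    def to_dict(self) -> dict:
        return {"group": self.group, "n": self.n, "mae": self.mae,
                "pearson_r": self.pearson_r, "r2": self.r2,
                "r2_corr": self.r2_corr, "pad_mean": self.pad_mean,
                "pad_sd": self.pad_sd}


def brain_pad(predicted_age, true_age):
    """Signed brain-predicted age difference in years."""
    return np.asarray(predicted_age, dtype=float) - np.asarray(true_age, dtype=float)


def prediction_table(ids, groups, true_age, predicted_age, sex=None,
                     scanner=None) -> pd.DataFrame:
    """Assemble the canonical predictions table with a brain_pad column."""
    n = len(ids)
    df = pd.DataFrame({
        "id": list(ids), "group": list(groups),
        "true_age": np.asarray(true_age, dtype=float),
        "predicted_age": np.asarray(predicted_age, dtype=float),
        "sex": list(sex) if sex is not None else [""] * n,
        "scanner": list(scanner) if scanner is not None else [""] * n,
    })
    df["brain_pad"] = brain_pad(df["predicted_age"], df["true_age"])
    return df[PREDICTIONS_COLUMNS]


def performance_metrics(true_age, predicted_age, group: str = "") -> GroupMetrics:
    """MAE, Pearson r and R^2 of predictions against chronological age.

    R^2 is the coefficient of determination against the identity
    prediction, 1 - SS_res/SS_tot (not the squared correlation, which is
    also reported as ``r2_corr`` since the two conventions differ once
    predictions are biased).
    """
    t = np.asarray(true_age, dtype=float)
    p = np.asarray(predicted_age, dtype=float)
    if t.size < 2:
        raise ValueError("need n >= 2 for performance metrics")
    pad = p - t
    mae = float(np.abs(pad).mean())
    if np.allclose(t, t[0]):
        raise ValueError("true ages have zero variance; r undefined")
    r = float(stats.pearsonr(p, t)[0])
    ss_res = float(((t - p) ** 2).sum())
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return GroupMetrics(group=group, n=int(t.size), mae=mae, pearson_r=r,
                        r2=float(r2), r2_corr=float(r ** 2),
                        pad_mean=float(pad.mean()), pad_sd=float(pad.std(ddof=1)))


def cohens_d(stats1: tuple[float, float, int],
             stats2: tuple[float, float, int]) -> float:
    """Pooled-SD Cohen's d from (mean, sd, n) summaries, (n-1)-weighted."""
    m1, s1, n1 = stats1
    m2, s2, n2 = stats2
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    return float((m1 - m2) / pooled)


def cohens_d_from_samples(x1, x2) -> float:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return cohens_d((x1.mean(), x1.std(ddof=1), x1.size),
                    (x2.mean(), x2.std(ddof=1), x2.size))


def group_comparisons(pads_by_group: dict[str, np.ndarray],
                      alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey HSD adjusted pairwise contrasts.

    Returns one row per pair with the mean difference, Tukey-adjusted p,
    and pooled-SD Cohen's d.
    """
    groups = list(pads_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(pads_by_group[g], dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    f_stat, f_p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * a.size for g, a in zip(groups, arrays)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = list(combinations(tk.groupsunique, 2))
    rows = []
    for (g1, g2), diff, p_adj in zip(pairs, tk.meandiffs, tk.pvalues):
        d = cohens_d_from_samples(pads_by_group[g1], pads_by_group[g2])
        rows.append({"group1": g1, "group2": g2, "mean_diff": float(diff),
                     "p_tukey": float(p_adj), "cohens_d": d,
                     "anova_F": float(f_stat), "anova_p": float(f_p)})
    return pd.DataFrame(rows)
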