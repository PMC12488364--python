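"""Supporting statistics: group CI summaries, LS-means two-factor ANOVA,
likelihood-ratio logistic test, and rank-based ROC AUC.

The ANOVA mirrors the reported CPE analysis: an additive fixed-effects model
``response ~ group + treatment`` fit by least squares; the least-squares
(marginal) mean of a group averages the model prediction with equal weight
over the treatment levels; the group effect is tested by comparing to the
model without group (for an additive model this equals the type-III F test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .categorize import ci_bounds


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    def display(self, decimals: int = 2) -> str:
        return (f"{self.label}: {self.mean:.{decimals}f} ({self.sd:.{decimals}f}) "
                f"[{self.ci_low:.{decimals}f}-{self.ci_high:.{decimals}f}]")


def summarize_group(values: Sequence[float], ci_level: float = 0.95,
                    label: str = "") -> GroupSummary:
    """Mean, sample SD (n−1) and z-based CI of the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        low = high = mean
    else:
        low, high = ci_bounds(mean, sd, x.size, ci_level)
    return GroupSummary(label, int(x.size), mean, sd, low, high)


@dataclass(frozen=True)
class LsMeansResult:
    ls_means: dict[str, tuple[float, float]]  # group -> (LS mean, SE)
    f_stat: float
    df_num: int
    df_den: int
    p_value: float

    def difference(self, a: str, b: str) -> float:
        return self.ls_means[a][0] - self.ls_means[b][0]


def ls_means_anova(response: Sequence[float], group: Sequence[str],
                   treatment: Sequence[str]) -> LsMeansResult:
    """Additive two-factor ANOVA with LS means for the group factor."""
    y = np.asarray(response, dtype=float)
    g = pd.Categorical(group)
    t = pd.Categorical(treatment)
    if len(g.categories) < 2:
        raise ValueError("need at least 2 group levels")
    if len(t.categories) < 1:
        raise ValueError("need at least 1 treatment level")
    # empty group×treatment cells break the equal-weight LS mean
    cell = pd.crosstab(pd.Series(g), pd.Series(t))
    if (cell.values == 0).any():
        empty = [(str(r), str(c)) for r in cell.index for c in cell.columns
                 if cell.loc[r, c] == 0]
        raise ValueError(f"empty design cells for LS means: {empty}")

    g_dum = pd.get_dummies(pd.Series(g), drop_first=True, dtype=float).add_prefix("g:")
    t_dum = pd.get_dummies(pd.Series(t), drop_first=True, dtype=float).add_prefix("t:")
    X_full = pd.concat([g_dum, t_dum], axis=1)
    X_full.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X_full.to_numpy()) < X_full.shape[1]:
        raise ValueError("rank-deficient design: aliased group/treatment levels")
    full = sm.OLS(y, X_full.to_numpy()).fit()
    X_red = pd.concat([t_dum], axis=1)
    X_red.insert(0, "const", 1.0)
    reduced = sm.OLS(y, X_red.to_numpy()).fit()

    df_num = int(len(g.categories) - 1)
    df_den = int(full.df_resid)
    f_stat = float(((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den))
    p_value = float(sps.f.sf(f_stat, df_num, df_den))

    cols = list(X_full.columns)
    cov = full.cov_params()
    ls_means: dict[str, tuple[float, float]] = {}
    n_t = len(t.categories)
    for glev in g.categories:
        L = np.zeros(len(cols))
        L[cols.index("const")] = 1.0
        if f"g:{glev}" in cols:
            L[cols.index(f"g:{glev}")] = 1.0
        # equal weight 1/n_t on every treatment level
        for tlev in t.categories[1:]:
            L[cols.index(f"t:{tlev}")] = 1.0 / n_t
        est = float(L @ full.params)
        se = float(np.sqrt(L @ cov @ L))
        ls_means[str(glev)] = (est, se)
    return LsMeansResult(ls_means, f_stat, df_num, df_den, p_value)


@dataclass(frozen=True)
class LogisticTestResult:
    p_value: float
    lr_stat: float
    df: int
    separation: bool


def logistic_group_test(outcome: Sequence[str], predictor: Sequence[str],
                        positive: str = "PD") -> LogisticTestResult:
    """Likelihood-ratio test of a categorical predictor in a binary logistic
    model (vs intercept-only).

    Complete separation is flagged; the LRT statistic is still reported (the
    log-likelihood is then evaluated at the boundary fit).
    """
    y = np.asarray([1.0 if o == positive else 0.0 for o in outcome])
    p = pd.Categorical(predictor)
    if len(p.categories) < 2:
        raise ValueError("need at least 2 predictor levels")
    X = pd.get_dummies(pd.Series(p), drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    separation = False
    if y.min() == y.max():
        warnings.warn("degenerate outcome: all labels identical", stacklevel=2)
        return LogisticTestResult(1.0, 0.0, int(len(p.categories) - 1), True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, X.to_numpy()).fit(method="newton", tol=1e-10,
                                                 maxiter=100, disp=False)
            llf_full = full.llf
            fitted = full.predict()
            if np.any(fitted < 1e-8) or np.any(fitted > 1 - 1e-8):
                separation = True
        except Exception:
            separation = True
            full = sm.Logit(y, X.to_numpy()).fit(method="bfgs", maxiter=500,
                                                 disp=False)
            llf_full = full.llf
        null = sm.Logit(y, np.ones((len(y), 1))).fit(method="newton", tol=1e-10,
                                                     disp=False)
    lr = float(2.0 * (llf_full - null.llf))
    lr = max(lr, 0.0)
    df = int(len(p.categories) - 1)
    p_value = float(sps.chi2.sf(lr, df))
    if separation:
        warnings.warn("complete or quasi-complete separation detected; "
                      "LRT p-value reported from the boundary fit", stacklevel=2)
    return LogisticTestResult(p_value, lr, df, separation)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC via the rank (Mann-Whitney U) statistic; ties get half credit.

    Higher score = more likely positive.  AUC below 0.5 is reported as-is.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
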