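"""Group-level tests on subject-derived measures.

One-sided Wilcoxon signed-rank post hocs (exact null distribution for
small samples, zeros dropped), a 2x2 within-subject repeated-measures
ANOVA computed from per-subject contrasts, Bonferroni-Holm step-down
correction, and advisory normality / homogeneity diagnostics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class WilcoxonResult:
    statistic: float        # W = sum of positive-difference ranks
    p: float
    effect_size: float      # rank-biserial correlation
    n_used: int             # pairs remaining after zero removal
    method: str             # exact | approx
    alternative: str


def wilcoxon_signed_rank(a, b, alternative: str = "greater") -> WilcoxonResult:
    """One-sided (or two-sided) Wilcoxon signed-rank test on paired values.

    Zero differences are dropped before ranking (Wilcoxon's original
    rule).  The exact null distribution is used for up to 25 remaining
    pairs without ties; otherwise the normal approximation with
    continuity correction.  The effect size is the rank-biserial
    correlation (W+ - W-) / (W+ + W-).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        # every pair tied: no evidence in either direction
        return WilcoxonResult(np.nan, 1.0, 0.0, 0, "degenerate", alternative)
    if n < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative,
                         method=method, correction=(method == "approx"))
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    effect = (w_plus - w_minus) / (w_plus + w_minus)
    return WilcoxonResult(float(res.statistic), float(res.pvalue),
                          float(effect), n, method, alternative)


@dataclass
class RMAnovaResult:
    effects: pd.DataFrame   # effect, F, df1, df2, p, partial_eta_sq

    def p(self, effect: str) -> float:
        return float(self.effects.set_index("effect").loc[effect, "p"])

    def F(self, effect: str) -> float:
        return float(self.effects.set_index("effect").loc[effect, "F"])


def rm_anova_2x2(data: pd.DataFrame, dv: str, within: tuple[str, str],
                 subject: str = "subject_id") -> RMAnovaResult:
    """Two-way fully-within-subject ANOVA on a complete balanced 2x2 design.

    Computed via per-subject contrasts: for a 2x2 within design each
    effect's F(1, n-1) equals the squared one-sample t of the
    corresponding contrast, and partial eta squared is F / (F + df2).
    Degenerate zero-variance contrasts give F = 0, p = 1 (no evidence)
    when the contrast mean is also zero, and a machine-large F otherwise.
    """
    fa, fb = within
    wide = data.pivot_table(index=subject, columns=[fa, fb], values=dv)
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("design must be complete and balanced (2x2 per subject)")
    a_levels = sorted({c[0] for c in wide.columns})
    b_levels = sorted({c[1] for c in wide.columns})
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    y = {ab: wide[ab].to_numpy() for ab in wide.columns}
    n = wide.shape[0]
    c_a = (y[(a_levels[0], b_levels[0])] + y[(a_levels[0], b_levels[1])]
           - y[(a_levels[1], b_levels[0])] - y[(a_levels[1], b_levels[1])]) / 2
    c_b = (y[(a_levels[0], b_levels[0])] - y[(a_levels[0], b_levels[1])]
           + y[(a_levels[1], b_levels[0])] - y[(a_levels[1], b_levels[1])]) / 2
    c_i = (y[(a_levels[0], b_levels[0])] - y[(a_levels[0], b_levels[1])]
           - y[(a_levels[1], b_levels[0])] + y[(a_levels[1], b_levels[1])]) / 2
    rows = []
    for name, c in ((fa, c_a), (fb, c_b), (f"{fa} * {fb}", c_i)):
        m = c.mean()
        v = c.var(ddof=1)
        if v < np.finfo(float).tiny:
            F = 0.0 if abs(m) < 1e-12 else np.finfo(float).max
        else:
            F = n * m ** 2 / v
        p = float(stats.f.sf(F, 1, n - 1))
        rows.append({"effect": name, "F": float(F), "df1": 1, "df2": n - 1,
                     "p": p, "partial_eta_sq": float(F / (F + (n - 1)))})
    return RMAnovaResult(pd.DataFrame(rows))


def holm_correction(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def assumption_diagnostics(data: pd.DataFrame, dv: str, group: str) -> pd.DataFrame:
    """Advisory Shapiro-Wilk (per group) and Levene checks; never a gate."""
    rows = []
    groups = [g[dv].to_numpy() for _, g in data.groupby(group)]
    for (label, g) in zip(data[group].unique(), groups):
        w, p = stats.shapiro(g)
        rows.append({"test": "shapiro", "group": label, "statistic": w, "p": p})
    if len(groups) >= 2:
        w, p = stats.levene(*groups)
        rows.append({"test": "levene", "group": "all", "statistic": w, "p": p})
    return pd.DataFrame(rows)
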