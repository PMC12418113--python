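"""Circular descriptive statistics and hypothesis tests for phase angles.

All functions work in radians; degree conversion belongs at I/O
boundaries.  The Watson-Williams test is the circular analogue of a
one-factor ANOVA (equality of mean directions across groups, assuming
comparable, reasonably high concentration); the Harrison-Kanji test is
the two-factor analogue, with an F-statistic branch for concentrated
data and a chi-squared branch for diffuse data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .synthetic import wrap_angle


@dataclass
class CircularSummary:
    """Circular grand mean (CGM) and resultant vector length (RVL)."""
    cgm: float        # radians in (-pi, pi]; NaN when rvl == 0 or n == 0
    rvl: float        # in [0, 1]; NaN when n == 0
    n: int


@dataclass
class CircularTestResult:
    effects: pd.DataFrame       # columns: effect, statistic, stat_name, df1, df2, p
    warnings: list = field(default_factory=list)

    def p(self, effect: str) -> float:
        return float(self.effects.set_index("effect").loc[effect, "p"])


def circular_mean_rvl(angles: Sequence[float]) -> CircularSummary:
    """Mean direction and mean resultant length of a set of angles."""
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n == 0:
        raise ValueError("empty angle set")
    if n == 1:
        return CircularSummary(cgm=float(wrap_angle(angles[0])), rvl=1.0, n=1)
    z = np.exp(1j * angles).sum()
    rvl = float(np.abs(z) / n)
    cgm = float(wrap_angle(np.angle(z))) if rvl > 1e-12 else np.nan
    return CircularSummary(cgm=cgm, rvl=rvl, n=int(n))


def vonmises_rvl(kappa: float) -> float:
    """Population mean resultant length of a von Mises(mu, kappa): I1/I0."""
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def estimate_kappa(r: float, n: Optional[int] = None) -> float:
    """Maximum-likelihood-style concentration estimate from a mean resultant
    length (Fisher's approximation, with the small-sample correction when
    ``n`` is given)."""
    r = float(r)
    if r >= 1.0 - 1e-12:
        return 1e10
    if r < 0.53:
        kappa = 2 * r + r ** 3 + 5 * r ** 5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        kappa = 1 / (r ** 3 - 4 * r ** 2 + 3 * r)
    if n is not None and n < 15 and kappa < 2:
        kappa = max(kappa - 2 / (n * kappa), 0.0) if kappa > 0 else 0.0
    return float(kappa)


def watson_williams(groups: Sequence[Sequence[float]]) -> CircularTestResult:
    """One-factor circular ANOVA for equality of mean directions.

    Uses the standard concentration-corrected F statistic
    ``F = K * (N - k)(sum R_i - R) / ((k - 1)(N - sum R_i))`` with
    ``K = 1 + 3 / (8 kappa_hat)``.  A warning is attached when the pooled
    concentration estimate falls below 1, where the test's assumptions
    are doubtful.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    R_i = np.array([len(g) * circular_mean_rvl(g).rvl for g in groups])
    R = len(np.concatenate(groups)) * circular_mean_rvl(np.concatenate(groups)).rvl
    warns = []
    if np.any(R_i / ns < 1e-12):
        warns.append("a group has zero resultant length; assumptions violated")
    rw = float(R_i.sum() / n)
    kappa = estimate_kappa(rw, n)
    if kappa < 1:
        warns.append(f"pooled concentration estimate {kappa:.2f} < 1; "
                     "Watson-Williams assumptions doubtful")
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    num = (n - k) * (R_i.sum() - R)
    den = (k - 1) * (n - R_i.sum())
    F = correction * num / den if den > 0 else np.inf
    F = max(F, 0.0)
    p = float(stats.f.sf(F, k - 1, n - k))
    table = pd.DataFrame([{"effect": "group", "statistic": F, "stat_name": "F",
                           "df1": k - 1, "df2": n - k, "p": p}])
    return CircularTestResult(table, warns)


def harrison_kanji(angles: Sequence[float], factor_a: Sequence,
                   factor_b: Sequence) -> CircularTestResult:
    """Two-factor circular ANOVA (Harrison-Kanji) for mean directions.

    Decomposes the resultant-length sums over rows, columns and cells of
    the two-way layout.  For concentrated data (kappa_hat > 2) each
    effect is tested with a concentration-corrected F statistic against
    the residual term; for diffuse data a chi-squared approximation with
    scale ``2 / (1 - rho^2)`` is used, where ``rho`` is the population
    resultant length implied by kappa_hat.  Requires a fully crossed
    design with at least 2 observations per cell.
    """
    angles = np.asarray(angles, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(angles) == len(a) == len(b)):
        raise ValueError("angles and factor labels must have equal length")
    a_levels = np.unique(a)
    b_levels = np.unique(b)
    p_, q_ = len(a_levels), len(b_levels)
    if p_ < 2 or q_ < 2:
        raise ValueError("each factor needs at least 2 levels")
    n = len(angles)

    def _res(x):
        return len(x) * circular_mean_rvl(x).rvl if len(x) else 0.0

    cn = np.zeros((p_, q_))
    cr = np.zeros((p_, q_))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            cell = angles[(a == al) & (b == bl)]
            if len(cell) < 2:
                raise ValueError(f"cell ({al}, {bl}) has fewer than 2 observations")
            cn[i, j] = len(cell)
            cr[i, j] = _res(cell)
    pn = np.array([np.sum(a == al) for al in a_levels], dtype=float)
    pr = np.array([_res(angles[a == al]) for al in a_levels])
    qn = np.array([np.sum(b == bl) for bl in b_levels], dtype=float)
    qr = np.array([_res(angles[b == bl]) for bl in b_levels])
    tr = _res(angles)

    kappa = estimate_kappa(tr / n, n)
    df_a, df_b = p_ - 1, q_ - 1
    df_i = df_a * df_b
    df_r = n - p_ * q_

    ss_a = float(np.sum(pr ** 2 / pn) - tr ** 2 / n)
    ss_b = float(np.sum(qr ** 2 / qn) - tr ** 2 / n)
    ss_cells = float(np.sum(cr ** 2 / cn))
    ss_i = ss_cells - np.sum(pr ** 2 / pn) - np.sum(qr ** 2 / qn) + tr ** 2 / n
    ss_r = n - ss_cells
    warns = []

    rows = []
    if kappa > 2:
        correction = 1 + 3 / (8 * kappa)
        ms_r = ss_r / df_r
        for name, ss, df in (("factor_a", ss_a, df_a), ("factor_b", ss_b, df_b),
                             ("interaction", ss_i, df_i)):
            if ss <= 1e-10:            # degenerate: no effect variation at all
                F = 0.0
            elif ms_r > 0:
                F = max(correction * (ss / df) / ms_r, 0.0)
            else:
                F = np.inf
            rows.append({"effect": name, "statistic": F, "stat_name": "F",
                         "df1": df, "df2": df_r, "p": float(stats.f.sf(F, df, df_r))})
    else:
        warns.append(f"low concentration (kappa_hat = {kappa:.2f}); "
                     "chi-squared approximation used")
        rho = vonmises_rvl(kappa)
        scale = 2.0 / (1.0 - rho ** 2)
        # each resultant carries two components (cos, sin), so the
        # chi-squared reference has twice the nominal df
        for name, ss, df in (("factor_a", ss_a, df_a), ("factor_b", ss_b, df_b),
                             ("interaction", ss_i, df_i)):
            chi = max(scale * ss, 0.0)
            rows.append({"effect": name, "statistic": chi, "stat_name": "chi2",
                         "df1": 2 * df, "df2": np.nan,
                         "p": float(stats.chi2.sf(chi, 2 * df))})
    return CircularTestResult(pd.DataFrame(rows), warns)
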