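"""Canonical-HRF designs, LSS beta-series estimation, and the
band-power -> BOLD random-intercept mixed model.

The single-trial coupling model is

    y_ij = beta0 + S0_i + sum_k beta_k * P_ijk + eps_ij

where y_ij is the trial-j BOLD beta of subject i in one region, P_ijk is
subject i's trial-j power in band k (mean-centred within subject), S0_i
is a subject random intercept, and the fixed weights beta_k are reported
as standardized coefficients with FDR-corrected p-values within each
model.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import (
    compute_regressor, spm_hrf, spm_time_derivative)
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_BANDS, band_label

BAND_ORDER = tuple(band_label(b) for b in DEFAULT_BANDS)


def canonical_hrf(tr: float, duration: float = 32.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Double-gamma canonical HRF and its temporal derivative on the TR grid.

    The kernel peaks near 5 s with a negative undershoot around 15 s and
    32 s of support.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    hrf = spm_hrf(tr, oversampling=1, time_length=duration)
    dhrf = spm_time_derivative(tr, oversampling=1, time_length=duration)
    return np.asarray(hrf), np.asarray(dhrf)


def cosine_drift_basis(n_scans: int, tr: float, cutoff: float = 128.0
                       ) -> np.ndarray:
    """Discrete-cosine high-pass drift regressors with a period cutoff (s).

    Returns an [n_scans, k] matrix (possibly empty) of unit-norm cosines
    with periods longer than ``cutoff`` excluded from the residual space.
    """
    duration = n_scans * tr
    order = int(np.floor(2 * duration / cutoff))
    t = np.arange(n_scans)
    basis = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * t + 1) * k / (2 * n_scans))
             for k in range(1, order + 1)]
    return np.column_stack(basis) if basis else np.empty((n_scans, 0))


def _event_regressor(onset: float, duration: float, amplitude: float,
                     frame_times: np.ndarray, derivative: bool) -> np.ndarray:
    cond = np.array([[onset], [duration], [amplitude]])
    model = "spm + derivative" if derivative else "spm"
    reg, _ = compute_regressor(cond, model, frame_times)
    return reg


def sample_bold_timeseries(onsets: np.ndarray, durations: np.ndarray,
                           amplitudes: np.ndarray, tr: float,
                           n_scans: Optional[int] = None) -> np.ndarray:
    """Noise-free BOLD series: amplitude-modulated events * canonical HRF."""
    onsets = np.asarray(onsets, float)
    if n_scans is None:
        n_scans = int(np.ceil((onsets.max() + durations[-1] + 32.0) / tr))
    frame_times = np.arange(n_scans) * tr
    cond = np.vstack([onsets, np.asarray(durations, float),
                      np.asarray(amplitudes, float)])
    reg, _ = compute_regressor(cond, "spm", frame_times)
    return reg[:, 0]


@dataclass
class BetaSeries:
    """Single-trial BOLD amplitude estimates with trial metadata."""
    table: pd.DataFrame        # subject_id, region_id, trial_id, beta
    standardized: bool = False

    def __post_init__(self):
        dup = self.table.duplicated(["subject_id", "region_id", "trial_id"])
        if dup.any():
            raise ValueError("one row per (subject, region, trial) required")


def estimate_lss_beta_series(bold: np.ndarray, events: pd.DataFrame, tr: float,
                             subject_id=0, region_id: str = "ROI",
                             include_derivative: bool = True,
                             highpass_cutoff: Optional[float] = 128.0
                             ) -> BetaSeries:
    """Least-squares-separate single-trial betas from one BOLD time series.

    For each trial a separate GLM is fit with one HRF-convolved regressor
    for that trial, one for the combination of all other trials, plus
    (optionally) their temporal derivatives, discrete-cosine drift terms
    with a 128 s cutoff, and an intercept.  The trial's own beta enters
    the series.  Rank-deficient trial designs yield NaN with a flag
    rather than an arbitrary solution.
    """
    bold = np.asarray(bold, float)
    if len(events) < 2:
        raise ValueError("LSS requires at least 2 events")
    n_scans = len(bold)
    frame_times = np.arange(n_scans) * tr
    if events["onset"].max() > frame_times[-1]:
        raise ValueError("scan duration does not cover all events")

    own = []
    for _, ev in events.iterrows():
        own.append(_event_regressor(ev["onset"], ev["duration"], 1.0,
                                    frame_times, include_derivative))
    own = np.stack(own)                       # [trial, scan, 1 or 2]
    total = own.sum(axis=0)                   # convolution is linear
    drift = cosine_drift_basis(n_scans, tr, highpass_cutoff) \
        if highpass_cutoff else np.empty((n_scans, 0))
    const = np.ones((n_scans, 1))

    rows = []
    for k, (_, ev) in enumerate(events.iterrows()):
        others = total - own[k]
        X = np.hstack([own[k], others, drift, const])
        flagged = np.linalg.matrix_rank(X) < X.shape[1]
        if flagged:
            beta = np.nan
        else:
            coef, *_ = np.linalg.lstsq(X, bold, rcond=None)
            beta = float(coef[0])
        rows.append({"subject_id": subject_id, "region_id": region_id,
                     "trial_id": ev["trial_id"], "beta": beta,
                     "flagged": flagged})
    return BetaSeries(pd.DataFrame(rows))


def estimate_lsa_beta_series(bold: np.ndarray, events: pd.DataFrame, tr: float,
                             subject_id=0, region_id: str = "ROI",
                             include_derivative: bool = True,
                             highpass_cutoff: Optional[float] = 128.0
                             ) -> BetaSeries:
    """Least-squares-all reference: one GLM with every trial as its own
    regressor.  Used as the comparison estimator that LSS improves on at
    short inter-stimulus intervals."""
    bold = np.asarray(bold, float)
    n_scans = len(bold)
    frame_times = np.arange(n_scans) * tr
    own = [_event_regressor(ev["onset"], ev["duration"], 1.0, frame_times,
                            include_derivative)
           for _, ev in events.iterrows()]
    drift = cosine_drift_basis(n_scans, tr, highpass_cutoff) \
        if highpass_cutoff else np.empty((n_scans, 0))
    X = np.hstack([np.hstack(own), drift, np.ones((n_scans, 1))])
    coef, *_ = np.linalg.lstsq(X, bold, rcond=None)
    step = own[0].shape[1]
    betas = coef[0:len(own) * step:step]
    rows = [{"subject_id": subject_id, "region_id": region_id,
             "trial_id": ev["trial_id"], "beta": float(b), "flagged": False}
            for (_, ev), b in zip(events.iterrows(), betas)]
    return BetaSeries(pd.DataFrame(rows))


def build_band_regressors(band_powers: pd.DataFrame,
                          bands: Sequence[str] = BAND_ORDER) -> pd.DataFrame:
    """Mean-centre the per-trial band-power regressors within subject.

    Column order is fixed (delta first, then the four 2-Hz theta/alpha
    sub-bands).  Constant columns are centred to all-zero and flagged via
    the ``degenerate_bands`` attribute on the returned frame.
    """
    missing = [b for b in bands if b not in band_powers.columns]
    if missing:
        raise ValueError(f"missing band column(s): {missing}")
    meta = [c for c in band_powers.columns if c not in bands]
    out = band_powers[meta + list(bands)].copy()
    degenerate = []
    for b in bands:
        out[b] = out.groupby("subject_id")[b].transform(lambda x: x - x.mean())
        if np.allclose(out[b].to_numpy(), 0.0):
            degenerate.append(b)
    out.attrs["degenerate_bands"] = degenerate
    return out


@dataclass
class LMEFit:
    """Fixed-effect table and variance components of one coupling model."""
    table: pd.DataFrame      # regressor, beta (std), beta_raw, se, t, p, p_fdr, ci
    intercept: float
    random_intercept_var: float
    n_subjects: int
    n_obs: int
    converged: bool
    fit_method: str = "ml"
    region_id: Optional[str] = None
    condition: Optional[str] = None


def fit_random_intercept_lme(betas, regressors: pd.DataFrame,
                             bands: Sequence[str] = BAND_ORDER,
                             region_id: Optional[str] = None,
                             condition: Optional[str] = None,
                             force_zero_random_effects: bool = False) -> LMEFit:
    """Fit the band-power -> single-trial-BOLD random-intercept model.

    Estimation is by maximum likelihood.  Each band's fixed effect is
    reported as a standardized beta (raw coefficient scaled by the grand
    SDs of predictor and outcome), a t statistic (coefficient / SE) with
    a residual-degrees-of-freedom t reference, and Benjamini-Hochberg
    adjusted p-values across the bands of this one model.
    """
    table = betas.table if isinstance(betas, BetaSeries) else betas
    merged = table.merge(regressors, on=["subject_id", "trial_id"],
                         suffixes=("", "_reg"))
    merged = merged.dropna(subset=["beta", *bands])
    n_subj = merged["subject_id"].nunique()
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    if (merged.groupby("subject_id").size() < 10).any():
        raise ValueError("need at least 10 trials per subject")
    y = merged["beta"].to_numpy(float)
    sd_y = y.std(ddof=1)
    sd_x = np.array([max(merged[b].std(ddof=1), np.finfo(float).tiny)
                     for b in bands])
    # fit on grand-standardized variables for numerical stability; the
    # fixed-effect estimates on this scale ARE the standardized betas
    ys = (y - y.mean()) / sd_y
    Xs = np.column_stack(
        [np.ones(len(merged))]
        + [(merged[b].to_numpy(float) - merged[b].mean()) / s
           for b, s in zip(bands, sd_x)])
    groups = merged["subject_id"].to_numpy()
    import warnings as _w
    converged, method = True, "ml"
    try:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            if force_zero_random_effects:
                # variance component pinned at zero: the mixed model
                # degenerates to pooled OLS (used as an oracle check)
                from statsmodels.regression.mixed_linear_model import \
                    MixedLMParams
                free = MixedLMParams.from_components(
                    fe_params=np.ones(Xs.shape[1]), cov_re=np.zeros((1, 1)))
                start = MixedLMParams.from_components(
                    fe_params=np.zeros(Xs.shape[1]), cov_re=np.zeros((1, 1)))
                fit = MixedLM(ys, Xs, groups=groups).fit(
                    reml=False, free=free, start_params=start,
                    method="powell")
            else:
                fit = MixedLM(ys, Xs, groups=groups).fit(reml=False,
                                                         method="lbfgs")
                # lbfgs mis-profiles the fixed effects when the variance
                # estimate hits the zero boundary; powell is reliable there
                if float(np.asarray(fit.cov_re)[0, 0]) < 1e-6 \
                        or not getattr(fit, "converged", True):
                    fit = MixedLM(ys, Xs, groups=groups).fit(reml=False,
                                                             method="powell")
        fe = np.asarray(fit.fe_params, float)
        se_s = np.asarray(fit.bse_fe, float)
        re_var = float(np.asarray(fit.cov_re)[0, 0]) * sd_y ** 2
        converged = bool(getattr(fit, "converged", True)) \
            and np.all(np.isfinite(se_s))
    except (np.linalg.LinAlgError, ValueError):
        converged = False
    if not converged:
        # degenerate variance structure (e.g. noise-free input): report a
        # pooled OLS solution, flagged as a fallback
        method = "ols_fallback"
        fe, res, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        dof = max(len(ys) - Xs.shape[1], 1)
        sigma2 = float(res[0]) / dof if len(res) else \
            float(np.sum((ys - Xs @ fe) ** 2)) / dof
        cov = sigma2 * np.linalg.pinv(Xs.T @ Xs)
        se_s = np.sqrt(np.maximum(np.diag(cov), 0.0))
        re_var = np.nan

    df_resid = len(merged) - Xs.shape[1]
    rows = []
    for j, b in enumerate(bands, start=1):
        b_std = float(fe[j])
        se = float(se_s[j])
        coef = b_std * sd_y / sd_x[j - 1]
        t = b_std / se if se > 0 else np.inf * np.sign(b_std)
        p = 2 * stats.t.sf(abs(t), df_resid) if np.isfinite(t) else 0.0
        ci_half = stats.t.ppf(0.975, df_resid) * se
        rows.append({"regressor": b, "beta": b_std, "beta_raw": coef,
                     "se": se * sd_y / sd_x[j - 1],
                     "t": t, "p": p, "ci_low": b_std - ci_half,
                     "ci_high": b_std + ci_half})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_correct(out["p"].to_numpy())
    intercept = float(fe[0]) * sd_y + y.mean()
    return LMEFit(table=out, intercept=intercept,
                  random_intercept_var=re_var,
                  n_subjects=n_subj, n_obs=len(merged), converged=converged,
                  fit_method=method, region_id=region_id, condition=condition)


def fit_pooled_ols(betas, regressors: pd.DataFrame,
                   bands: Sequence[str] = BAND_ORDER) -> pd.DataFrame:
    """Pooled OLS reference fit (no random intercept); oracle for the
    zero-between-subject-variance limit of the mixed model."""
    table = betas.table if isinstance(betas, BetaSeries) else betas
    merged = table.merge(regressors, on=["subject_id", "trial_id"],
                         suffixes=("", "_reg"))
    y = merged["beta"].to_numpy(float)
    X = np.column_stack([np.ones(len(merged))]
                        + [merged[b].to_numpy(float) for b in bands])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.DataFrame({"regressor": bands, "beta_raw": coef[1:]})


def fdr_correct(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
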