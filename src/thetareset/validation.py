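"""Operating-characteristic experiments for the full pipeline.

Each function runs a self-contained simulation experiment against the
synthetic generator (or directly against a statistical routine) and
returns the measured quantities: null calibrations, detection rates,
parameter-recovery errors, and oracle-equivalence residuals.  They are
used both by the test suite and by the results-reproduction script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig, band_label, DEFAULT_BANDS
from .circstats import (circular_mean_rvl, harrison_kanji, vonmises_rvl,
                        watson_williams)
from .fmri import (build_band_regressors, estimate_lsa_beta_series,
                   estimate_lss_beta_series, fdr_correct, fit_pooled_ols,
                   fit_random_intercept_lme, sample_bold_timeseries)
from .groupstats import holm_correction, wilcoxon_signed_rank
from .phase import assess_partial_reset_from_spec, compute_itc, itc_from_phases
from .synthetic import simulate_band_power_table, simulate_coupled_bold, \
    simulate_epoch_set
from .timefreq import (BaselineSpec, baseline_normalize,
                       decompose_evoked_induced, find_peak,
                       find_subject_peak_frequency, morlet_transform)

BANDS = [band_label(b) for b in DEFAULT_BANDS]


# ---------------------------------------------------------------- ITC / RVL
def itc_null_mean(rng: np.random.Generator, n_trials: int = 100,
                  reps: int = 10_000) -> float:
    """Mean ITC of ``n_trials`` independent uniform phases over many draws.

    The expectation for uniform phases is sqrt(pi)/(2 sqrt(N)) (Rayleigh).
    """
    phases = rng.uniform(-np.pi, np.pi, size=(reps, n_trials))
    return float(itc_from_phases(phases, axis=1).mean())


def vonmises_rvl_errors(rng: np.random.Generator,
                        kappas=(1.0, 2.0, 4.0), n: int = 10_000) -> dict:
    """|empirical RVL - I1(k)/I0(k)| for von Mises samples at several kappas."""
    out = {}
    for k in kappas:
        draws = rng.vonmises(0.0, k, n)
        out[k] = {"rvl": circular_mean_rvl(draws).rvl,
                  "expected": vonmises_rvl(k),
                  "abs_error": abs(circular_mean_rvl(draws).rvl
                                   - vonmises_rvl(k))}
    return out


# ------------------------------------------------------- reset detection
def _detection_config(mechanism: str, seed: int,
                      n_trials: int) -> SimulationConfig:
    return SimulationConfig(
        n_subjects=1, n_trials_per_condition=n_trials // 2,
        include_nomaze=False, mechanism=mechanism, seed=seed,
        reset_concentration=4.0,
        amplitude_gain_by_condition={"left": 1.5, "right": 1.5})


def _analysis_spec(epochs, n_cycles: float = 3.0):
    return morlet_transform(epochs, "right_posterior",
                            freqs=np.arange(7.0, 11.0), n_cycles=n_cycles)


def reset_detection_rates(rng: np.random.Generator, n_runs: int = 200,
                          n_trials: int = 200) -> dict:
    """False-positive and true-positive rates of the partial-reset verdict.

    Null runs use the no-event-locked-change mechanism; signal runs use a
    phase reset with kappa = 4 and a transient amplitude gain of 1.5.
    """
    counts = {"none": 0, "reset": 0}
    seeds = rng.integers(0, 2 ** 31 - 1, size=(n_runs, 2))
    for i in range(n_runs):
        for j, mech in enumerate(("none", "reset")):
            cfg = _detection_config(mech, int(seeds[i, j]), n_trials)
            spec = _analysis_spec(simulate_epoch_set(cfg))
            verdict = assess_partial_reset_from_spec(spec).verdict
            counts[mech] += verdict == "partial_reset"
    return {"false_positive_rate": counts["none"] / n_runs,
            "sensitivity": counts["reset"] / n_runs}


# ------------------------------------------------------- latency recovery
def latency_recovery(rng: np.random.Generator, offset_ms: float = 16.0,
                     n_runs: int = 16, n_trials_per_condition: int = 200
                     ) -> dict:
    """Recover a configured left-right reset-latency offset.

    Amplitude gains are equalised across alleys so the experiment isolates
    the latency manipulation.  For each of ``n_runs`` independent
    subject-runs the left-right difference in evoked-power peak latency
    (7-cycle analysis, at the subject's raw-power peak frequency) and in
    ITC peak latency (3-cycle analysis, 7-8 Hz) is measured; the means
    across runs are returned in ms.
    """
    base = 188.0
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_runs)
    pow_diffs, itc_diffs = [], []
    for s in seeds:
        cfg = SimulationConfig(
            n_subjects=1, n_trials_per_condition=n_trials_per_condition,
            include_nomaze=False, seed=int(s),
            reset_latency_by_condition={"left": base + offset_ms / 2,
                                        "right": base - offset_ms / 2},
            amplitude_gain_by_condition={"left": 1.5, "right": 1.5})
        epochs = simulate_epoch_set(cfg)
        spec7 = morlet_transform(epochs, "right_posterior",
                                 freqs=np.arange(4.0, 13.0))
        spec3 = morlet_transform(epochs, "right_posterior",
                                 freqs=np.array([7.0, 8.0]), n_cycles=3)
        f_peak = find_subject_peak_frequency(spec7)
        lat = {}
        for alley in ("left", "right"):
            mask = (epochs.events["alley"] == alley).to_numpy()
            sub7 = spec7.select(mask)
            sub7 = decompose_evoked_induced(sub7, epochs.select(mask),
                                            "right_posterior")
            norm = baseline_normalize(sub7.power_evoked, BaselineSpec(),
                                      sub7.time_axis)
            peak = find_peak(norm, sub7.freqs, sub7.time_axis,
                             (f_peak, f_peak), (0, 600))
            itc = compute_itc(spec3.select(mask), (7, 8), (0, 600))
            lat[alley] = (peak.peak_latency, itc.peak_latency)
        pow_diffs.append(lat["left"][0] - lat["right"][0])
        itc_diffs.append(lat["left"][1] - lat["right"][1])
    return {"configured_offset_ms": offset_ms,
            "power_latency_diff_ms": float(np.mean(pow_diffs)),
            "itc_latency_diff_ms": float(np.mean(itc_diffs))}


# -------------------------------------------------- evoked/induced limits
def evoked_induced_limits(rng: np.random.Generator, n_random: int = 2000
                          ) -> dict:
    """Identity and limiting-case behaviour of the power decomposition."""
    from .synthetic import EpochSet
    fs, f0 = 250.0, 8.0
    t = np.arange(-256, 256) / fs * 1000.0
    ts = t / 1000.0
    events = lambda n: pd.DataFrame({"trial_id": np.arange(n)})

    def transform(data):
        eps = EpochSet(data[:, None, :], t, fs, events(len(data)),
                       ("ch",), None)
        spec = morlet_transform(eps, 0, freqs=np.array([f0]),
                                trim=(-500, 500))
        return decompose_evoked_induced(spec, eps, 0), eps

    # fully phase-locked: identical trials
    locked = np.tile(np.cos(2 * np.pi * f0 * ts), (50, 1))
    spec_l, _ = transform(locked)
    locked_induced_ratio = float(np.max(np.abs(spec_l.power_induced))
                                 / np.max(spec_l.power_total))
    # fully random phases
    phis = rng.uniform(-np.pi, np.pi, n_random)
    rand = np.cos(2 * np.pi * f0 * ts[None, :] + phis[:, None])
    spec_r, _ = transform(rand)
    mid = len(spec_r.time_axis) // 2
    random_evoked_ratio = float(spec_r.power_evoked[0, mid]
                                / spec_r.power_total[0, mid])
    identity_residual = float(np.max(np.abs(
        spec_r.power_total - spec_r.power_evoked - spec_r.power_induced)))
    return {"identity_residual": identity_residual,
            "locked_induced_ratio": locked_induced_ratio,
            "random_evoked_ratio": random_evoked_ratio,
            "n_random": n_random}


# ----------------------------------------------------------- LSS recovery
def lss_recovery(rng: np.random.Generator, n_reps: int = 100,
                 n_trials: int = 96, tr: float = 2.0) -> dict:
    """Single-trial amplitude recovery by LSS vs LSA at short ISIs.

    Trial amplitudes are standard normal (beta-scale); noise is white
    with SD equal to the SD of the clean task series (series-level
    SNR 1).  Also checks exact recovery for isolated events.
    """
    # exact recovery, isolated events
    onsets = 15.0 + 40.0 * np.arange(6)
    amps = np.array([1.0, -0.5, 2.0, 0.3, -1.2, 0.8])
    clean = sample_bold_timeseries(onsets, np.ones(6), amps, tr)
    ev = pd.DataFrame({"onset": onsets, "duration": np.ones(6),
                       "trial_id": np.arange(6)})
    # orthogonal design: no drift terms, so trial regressors are mutually
    # orthogonal and recovery is exact
    bs = estimate_lss_beta_series(clean, ev, tr, highpass_cutoff=None)
    exact_err = float(np.max(np.abs(bs.table["beta"].to_numpy() - amps)))

    r_lss, r_lsa = [], []
    for _ in range(n_reps):
        amps = rng.standard_normal(n_trials)
        isis = rng.uniform(3.0, 5.0, n_trials)
        onsets = 10.0 + np.concatenate([[0.0], np.cumsum(isis[:-1])])
        clean = sample_bold_timeseries(onsets, np.ones(n_trials), amps, tr)
        bold = clean + rng.standard_normal(len(clean)) * clean.std()
        ev = pd.DataFrame({"onset": onsets, "duration": np.ones(n_trials),
                           "trial_id": np.arange(n_trials)})
        est_lss = estimate_lss_beta_series(bold, ev, tr,
                                           include_derivative=False)
        est_lsa = estimate_lsa_beta_series(bold, ev, tr,
                                           include_derivative=False)
        r_lss.append(stats.pearsonr(amps, est_lss.table["beta"])[0])
        r_lsa.append(stats.pearsonr(amps, est_lsa.table["beta"])[0])
    return {"exact_recovery_error": exact_err,
            "r_lss": float(np.mean(r_lss)),
            "r_lsa": float(np.mean(r_lsa)),
            "n_reps": n_reps}


# ----------------------------------------------------------- LME recovery
def lme_recovery(rng: np.random.Generator, n_reps: int = 200,
                 n_subjects: int = 25, trials_per_cell: int = 48) -> dict:
    """Coupling-weight recovery and condition specificity of the LME.

    Simulation truth: standardized 7-8 Hz weight +0.148 and 5-6 Hz weight
    -0.097 in the spatial condition, all-zero coupling in the control
    condition.  Reports sign-recovery rates, mean absolute estimation
    error over the two non-zero weights, and the rate at which the
    control-condition model shows any FDR-significant band.
    """
    sign78 = sign56 = nomaze_fp = 0
    errs, est78, est56 = [], [], []
    seeds = rng.integers(0, 2 ** 31 - 1, size=(n_reps, 2))
    truth = {"7-8": 0.148, "5-6": -0.097}
    for i in range(n_reps):
        cfg = SimulationConfig(n_subjects=n_subjects,
                               n_trials_per_condition=trials_per_cell,
                               seed=int(seeds[i, 0]))
        bp = simulate_band_power_table(
            cfg, np.random.default_rng(int(seeds[i, 0])))
        ds = simulate_coupled_bold(
            bp[["trial_id", "subject_id", "condition", "alley"]], cfg, bp,
            rng=np.random.default_rng(int(seeds[i, 1])))
        regs = build_band_regressors(bp, BANDS)
        for cond in ("maze", "nomaze"):
            tb = ds.true_betas[ds.true_betas["condition"] == cond]
            fit = fit_random_intercept_lme(tb, regs, BANDS, condition=cond)
            tab = fit.table.set_index("regressor")
            if cond == "maze":
                b78, b56 = tab.loc["7-8", "beta"], tab.loc["5-6", "beta"]
                sign78 += b78 > 0
                sign56 += b56 < 0
                est78.append(b78)
                est56.append(b56)
                errs.extend([abs(b78 - truth["7-8"]),
                             abs(b56 - truth["5-6"])])
            else:
                nomaze_fp += bool((tab["p_fdr"] < 0.05).any())
    return {"sign_recovery_78": sign78 / n_reps,
            "sign_recovery_56": sign56 / n_reps,
            "mean_abs_error": float(np.mean(errs)),
            "mean_beta_78": float(np.mean(est78)),
            "mean_beta_56": float(np.mean(est56)),
            "nomaze_fp_rate": nomaze_fp / n_reps,
            "n_reps": n_reps}


def lme_null_calibration(rng: np.random.Generator, n_reps: int = 200,
                         n_subjects: int = 25, trials_per_cell: int = 48
                         ) -> float:
    """Per-regressor raw-p rejection rate at alpha = .05 under zero coupling."""
    rejections = total = 0
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_reps)
    weights = {b: 0.0 for b in BANDS}
    for s in seeds:
        cfg = SimulationConfig(n_subjects=n_subjects,
                               n_trials_per_condition=trials_per_cell,
                               include_nomaze=False, seed=int(s),
                               coupling_weights=weights)
        bp = simulate_band_power_table(cfg, np.random.default_rng(int(s)))
        ds = simulate_coupled_bold(
            bp[["trial_id", "subject_id", "condition", "alley"]], cfg, bp,
            rng=np.random.default_rng(int(s) + 1))
        regs = build_band_regressors(bp, BANDS)
        fit = fit_random_intercept_lme(ds.true_betas, regs, BANDS)
        rejections += int((fit.table["p"] < 0.05).sum())
        total += len(fit.table)
    return rejections / total


# -------------------------------------------------- test calibration
def circular_test_calibration(rng: np.random.Generator,
                              n_reps: int = 2000) -> dict:
    """Type-I error of Watson-Williams and Harrison-Kanji at alpha = .05."""
    ww_rej = 0
    hk_rej = np.zeros(3)
    for _ in range(n_reps):
        g1 = rng.vonmises(0.0, 4.0, 50)
        g2 = rng.vonmises(0.0, 4.0, 50)
        ww_rej += watson_williams([g1, g2]).p("group") < 0.05
        ang = rng.vonmises(0.0, 4.0, 40)
        a = np.repeat([0, 1], 20)
        b = np.tile(np.repeat([0, 1], 10), 2)
        res = harrison_kanji(ang, a, b)
        hk_rej += (res.effects["p"].to_numpy() < 0.05)
    return {"watson_williams_type1": ww_rej / n_reps,
            "harrison_kanji_type1_a": float(hk_rej[0]) / n_reps,
            "harrison_kanji_type1_b": float(hk_rej[1]) / n_reps,
            "harrison_kanji_type1_interaction": float(hk_rej[2]) / n_reps}


def bh_fdr_empirical(rng: np.random.Generator, n_reps: int = 1000,
                     m: int = 20) -> float:
    """Empirical FDR of Benjamini-Hochberg on a 50% null / 50% alt mixture."""
    fdps = []
    m_null = m // 2
    for _ in range(n_reps):
        p_null = rng.uniform(size=m_null)
        p_alt = rng.beta(0.05, 1.0, size=m - m_null)
        p = np.concatenate([p_null, p_alt])
        is_null = np.arange(m) < m_null
        rejected = fdr_correct(p) < 0.05
        n_rej = rejected.sum()
        fdps.append((rejected & is_null).sum() / n_rej if n_rej else 0.0)
    return float(np.mean(fdps))


def wilcoxon_exact_vs_enumeration(rng: np.random.Generator,
                                  n_sets: int = 20) -> float:
    """Max |p_exact - p_enumeration| for small samples without ties."""
    worst = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(5, 11))
        d = rng.standard_normal(n) + 0.5
        while len(np.unique(np.abs(d))) < n or np.any(d == 0):
            d = rng.standard_normal(n) + 0.5
        res = wilcoxon_signed_rank(d, np.zeros(n), alternative="greater")
        worst = max(worst, abs(res.p - _enumerated_p_greater(d)))
    return worst


def _enumerated_p_greater(d: np.ndarray) -> float:
    """Exact one-sided Wilcoxon p by enumeration of all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for bits in range(2 ** n):
        signs = np.array([(bits >> k) & 1 for k in range(n)], dtype=bool)
        if ranks[signs].sum() >= w_obs:
            count += 1
    return count / 2 ** n


def correction_worked_examples() -> dict:
    """Hand-computed Holm / Benjamini-Hochberg step examples."""
    return {
        "bh_uniform_ladder": fdr_correct([0.01, 0.02, 0.03, 0.04, 0.05]).tolist(),
        "bh_two": fdr_correct([0.001, 0.9]).tolist(),
        "holm_two": holm_correction([0.01, 0.04]).tolist(),
        "holm_ties": holm_correction([0.03, 0.03, 0.03]).tolist(),
    }


# -------------------------------------------------- oracle equivalences
def morlet_oracle_error(rng: np.random.Generator) -> float:
    """Max relative deviation of the FFT-convolution Morlet transform from
    a brute-force direct time-domain convolution on a small fixture."""
    from .synthetic import EpochSet
    from .timefreq import morlet_wavelet
    fs = 256.0
    n = 512
    t = (np.arange(n) - n // 2) / fs * 1000.0
    data = rng.standard_normal((3, 1, n))
    eps = EpochSet(data, t, fs, pd.DataFrame({"trial_id": range(3)}),
                   ("ch",), None)
    freqs = np.array([5.0, 10.0, 20.0])
    spec = morlet_transform(eps, 0, freqs, trim=(t[0], t[-1]))
    worst = 0.0
    for i, f in enumerate(freqs):
        kernel = morlet_wavelet(f, fs)
        for tr_i in range(3):
            full = np.convolve(data[tr_i, 0], kernel, mode="full")
            start = (len(kernel) - 1) // 2
            direct = full[start:start + n]
            num = np.max(np.abs(spec.complex_coeffs[tr_i, i] - direct))
            worst = max(worst, num / np.max(np.abs(direct)))
    return worst


def circular_trig_error(rng: np.random.Generator) -> float:
    """Max deviation of CGM/RVL from the direct trigonometric-sum formulas
    on small integer-degree inputs."""
    worst = 0.0
    for _ in range(50):
        n = int(rng.integers(1, 9))
        deg = rng.integers(0, 360, n).astype(float)
        ang = np.deg2rad(deg)
        s = circular_mean_rvl(ang)
        c_sum, s_sum = np.cos(ang).sum(), np.sin(ang).sum()
        rvl = np.hypot(c_sum, s_sum) / n
        worst = max(worst, abs(s.rvl - rvl))
        if rvl > 1e-9:
            cgm = np.arctan2(s_sum, c_sum)
            dev = np.angle(np.exp(1j * (s.cgm - cgm)))
            worst = max(worst, abs(dev))
    return worst


def lme_ols_error(rng: np.random.Generator) -> float:
    """Max |LME - OLS| raw-coefficient difference when the random-intercept
    variance is pinned at zero, on a no-between-subject-variance simulation."""
    cfg = SimulationConfig(n_subjects=10, n_trials_per_condition=20,
                           subject_intercept_sd=0.0,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
    bp = simulate_band_power_table(cfg, np.random.default_rng(cfg.seed))
    ds = simulate_coupled_bold(
        bp[["trial_id", "subject_id", "condition", "alley"]], cfg, bp,
        rng=np.random.default_rng(cfg.seed + 1))
    regs = build_band_regressors(bp, BANDS)
    tb = ds.true_betas[ds.true_betas["condition"] == "maze"]
    fit = fit_random_intercept_lme(tb, regs, BANDS,
                                   force_zero_random_effects=True)
    ols = fit_pooled_ols(tb, regs, BANDS)
    return float(np.max(np.abs(fit.table["beta_raw"].to_numpy()
                               - ols["beta_raw"].to_numpy())))
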