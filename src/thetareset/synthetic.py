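"""Synthetic multi-subject epoched oscillations and coupled BOLD data.

Every downstream stage of the pipeline (time-frequency decomposition,
inter-trial coherence, circular statistics, beta-series coupling) is
exercised against this generator, which provides exact ground truth for
reset latencies, per-trial amplitudes and phases, and BOLD coupling
weights.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import DEFAULT_BANDS, SimulationConfig, band_label

CHANNELS = ("right_posterior", "left_posterior")
#: kappa above which the von Mises draw degenerates to the target phase
_KAPPA_DEGENERATE = 1e5


@dataclass
class EpochSet:
    """Trial-epoched multi-channel time series with event metadata.

    ``data`` has shape [trial, channel, time] in microvolt-like units;
    ``time_axis`` is in ms relative to event onset (uniform step
    1000 / sampling_rate); ``events`` has exactly one row per trial with
    trial_id, subject_id, condition (maze / nomaze), alley (left / right)
    and valence (reward / noreward); ``ground_truth`` carries the
    generator's per-trial latent variables when the data are synthetic.
    """

    data: np.ndarray
    time_axis: np.ndarray
    sampling_rate: float
    events: pd.DataFrame
    channel_names: tuple = CHANNELS
    ground_truth: Optional[pd.DataFrame] = None

    def __post_init__(self):
        steps = np.diff(self.time_axis)
        if not np.all(steps > 0):
            raise ValueError("time_axis must be strictly increasing")
        expected = 1000.0 / self.sampling_rate
        if not np.allclose(steps, expected, rtol=1e-6):
            raise ValueError("time_axis step must equal 1000/sampling_rate ms")
        if len(self.events) != self.data.shape[0]:
            raise ValueError("events must have exactly one row per trial")
        if self.events["trial_id"].duplicated().any():
            raise ValueError("trial_id must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, channel) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        return self.channel_names.index(channel)

    def select(self, mask) -> "EpochSet":
        """Subset trials by a boolean mask or an index array over rows of ``events``."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        gt = self.ground_truth.iloc[idx].reset_index(drop=True) \
            if self.ground_truth is not None else None
        return EpochSet(self.data[idx], self.time_axis, self.sampling_rate,
                        self.events.iloc[idx].reset_index(drop=True),
                        self.channel_names, gt)


@dataclass
class CoupledDataset:
    """Epoched electrophysiology with matched single-trial BOLD data.

    ``true_betas`` always holds the noiseless-model trial amplitudes that
    generated the BOLD responses; ``bold`` optionally holds per-subject
    TR-gridded time series, and ``design_events`` the event onsets (s)
    used to build them.
    """

    epochs: EpochSet
    true_betas: pd.DataFrame
    bold: Optional[dict] = None          # subject_id -> 1-D array on TR grid
    design_events: Optional[pd.DataFrame] = None
    region_id: str = "PHG"


def _one_over_f_noise(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """Unit-variance 1/f (power) noise along the last axis, via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])   # amplitude ~ f^-1/2 -> power ~ 1/f
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _draw_reset_phase(rng: np.random.Generator, mu: float, kappa: float) -> float:
    if kappa >= _KAPPA_DEGENERATE:
        return mu
    if kappa < 1e-9:
        return rng.uniform(-np.pi, np.pi)
    return float(rng.vonmises(mu, kappa))


def _trial_waveform(t_s: np.ndarray, amp: float, freq: float, phi0: float,
                    mechanism: str, reset_ms: float, theta_new: float,
                    gain: float, burst_decay_ms: float,
                    target_phase: float) -> np.ndarray:
    """Noise-free single-trial waveform on the epoch time grid (seconds)."""
    ongoing = amp * np.cos(2 * np.pi * freq * t_s + phi0)
    if mechanism == "none":
        return ongoing
    t_r = reset_ms / 1000.0
    dt = t_s - t_r
    cycle = 1.0 / freq
    # alpha-function amplitude transient: unimodal, peaks burst_decay_ms
    # after the reset so peak-latency detection is well posed
    tau = burst_decay_ms / 1000.0
    dtp = np.clip(dt, 0, None)
    bump = (dtp / tau) * np.exp(1.0 - dtp / tau)
    if mechanism == "reset":
        # raised-cosine crossfade over one carrier cycle avoids broadband
        # splatter from the phase discontinuity
        w = np.clip(dt / cycle, 0.0, 1.0)
        w = 0.5 * (1 - np.cos(np.pi * w))
        envelope = 1.0 + (gain - 1.0) * bump
        post = amp * envelope * np.cos(2 * np.pi * freq * dt + theta_new)
        return (1 - w) * ongoing + w * post
    # additive: fixed-phase damped burst on top of the undisturbed carrier
    burst = (amp * max(gain - 1.0, 0.0) * bump
             * np.cos(2 * np.pi * freq * dt + target_phase))
    return ongoing + burst


def simulate_epoch_set(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None) -> EpochSet:
    """Generate a multi-subject feedback-locked epoch set.

    Two channels are emitted: the condition (alley) effects on reset
    latency and amplitude gain are applied only to ``right_posterior``;
    ``left_posterior`` receives the same mechanism with alley-averaged
    parameters, mirroring the hemispheric asymmetry of the modelled
    effect.  Fully reproducible from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    lo, hi = config.epoch_window
    n_time = int(round((hi - lo) * fs / 1000.0)) + 1
    time_axis = lo + np.arange(n_time) * 1000.0 / fs
    t_s = time_axis / 1000.0

    conditions = ["maze", "nomaze"] if config.include_nomaze else ["maze"]
    alleys = list(config.reset_latency_by_condition.keys())
    mean_latency = float(np.mean(list(config.reset_latency_by_condition.values())))
    mean_gain = float(np.mean(list(config.amplitude_gain_by_condition.values())))

    rows, gt_rows, signals = [], [], []
    trial_id = 0
    for subj in range(config.n_subjects):
        for cond in conditions:
            for alley in alleys:
                lat = float(config.reset_latency_by_condition[alley])
                gain = float(config.amplitude_gain_by_condition.get(alley, 1.0))
                for _ in range(config.n_trials_per_condition):
                    amp = float(np.exp(rng.normal(0.0, config.amplitude_trial_sigma)))
                    freq = config.carrier_freq + float(
                        rng.normal(0.0, config.freq_jitter_sd))
                    phi0 = float(rng.uniform(-np.pi, np.pi))
                    theta_new = _draw_reset_phase(
                        rng, config.reset_target_phase, config.reset_concentration)
                    right = _trial_waveform(
                        t_s, amp, freq, phi0, config.mechanism, lat, theta_new,
                        gain, config.burst_decay_ms, config.reset_target_phase)
                    # left channel: same mechanism, alley-averaged parameters,
                    # independent phase draws
                    phi0_l = float(rng.uniform(-np.pi, np.pi))
                    theta_l = _draw_reset_phase(
                        rng, config.reset_target_phase, config.reset_concentration)
                    left = _trial_waveform(
                        t_s, amp, freq, phi0_l, config.mechanism, mean_latency,
                        theta_l, mean_gain, config.burst_decay_ms,
                        config.reset_target_phase)
                    chans = np.stack([right, left])
                    if config.noise_1f_amp > 0:
                        chans = chans + config.noise_1f_amp * _one_over_f_noise(
                            rng, chans.shape, fs)
                    if config.noise_white_amp > 0:
                        chans = chans + config.noise_white_amp * rng.standard_normal(
                            chans.shape)
                    signals.append(chans)
                    rows.append({
                        "trial_id": trial_id, "subject_id": subj,
                        "condition": cond, "alley": alley,
                        "valence": "reward" if rng.random() < 0.5 else "noreward",
                    })
                    gt_rows.append({
                        "trial_id": trial_id, "subject_id": subj,
                        "condition": cond, "alley": alley,
                        "amplitude": amp, "freq_hz": freq,
                        "initial_phase": phi0,
                        "reset_phase": theta_new if config.mechanism == "reset"
                        else np.nan,
                        "reset_latency_ms": lat if config.mechanism != "none"
                        else np.nan,
                        "amplitude_gain": gain,
                    })
                    trial_id += 1

    return EpochSet(
        data=np.asarray(signals), time_axis=time_axis, sampling_rate=fs,
        events=pd.DataFrame(rows), channel_names=CHANNELS,
        ground_truth=pd.DataFrame(gt_rows))


def true_phase_at(epochs: EpochSet, t_ms: float) -> np.ndarray:
    """Generator-truth instantaneous carrier phase per trial at ``t_ms``.

    For reset trials with ``t_ms`` at or after the reset latency this is
    the redrawn phase advanced to ``t_ms``; otherwise the ongoing phase.
    Returned in (-pi, pi].  Only defined for synthetic epoch sets.
    """
    gt = epochs.ground_truth
    if gt is None:
        raise ValueError("true_phase_at requires generator ground truth")
    t = t_ms / 1000.0
    phase = gt["initial_phase"].to_numpy() + 2 * np.pi * gt["freq_hz"].to_numpy() * t
    after = (~gt["reset_phase"].isna().to_numpy()) & \
        (t_ms >= gt["reset_latency_ms"].fillna(np.inf).to_numpy())
    dt = t - gt["reset_latency_ms"].to_numpy() / 1000.0
    reset_phase = gt["reset_phase"].to_numpy() + \
        2 * np.pi * gt["freq_hz"].to_numpy() * dt
    phase = np.where(after, reset_phase, phase)
    return wrap_angle(phase)


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Map angles to (-pi, pi]."""
    wrapped = np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def simulate_band_power_table(config: SimulationConfig,
                              rng: Optional[np.random.Generator] = None,
                              corr: float = 0.3) -> pd.DataFrame:
    """Draw a per-trial band-power table directly, without signal synthesis.

    A single latent per-trial factor induces pairwise correlation ``corr``
    between bands (the mild-multicollinearity regime of real band powers);
    marginals are standard normal.  Used for coupling-stage simulations
    where the full oscillation synthesis would add nothing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    conditions = ["maze", "nomaze"] if config.include_nomaze else ["maze"]
    alleys = list(config.reset_latency_by_condition.keys())
    n_trials = (config.n_subjects * len(conditions) * len(alleys)
                * config.n_trials_per_condition)
    bands = [band_label(b) for b in DEFAULT_BANDS]
    g = rng.standard_normal(n_trials)[:, None]
    eps = rng.standard_normal((n_trials, len(bands)))
    powers = np.sqrt(corr) * g + np.sqrt(1 - corr) * eps
    rows = []
    trial_id = 0
    for subj in range(config.n_subjects):
        for cond in conditions:
            for alley in alleys:
                for _ in range(config.n_trials_per_condition):
                    rows.append({"trial_id": trial_id, "subject_id": subj,
                                 "condition": cond, "alley": alley})
                    trial_id += 1
    df = pd.DataFrame(rows)
    for j, b in enumerate(bands):
        df[b] = powers[:, j]
    return df


def simulate_coupled_bold(epochs_or_events, config: SimulationConfig,
                          band_powers: pd.DataFrame,
                          rng: Optional[np.random.Generator] = None,
                          emit_timeseries: bool = False,
                          region_id: str = "PHG") -> CoupledDataset:
    """Generate single-trial BOLD amplitudes coupled to band power.

    The true amplitude for subject *i*, trial *j* is

        beta_ij = beta0 + S0_i + sum_k b_k * P_ijk * [condition == maze] + eps_ij

    with S0_i ~ N(0, subject_intercept_sd^2) and
    eps_ij ~ N(0, bold_noise_sd^2).  Coupling weights apply only to the
    spatial ("maze") condition; no-maze trials are uncoupled.  With
    ``emit_timeseries`` the per-subject event trains (ISI uniform on
    ``config.isi_range``) are convolved with the canonical HRF so the
    per-trial response amplitudes equal the true betas.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    epochs = epochs_or_events if isinstance(epochs_or_events, EpochSet) else None
    events = epochs.events if epochs is not None else epochs_or_events

    bp = band_powers.set_index("trial_id") if "trial_id" in band_powers.columns \
        else band_powers
    if not set(events["trial_id"]).issubset(set(bp.index)):
        raise ValueError("band_powers must contain one row per epochs trial")
    band_cols = [c for c in bp.columns if c in config.coupling_weights]
    if not band_cols:
        raise ValueError("band_powers has no columns matching coupling_weights")

    subjects = sorted(events["subject_id"].unique())
    intercepts = pd.Series(
        rng.normal(0.0, config.subject_intercept_sd, len(subjects)),
        index=subjects)
    p = bp.loc[events["trial_id"], band_cols].to_numpy(float)
    weights = np.array([config.coupling_weights[b] for b in band_cols])
    coupled_mask = (events["condition"] == "maze").to_numpy()
    signal = np.where(coupled_mask, p @ weights, 0.0)
    beta = (config.bold_intercept
            + intercepts.loc[events["subject_id"]].to_numpy()
            + signal
            + rng.normal(0.0, config.bold_noise_sd, len(events)))
    true_betas = pd.DataFrame({
        "subject_id": events["subject_id"].to_numpy(),
        "region_id": region_id,
        "trial_id": events["trial_id"].to_numpy(),
        "beta": beta,
        "condition": events["condition"].to_numpy(),
        "alley": events["alley"].to_numpy()})

    bold, design_events = None, None
    if emit_timeseries:
        from .fmri import sample_bold_timeseries
        bold, design_events = {}, []
        for subj, grp in true_betas.groupby("subject_id"):
            isis = rng.uniform(*config.isi_range, size=len(grp))
            onsets = 10.0 + np.concatenate([[0.0], np.cumsum(isis[:-1])])
            ts = sample_bold_timeseries(
                onsets, np.full(len(grp), config.event_duration),
                grp["beta"].to_numpy(), config.tr)
            bold[subj] = ts
            for onset, (_, row) in zip(onsets, grp.iterrows()):
                design_events.append({
                    "onset": onset, "duration": config.event_duration,
                    "trial_id": row["trial_id"], "subject_id": subj})
        design_events = pd.DataFrame(design_events)

    return CoupledDataset(epochs=epochs, true_betas=true_betas, bold=bold,
                          design_events=design_events, region_id=region_id)
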