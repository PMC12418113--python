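"""Morlet time-frequency decomposition and event-related power measures.

Single-trial spectra are obtained by convolution with complex Morlet
wavelets (seven cycles by default, amplitude-calibrated so power is
comparable across frequencies; the normalisation cancels in the ratio
baseline).
Total power is the trial average of single-trial power, evoked power is
the power of the trial-averaged time series (the phase-locked component),
and induced power is their difference -- non-negative by Cauchy-Schwarz
because the wavelet transform is linear.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .config import band_label
from .synthetic import EpochSet

DEFAULT_FREQS = np.arange(1.0, 51.0)          # Hz, 1-Hz steps
ANALYSIS_WINDOW = (-500.0, 1000.0)            # ms, post-transform trim
DEFAULT_BASELINE = (-200.0, -100.0)           # ms, pre-event


@dataclass
class BaselineSpec:
    """Pre-event window used for relative-change power normalisation."""
    window: tuple[float, float] = DEFAULT_BASELINE

    def __post_init__(self):
        lo, hi = self.window
        if not (lo < hi <= 0):
            raise ValueError("baseline window must be entirely pre-event")


@dataclass
class Spectrogram:
    """Complex Morlet coefficients and derived power/phase per trial set."""
    complex_coeffs: np.ndarray            # [trial, freq, time]
    freqs: np.ndarray                     # Hz
    time_axis: np.ndarray                 # ms
    sampling_rate: float
    events: pd.DataFrame
    edge_flags: np.ndarray = None         # bool per freq: edge effects in window
    power_total: Optional[np.ndarray] = None    # [freq, time]
    power_evoked: Optional[np.ndarray] = None
    power_induced: Optional[np.ndarray] = None

    @property
    def n_trials(self) -> int:
        return self.complex_coeffs.shape[0]

    @property
    def phase(self) -> np.ndarray:
        """Instantaneous phase in radians, [trial, freq, time]."""
        return np.angle(self.complex_coeffs)

    @property
    def power_single_trial(self) -> np.ndarray:
        """Squared magnitude per trial, [trial, freq, time]."""
        return np.abs(self.complex_coeffs) ** 2

    def select(self, mask) -> "Spectrogram":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return Spectrogram(self.complex_coeffs[idx], self.freqs, self.time_axis,
                           self.sampling_rate,
                           self.events.iloc[idx].reset_index(drop=True),
                           self.edge_flags)


@dataclass
class PeakResult:
    peak_power: float
    peak_latency: float      # ms
    peak_frequency: float    # Hz
    search_window: tuple
    band: tuple


def morlet_wavelet(freq: float, sampling_rate: float, n_cycles: float = 7.0
                   ) -> np.ndarray:
    """Complex Morlet wavelet truncated at +/-5 sigma_t.

    Amplitude-calibrated: convolving a unit sinusoid at the centre
    frequency returns unit magnitude, so squared magnitude reads directly
    as squared signal amplitude at every frequency.  (Any consistent
    normalisation cancels in the ratio baseline.)
    """
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(5 * sigma_t * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    envelope = np.exp(-t ** 2 / (2 * sigma_t ** 2))
    w = np.exp(2j * np.pi * freq * t) * envelope
    return w / (0.5 * envelope.sum())


def morlet_transform(epochs: EpochSet, channel, freqs: Sequence[float] = None,
                     n_cycles: float = 7.0,
                     trim: tuple[float, float] = ANALYSIS_WINDOW) -> Spectrogram:
    """Convolve every trial with complex Morlet wavelets.

    The full epoch is transformed and then trimmed to ``trim`` (default
    -500..+1000 ms) so wavelet edge effects fall outside the analysis
    span; frequencies whose half-support still reaches the epoch edge
    within the trimmed window are flagged in ``edge_flags``.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    ch = epochs.channel_index(channel)
    data = epochs.data[:, ch, :]                      # [trial, time]
    fs = epochs.sampling_rate

    keep = (epochs.time_axis >= trim[0]) & (epochs.time_axis <= trim[1])
    if not keep.any():
        raise ValueError("trim window outside epoch time axis")
    coeffs = np.empty((data.shape[0], len(freqs), keep.sum()), dtype=complex)
    edge_flags = np.zeros(len(freqs), dtype=bool)
    margin_lo = trim[0] - epochs.time_axis[0]         # ms of guard data
    margin_hi = epochs.time_axis[-1] - trim[1]
    for i, f in enumerate(freqs):
        kernel = morlet_wavelet(f, fs, n_cycles)
        conv = fftconvolve(data, kernel[None, :], mode="same", axes=1)
        coeffs[:, i, :] = conv[:, keep]
        half_support_ms = (n_cycles / 2.0) / f * 1000.0
        edge_flags[i] = min(margin_lo, margin_hi) < half_support_ms
    return Spectrogram(coeffs, freqs, epochs.time_axis[keep], fs,
                       epochs.events.copy(), edge_flags)


def decompose_evoked_induced(spec: Spectrogram, epochs: EpochSet, channel,
                             n_cycles: float = 7.0) -> Spectrogram:
    """Fill total / evoked / induced trial-average power on a spectrogram.

    Evoked power is the Morlet power of the across-trial time-domain
    average (the ERP); total is the trial mean of single-trial power;
    induced = total - evoked.
    """
    if spec.n_trials < 2:
        raise ValueError("evoked/induced decomposition requires >= 2 trials")
    ch = epochs.channel_index(channel)
    erp = epochs.data[:, ch, :].mean(axis=0, keepdims=True)
    erp_epochs = EpochSet(erp[:, None, :], epochs.time_axis,
                          epochs.sampling_rate,
                          pd.DataFrame({"trial_id": [0]}), ("erp",), None)
    trim = (spec.time_axis[0], spec.time_axis[-1])
    erp_spec = morlet_transform(erp_epochs, 0, spec.freqs, n_cycles, trim)
    spec.power_total = spec.power_single_trial.mean(axis=0)
    spec.power_evoked = erp_spec.power_single_trial[0]
    spec.power_induced = spec.power_total - spec.power_evoked
    return spec


def baseline_normalize(power: np.ndarray, baseline: BaselineSpec,
                       time_axis: np.ndarray) -> np.ndarray:
    """Relative change: (power - B) / B with B the per-frequency baseline mean.

    ``power`` has time on the last axis and frequency on the second-to-last
    axis (leading axes, e.g. trials, are broadcast).  Frequencies whose
    baseline mean is not positive are returned as NaN rather than +/-inf.
    """
    lo, hi = baseline.window
    sel = (time_axis >= lo) & (time_axis <= hi)
    if sel.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    b = power[..., sel].mean(axis=-1, keepdims=True)
    out = np.full_like(power, np.nan, dtype=float)
    ok = np.broadcast_to(b > np.finfo(float).tiny, power.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (power - b) / b
    out[ok] = ratio[ok]
    return out


def find_peak(normalized_power: np.ndarray, freqs: np.ndarray,
              time_axis: np.ndarray, band: tuple[float, float],
              window: tuple[float, float]) -> PeakResult:
    """Global maximum over a band x window sub-grid.

    Ties break deterministically to the earliest latency, then the lowest
    frequency.
    """
    fsel = (freqs >= band[0]) & (freqs <= band[1])
    tsel = (time_axis >= window[0]) & (time_axis <= window[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band x window sub-grid")
    sub = normalized_power[np.ix_(np.flatnonzero(fsel), np.flatnonzero(tsel))]
    # [time, freq] ordering makes row-major argmax tie-break earliest
    # latency first, then lowest frequency
    sub_tf = sub.T
    flat = np.nanargmax(sub_tf)
    ti, fi = np.unravel_index(flat, sub_tf.shape)
    peak = sub_tf[ti, fi]
    # resolve exact ties explicitly
    ties = np.argwhere(sub_tf == peak)
    ti, fi = ties[np.lexsort((ties[:, 1], ties[:, 0]))][0]
    return PeakResult(float(peak),
                      float(time_axis[tsel][ti]),
                      float(freqs[fsel][fi]),
                      tuple(window), tuple(band))


def find_subject_peak_frequency(spec: Spectrogram,
                                band: tuple[float, float] = (4.0, 12.0),
                                window: tuple[float, float] = None) -> float:
    """Frequency with maximum raw trial-average power within ``band``.

    Identified from un-normalised total power (optionally restricted to a
    time window) so the ongoing carrier dominates; ties break to the
    lowest frequency.
    """
    power = spec.power_total if spec.power_total is not None \
        else spec.power_single_trial.mean(axis=0)
    tsel = np.ones(len(spec.time_axis), bool) if window is None else \
        (spec.time_axis >= window[0]) & (spec.time_axis <= window[1])
    fsel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band x window sub-grid")
    mean_power = power[np.ix_(np.flatnonzero(fsel), np.flatnonzero(tsel))
                       ].mean(axis=1)
    return float(spec.freqs[fsel][np.argmax(mean_power)])


def band_mean(values: np.ndarray, freqs: np.ndarray,
              band: tuple[float, float], axis: int) -> np.ndarray:
    """Mean over the 1-Hz bins spanned by ``band`` (inclusive)."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} outside frequency grid")
    return np.take(values, np.flatnonzero(sel), axis=axis).mean(axis=axis)


def single_trial_band_power(spec: Spectrogram,
                            bands: Sequence[tuple[float, float]],
                            window: tuple[float, float] = (50.0, 250.0),
                            baseline: BaselineSpec = None) -> pd.DataFrame:
    """Per-trial baseline-relative band power, one column per band.

    The baseline is the across-trial mean single-trial power per
    frequency over the baseline window (shared across trials), and each
    trial's power is expressed as relative change against it before
    averaging over the band x window sub-grid.  Event metadata columns
    are carried through.
    """
    baseline = baseline or BaselineSpec()
    power = spec.power_single_trial                   # [trial, freq, time]
    lo, hi = baseline.window
    bsel = (spec.time_axis >= lo) & (spec.time_axis <= hi)
    if bsel.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    b = power[:, :, bsel].mean(axis=(0, 2))           # [freq], shared
    if np.any(b <= np.finfo(float).tiny):
        raise ValueError("non-positive baseline power at some frequency")
    rel = (power - b[None, :, None]) / b[None, :, None]
    tsel = (spec.time_axis >= window[0]) & (spec.time_axis <= window[1])
    if not tsel.any():
        raise ValueError("power window outside analysis span")
    out = spec.events.copy()
    for band in bands:
        fsel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
        if not fsel.any():
            raise ValueError(f"band {band} outside frequency grid")
        out[band_label(band)] = rel[np.ix_(np.arange(spec.n_trials),
                                           np.flatnonzero(fsel),
                                           np.flatnonzero(tsel))].mean(axis=(1, 2))
    return out
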