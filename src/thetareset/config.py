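"""Configuration objects for the simulation and analysis pipeline."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Canonical frequency bands (Hz) used for single-trial power regressors:
#: delta plus four 2-Hz theta/alpha sub-bands.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1, 4), (5, 6), (7, 8), (9, 10), (11, 12),
)


def band_label(band: tuple[float, float]) -> str:
    """Format a (low, high) band in Hz as a table-friendly label, e.g. ``"7-8"``."""
    lo, hi = band
    return f"{lo:g}-{hi:g}"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic feedback-locked oscillation + BOLD generator.

    The generator emulates a two-condition (maze / no-maze), two-alley
    (left / right) virtual-navigation experiment in which feedback onset
    partially resets an ongoing posterior theta oscillation.  Three
    event-locked mechanisms are available:

    ``reset``
        the ongoing carrier keeps its amplitude but its phase is redrawn
        from a von Mises distribution at the (condition-dependent) reset
        latency;
    ``additive``
        a fixed-phase damped oscillatory burst is superimposed on the
        undisturbed ongoing oscillation;
    ``none``
        no event-locked change (null condition).

    Amplitude effects are controlled separately from phase effects via
    ``amplitude_gain_by_alley`` (a transient post-event gain envelope), so
    phase concentration and power change can be manipulated independently.
    """

    n_subjects: int = 11
    #: trials per subject per (condition x alley) cell
    n_trials_per_condition: int = 50
    sampling_rate: float = 250.0           # Hz
    epoch_window: tuple[float, float] = (-2500.0, 2500.0)  # ms around event
    carrier_freq: float = 8.0              # Hz
    mechanism: str = "reset"               # reset | additive | none
    #: event-to-reset latency (ms) per alley; right alley resets earlier
    reset_latency_by_condition: dict = field(
        default_factory=lambda: {"left": 196.0, "right": 180.0})
    reset_concentration: float = 4.0       # von Mises kappa (>= 0)
    reset_target_phase: float = np.pi      # radians
    #: transient post-event amplitude gain per alley (1.0 = no power change)
    amplitude_gain_by_condition: dict = field(
        default_factory=lambda: {"left": 1.4, "right": 1.55})
    #: e-folding time (ms) of the post-event gain transient
    burst_decay_ms: float = 150.0
    #: SD of per-trial carrier-frequency jitter (Hz); makes post-reset
    #: coherence decay so the ITC time course has a well-defined peak
    freq_jitter_sd: float = 0.5
    #: sigma of the log-normal per-trial amplitude distribution (median 1)
    amplitude_trial_sigma: float = 0.2
    noise_1f_amp: float = 1.0              # relative to carrier amplitude
    noise_white_amp: float = 0.3
    include_nomaze: bool = True
    # ---- BOLD / coupling stage -------------------------------------------
    #: coupling weight per band label; applies to "maze" trials only
    coupling_weights: dict = field(
        default_factory=lambda: {"1-4": 0.0, "5-6": -0.097, "7-8": 0.148,
                                 "9-10": 0.0, "11-12": 0.0})
    bold_intercept: float = 0.0
    subject_intercept_sd: float = 0.5
    bold_noise_sd: float = 0.85
    tr: float = 2.0                        # seconds
    isi_range: tuple[float, float] = (3.0, 5.0)   # seconds between events
    event_duration: float = 1.0            # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("reset", "additive", "none"):
            raise ValueError(
                f"mechanism must be 'reset', 'additive' or 'none', "
                f"got {self.mechanism!r}")
        if self.reset_concentration < 0:
            raise ValueError("reset_concentration (von Mises kappa) must be >= 0")
        if self.sampling_rate <= 2 * self.carrier_freq:
            raise ValueError(
                f"sampling_rate ({self.sampling_rate} Hz) must exceed twice "
                f"the carrier frequency ({self.carrier_freq} Hz)")
        lo, hi = self.epoch_window
        if not (lo < 0 < hi):
            raise ValueError("epoch_window must span the event (start < 0 < end)")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch_window"] = list(d["epoch_window"])
        d["isi_range"] = list(d["isi_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("epoch_window", "isi_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def content_hash(self) -> str:
        """Stable hash of the configuration, for reproducibility manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
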