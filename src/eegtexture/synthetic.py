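"""Synthetic resting-state EEG cohorts with PD-like class structure.

Two electrophysiological effects reported for Parkinson's disease drive
the class difference: reduced beta-band (13-30 Hz) activity and an
overall amplitude decrease. Each channel is simulated independently as
a sum of band-limited Gaussian noise components (white noise band-pass
filtered to the delta/theta/alpha/beta bands and rescaled to a target
RMS in microvolts) plus 1/f pink noise. For patient-class subjects the
beta component's RMS is multiplied by ``1 - beta_reduction`` and the
finished channel by ``1 - amplitude_reduction``; both effects compose
multiplicatively.

This is deliberately a minimal statistical model, not forward-modeled
EEG: there is no spatial covariance between channels (the downstream
method treats channels independently), no ocular/muscle artifacts, and
no drug-condition effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Condition, Recording

__all__ = ["BANDS", "SimSpec", "simulate_cohort"]

#: Canonical EEG frequency bands, Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

_DEFAULT_AMPLITUDES = {"delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 5.0}


@dataclass(frozen=True)
class SimSpec:
    """Cohort simulation parameters.

    Band amplitudes are RMS in microvolts; the defaults put most power
    in alpha and delta, as in eyes-closed resting EEG. ``beta_reduction``
    and ``amplitude_reduction`` are the two patient-class effects, as
    fractions in [0, 1).
    """

    n_per_class: int = 30
    n_channels: int = 57
    duration_s: float = 60.0
    fs: float = 500.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES)
    )
    pink_noise_rms: float = 4.0
    beta_reduction: float = 0.5
    amplitude_reduction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.beta_reduction < 1:
            raise ValueError("beta_reduction must be in [0, 1)")
        if not 0 <= self.amplitude_reduction < 1:
            raise ValueError("amplitude_reduction must be in [0, 1)")
        if self.fs <= 2 * BANDS["beta"][1]:
            raise ValueError("fs must exceed twice the beta upper edge (60 Hz)")
        if self.n_per_class < 1 or self.n_channels < 1:
            raise ValueError("n_per_class and n_channels must be >= 1")
        if self.duration_s * self.fs < 1:
            raise ValueError("duration too short")
        unknown = set(self.band_amplitudes) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")


def _rescale_rms(x: np.ndarray, target: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    return x * (target / rms) if rms > 0 and target > 0 else x * 0.0


def _band_noise(
    rng: np.random.Generator, n: int, band: tuple[float, float], fs: float, rms: float
) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return _rescale_rms(signal.sosfiltfilt(sos, rng.standard_normal(n)), rms)


def _pink_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """1/f noise by spectral shaping of white noise."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    return _rescale_rms(np.fft.irfft(spectrum * shaping, n), rms)


def _channel(
    rng: np.random.Generator, n: int, spec: SimSpec, is_patient: bool
) -> np.ndarray:
    total = np.zeros(n)
    for name, rms in spec.band_amplitudes.items():
        if name == "beta" and is_patient:
            rms = rms * (1.0 - spec.beta_reduction)
        total += _band_noise(rng, n, BANDS[name], spec.fs, rms)
    total += _pink_noise(rng, n, spec.pink_noise_rms)
    if is_patient:
        total *= 1.0 - spec.amplitude_reduction
    return total


def simulate_cohort(spec: SimSpec | None = None, **kwargs) -> list[Recording]:
    """Simulate a balanced two-class cohort of multichannel recordings.

    Controls (label 0) come first, then patients (label 1). The same
    seed reproduces the cohort bit for bit.
    """
    if spec is None:
        spec = SimSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimSpec or keyword overrides, not both")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    names = [f"ch{c:02d}" for c in range(spec.n_channels)]
    cohort: list[Recording] = []
    for label in (0, 1):
        group = "ctl" if label == 0 else "pd"
        for s in range(spec.n_per_class):
            data = np.vstack(
                [_channel(rng, n, spec, label == 1) for _ in range(spec.n_channels)]
            )
            cohort.append(
                Recording(
                    subject_id=f"{group}{s:03d}",
                    data=data,
                    fs=spec.fs,
                    channel_names=list(names),
                    label=label,
                    condition=Condition(eyes="closed", drug="off"),
                )
            )
    return cohort
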