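"""Band-pass filtering and average re-referencing of EEG recordings.

The standard cleanup applied before feature extraction: a 1-50 Hz
Butterworth band-pass per channel (zero-phase by default, so no latency
shift across windows) followed by re-referencing every channel to the
instantaneous cross-channel mean. Artifact removal by ICA is an upstream
responsibility and deliberately out of scope here; callers supply
already-cleaned data or accept basic filtering only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import Recording

__all__ = ["FilterSpec", "bandpass", "average_rereference", "preprocess"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter parameters.

    Defaults follow common resting-state EEG practice: 1-50 Hz,
    4th-order Butterworth, applied forward-backward (zero phase).
    """

    low_hz: float = 1.0
    high_hz: float = 50.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high_hz={self.high_hz} must be below the Nyquist rate {fs / 2}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Band-pass filter every channel independently.

    Zero-phase filtering uses reflection padding at the record edges, so
    the output has exactly the input's shape; no samples are dropped.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    sos = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=rec.fs,
        output="sos",
    )
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        filtered = signal.sosfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def average_rereference(rec: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel.

    After re-referencing, the mean across channels is zero at every
    sample. Requires at least two channels; the common average of a
    single channel would zero it out entirely.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def preprocess(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Filter then re-reference, in that order."""
    return average_rereference(bandpass(rec, spec))
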