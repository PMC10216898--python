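"""Shared fixtures: tiny synthetic recordings and on-disk format helpers.

All binary-format fixtures (EDF, EEGLAB .set) are generated at test time
in tmp_path; nothing binary is stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegtexture import Recording, SimSpec, extract_cohort, preprocess, simulate_cohort


def make_recording(n_channels=3, n_samples=500, fs=500.0, seed=0, label=0,
                   subject_id="s000"):
    rng = np.random.default_rng(seed)
    return Recording(
        subject_id=subject_id,
        data=rng.standard_normal((n_channels, n_samples)) * 10.0,
        fs=fs,
        channel_names=[f"ch{i:02d}" for i in range(n_channels)],
        label=label,
    )


@pytest.fixture
def recording():
    return make_recording()


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap separable cohort for unit-level pipeline tests."""
    return simulate_cohort(
        SimSpec(n_per_class=6, n_channels=2, duration_s=4.0, fs=250.0, seed=11)
    )


@pytest.fixture(scope="session")
def acceptance_cohort():
    """The scaled synthetic study cohort: 60 subjects, 8 channels, 20 s.

    Effect sizes are the generator defaults (beta_reduction=0.5,
    amplitude_reduction=0.3), seed 42. Session-scoped because extraction
    dominates suite runtime.
    """
    return simulate_cohort(
        SimSpec(n_per_class=30, n_channels=8, duration_s=20.0, fs=500.0, seed=42)
    )


@pytest.fixture(scope="session")
def acceptance_table(acceptance_cohort):
    return extract_cohort([preprocess(r) for r in acceptance_cohort])


def write_edf(path, data, fs, labels, pmin=-1000.0, pmax=1000.0):
    """Write a minimal valid EDF file (int16 records, 1 s record length)."""
    data = np.asarray(data, dtype=float)
    n_sig, n_samp = data.shape
    spr = int(fs)
    n_rec = n_samp // spr
    assert n_rec >= 1 and len(labels) == n_sig

    def field(value, width):
        return str(value)[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            field(0, 8),
            field("X", 80),
            field("X", 80),
            field("01.01.20", 8),
            field("00.00.00", 8),
            field(256 * (n_sig + 1), 8),
            field("", 44),
            field(n_rec, 8),
            field(1, 8),
            field(n_sig, 4),
        ]
    )
    header += b"".join(field(lbl, 16) for lbl in labels)
    header += b"".join(field("", 80) for _ in labels)
    header += b"".join(field("uV", 8) for _ in labels)
    header += b"".join(field(pmin, 8) for _ in labels)
    header += b"".join(field(pmax, 8) for _ in labels)
    header += b"".join(field(-32768, 8) for _ in labels)
    header += b"".join(field(32767, 8) for _ in labels)
    header += b"".join(field("", 80) for _ in labels)
    header += b"".join(field(spr, 8) for _ in labels)
    header += b"".join(field("", 32) for _ in labels)

    scale = 65535.0 / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for s in range(n_sig):
                seg = data[s, r * spr : (r + 1) * spr]
                dig = np.round((seg - pmin) * scale - 32768.0).astype("<i2")
                fh.write(dig.tobytes())


def write_set(path, data, fs, labels):
    """Write a minimal EEGLAB .set file via scipy.io.savemat."""
    from scipy.io import savemat

    data = np.asarray(data, dtype=np.float32)
    n_ch, n_s = data.shape
    chanlocs = np.zeros((n_ch,), dtype=[("labels", "O")])
    for i, lbl in enumerate(labels):
        chanlocs[i] = (lbl,)
    eeg = {
        "data": data,
        "srate": float(fs),
        "nbchan": float(n_ch),
        "pnts": float(n_s),
        "trials": 1.0,
        "xmin": 0.0,
        "xmax": (n_s - 1) / fs,
        "chanlocs": chanlocs,
        "icawinv": np.array([]),
        "icasphere": np.array([]),
        "icaweights": np.array([]),
        "icaact": np.array([]),
        "event": np.array([]),
        "epoch": np.array([]),
        "setname": "synthetic fixture",
        "ref": "common",
    }
    savemat(str(path), {"EEG": eeg}, appendmat=False)
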