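"""Reading and writing EEG recordings and per-subject feature tables.

Recordings are kept channels x samples in microvolts throughout the
package. Three on-disk formats are supported for recordings: EEGLAB
``.set`` and EDF (both read-only, through :mod:`mne`), and a delimited
CSV layout with one channel per row and the channel name in the first
column. CSV recordings carry their metadata (sampling rate, class label,
recording condition) in a YAML sidecar next to the data file, because
plain delimited text has no standard header for any of it.

Feature tables (subjects x features) round-trip through CSV with one row
per subject and feature columns named ``<channel>.<window>.<feature>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Condition",
    "Recording",
    "FeatureTable",
    "read_recording",
    "write_recording",
    "select_channels",
    "read_feature_table",
    "write_feature_table",
]

_EYES = ("open", "closed", "mixed")
_DRUG = ("on", "off")


@dataclass(frozen=True)
class Condition:
    """Recording condition: eye state and dopaminergic medication state."""

    eyes: str = "mixed"
    drug: str = "off"

    def __post_init__(self) -> None:
        if self.eyes not in _EYES:
            raise ValueError(f"eyes must be one of {_EYES}, got {self.eyes!r}")
        if self.drug not in _DRUG:
            raise ValueError(f"drug must be one of {_DRUG}, got {self.drug!r}")


@dataclass
class Recording:
    """One subject's multichannel EEG.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz, > 0.
    channel_names : list of str
        One unique name per data row.
    label : int
        Binary class label: 1 for the patient (PD) class, 0 for control.
    condition : Condition
        Eye and medication state.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    channel_names: list[str]
    label: int = 0
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if self.data.shape[1] == 0:
            raise ValueError("recording has no samples")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and feature provenance.

    ``feature_ids`` holds one ``(channel_name, window_index, feature_name)``
    triple per column, in column order.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[tuple[str, int, str]]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length must equal number of columns")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length must equal number of rows")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels must have one entry per subject")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return {}
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}
    if not isinstance(meta, dict):
        raise ValueError(f"sidecar {sidecar} must contain a YAML mapping")
    return meta


def _condition_from_meta(meta: dict) -> Condition:
    return Condition(
        eyes=str(meta.get("eyes", "mixed")), drug=str(meta.get("drug", "off"))
    )


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from ``.set``, EDF, or delimited CSV.

    For CSV input the sampling rate must be present in the YAML sidecar
    (``<stem>.yaml``); for ``.set``/EDF it comes from the file itself and
    the sidecar only supplies label/condition metadata when present.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"recording file not found: {path}")
    if format is None:
        format = {".set": "set", ".edf": "edf"}.get(path.suffix.lower(), "delimited")
    if format not in ("set", "edf", "delimited"):
        raise ValueError(f"unknown format {format!r}")

    meta = _read_sidecar(path)

    if format == "delimited":
        frame = pd.read_csv(path, header=None, index_col=0)
        data = frame.to_numpy(dtype=float)
        names = [str(n) for n in frame.index]
        if "fs" not in meta:
            raise ValueError(
                f"delimited recording {path} needs 'fs' in sidecar {_sidecar_path(path)}"
            )
        fs = float(meta["fs"])
    else:
        import mne

        reader = {
            "set": lambda p: mne.io.read_raw_eeglab(p, preload=True, verbose="error"),
            "edf": lambda p: mne.io.read_raw_edf(p, preload=True, verbose="error"),
        }[format]
        try:
            raw = reader(str(path))
        except Exception as exc:  # noqa: BLE001 - reader-specific failures
            raise IOError(f"could not read {format} file {path}: {exc}") from exc
        data = raw.get_data() * 1e6  # mne returns volts; the package works in uV
        names = list(raw.ch_names)
        fs = float(raw.info["sfreq"])

    return Recording(
        subject_id=str(meta.get("subject_id", path.stem)),
        data=data,
        fs=fs,
        channel_names=names,
        label=int(meta.get("label", 0)),
        condition=_condition_from_meta(meta),
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as delimited CSV plus YAML sidecar."""
    path = Path(path)
    frame = pd.DataFrame(rec.data, index=rec.channel_names)
    frame.to_csv(path, header=False, float_format="%.10g")
    meta = {
        "subject_id": rec.subject_id,
        "fs": float(rec.fs),
        "label": int(rec.label),
        "eyes": rec.condition.eyes,
        "drug": rec.condition.drug,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def select_channels(rec: Recording, keep: list[str]) -> Recording:
    """Project a recording onto the named channels, in the given order."""
    missing = [name for name in keep if name not in rec.channel_names]
    if missing:
        raise KeyError(f"channels not present in recording: {missing}")
    idx = [rec.channel_names.index(name) for name in keep]
    return replace(rec, data=rec.data[idx], channel_names=list(keep))


def feature_id_to_str(fid: tuple[str, int, str]) -> str:
    channel, window, name = fid
    return f"{channel}.{window}.{name}"


def _feature_id_from_str(text: str) -> tuple[str, int, str]:
    channel, window, name = text.rsplit(".", 2)
    return channel, int(window), name


def write_feature_table(tbl: FeatureTable, path: str | Path) -> None:
    """Write a feature table to CSV (one row per subject)."""
    if tbl.n_features == 0:
        raise ValueError("refusing to write a table with zero features")
    frame = pd.DataFrame(
        tbl.values, columns=[feature_id_to_str(f) for f in tbl.feature_ids]
    )
    frame.insert(0, "subject_id", tbl.subject_ids)
    frame.insert(1, "label", tbl.labels)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise IOError(f"feature table not found: {path}")
    frame = pd.read_csv(path)
    feature_cols = [c for c in frame.columns if c not in ("subject_id", "label")]
    if not feature_cols:
        raise ValueError(f"{path} contains no feature columns")
    return FeatureTable(
        values=frame[feature_cols].to_numpy(dtype=float),
        labels=frame["label"].to_numpy(dtype=int),
        feature_ids=[_feature_id_from_str(c) for c in feature_cols],
        subject_ids=[str(s) for s in frame["subject_id"]],
    )
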