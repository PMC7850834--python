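"""Reading and writing EEG recordings and feature tables.

Recordings are held as channels x samples matrices in microvolts together
with a sampling rate, ordered channel names and optional interval
annotations.  EDF/EDF+ files are read through :mod:`mne`; a small EDF+C
writer lives in :mod:`emdwave._edf`.  Feature tables travel as plain CSV
with a header row and the class label in the last column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical 10-20 montage order used throughout the package.
MONTAGE: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "T7", "T8", "O1", "O2")

#: Older 10-20 names for the temporal sites (T3/T4 are the pre-1991 labels
#: for the same scalp positions as T7/T8).
CHANNEL_ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8"}

#: Expected feature counts per extraction method for the 8-channel montage.
METHOD_FEATURE_COUNTS: dict[str, int] = {
    "hybrid": 64,
    "emd-energy": 64,
    "dwt-energy": 48,
}


class EmdwaveError(Exception):
    """Base class for all package errors."""


class FormatError(EmdwaveError):
    """Malformed or unsupported input file."""


class DomainError(EmdwaveError, ValueError):
    """Argument outside the mathematically valid domain."""


class ConfigurationError(EmdwaveError):
    """Inconsistent pipeline configuration (montage, labels, shapes)."""


@dataclass
class EEGRecording:
    """A multichannel EEG time series.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One unique name per row of ``data``.
    annotations
        ``(label, start_s, end_s)`` intervals within the recording.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DomainError("data must be a channels x samples matrix")
        if not np.isfinite(self.data).all():
            raise DomainError("recording contains non-finite samples")
        if self.fs <= 0:
            raise DomainError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise DomainError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise DomainError("channel names must be unique")
        dur = self.duration_s
        for label, start, end in self.annotations:
            if not (0 <= start < end <= dur + 1e-9):
                raise DomainError(
                    f"annotation {label!r} [{start}, {end}] outside recording "
                    f"of {dur:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class InterestLabel:
    """Situational-interest class derived from a questionnaire score."""

    value: str  # "high" | "low" | "moderate"
    score: float


def assign_interest_label(score: float) -> InterestLabel:
    """Map a 0-100 situational-interest questionnaire score to a class.

    Scores above 77 are *high* interest, below 69 *low* interest, and the
    closed band [69, 77] is *moderate* (moderate subjects are excluded from
    classification downstream).

    Raises
    ------
    DomainError
        If ``score`` is outside [0, 100].
    """
    if not 0 <= score <= 100:
        raise DomainError(f"score {score} outside [0, 100]")
    if score > 77:
        value = "high"
    elif score < 69:
        value = "low"
    else:
        value = "moderate"
    return InterestLabel(value=value, score=float(score))


def _canonicalize_channels(rec: EEGRecording) -> EEGRecording:
    """Apply T3/T4 aliases and reorder to the canonical montage if complete."""
    names = tuple(CHANNEL_ALIASES.get(n, n) for n in rec.channel_names)
    rec = replace(rec, channel_names=names)
    if set(MONTAGE).issubset(names):
        order = [names.index(n) for n in MONTAGE]
        extra = [i for i in range(len(names)) if i not in order]
        order += extra
        rec = replace(
            rec,
            data=rec.data[order],
            channel_names=tuple(names[i] for i in order),
        )
    else:
        logger.warning(
            "montage incomplete (%s); keeping file channel order", names
        )
    return rec


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording`.

    Channels are canonicalized to the standard montage order when all eight
    sites are present; EDF+ annotations become ``(label, start_s, end_s)``
    intervals.
    """
    import mne

    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such EDF file: {path}")
    _check_uniform_rate(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    try:
        data = raw.get_data(units="uV")
    except Exception:  # pragma: no cover - unit-less channel types
        data = raw.get_data() * 1e6
    ann = [
        (desc, float(onset), float(onset + dur))
        for desc, onset, dur in zip(
            raw.annotations.description,
            raw.annotations.onset,
            raw.annotations.duration,
        )
    ]
    rec = EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        annotations=ann,
    )
    return _canonicalize_channels(rec)


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a 16-bit EDF+C file (annotations included)."""
    from . import _edf

    _edf.write_edf(Path(path), rec)


def read_delimited(
    path: str | Path,
    fs: float,
    channel_names: Sequence[str] | None = None,
) -> EEGRecording:
    """Read a delimited numeric matrix (one column per channel).

    The dialect is comma-separated with ``.`` decimals and an optional
    single header row; when ``channel_names`` is omitted the header row
    supplies the names.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = first.iloc[0].map(
        lambda v: isinstance(v, str) and not _is_number(v)
    ).any()
    try:
        if has_header:
            frame = pd.read_csv(path, header=0)
            header_names = tuple(str(c) for c in frame.columns)
        else:
            frame = pd.read_csv(path, header=None)
            header_names = None
    except ValueError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    values = frame.to_numpy()
    bad = ~np.isfinite(pd.to_numeric(values.ravel(), errors="coerce").reshape(
        values.shape
    ))
    if bad.any():
        row = int(np.argwhere(bad)[0][0]) + (1 if has_header else 0)
        raise FormatError(f"{path}: non-numeric cell in data row {row}")
    if channel_names is None:
        if header_names is None:
            raise FormatError(
                f"{path}: no channel names given and no header row found"
            )
        channel_names = header_names
    if len(channel_names) != values.shape[1]:
        raise FormatError(
            f"{path}: {values.shape[1]} columns but "
            f"{len(channel_names)} channel names"
        )
    rec = EEGRecording(
        data=values.astype(float).T,
        fs=fs,
        channel_names=tuple(channel_names),
    )
    return _canonicalize_channels(rec)


def _check_uniform_rate(path: Path) -> None:
    """Reject EDF files whose signals are sampled at different rates.

    The annotation channel of an EDF+ file is exempt (its "samples" are
    bytes of text, not waveform data).
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: corrupt EDF header") from exc
        sig_header = fh.read(256 * ns)
        if len(sig_header) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal header")
    labels = [
        sig_header[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    off = ns * (16 + 80 + 8 * 5 + 80)
    rates = set()
    for i, label in enumerate(labels):
        if label == "EDF Annotations":
            continue
        spr = sig_header[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip()
        rates.add(spr)
    if len(rates) > 1:
        raise FormatError(f"{path}: channels with differing sampling rates")


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


@dataclass
class FeatureTable:
    """Segments x features matrix with class labels.

    ``frame`` holds one named numeric column per feature plus a final
    ``label`` column in {"high", "low"}.
    """

    frame: pd.DataFrame
    method: str
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "label" not in self.frame.columns:
            raise ConfigurationError("feature table must have a 'label' column")
        if list(self.frame.columns).index("label") != len(self.frame.columns) - 1:
            cols = [c for c in self.frame.columns if c != "label"] + ["label"]
            self.frame = self.frame[cols]
        feats = self.feature_names
        if len(set(feats)) != len(feats):
            raise ConfigurationError("feature names must be unique")
        if self.frame[list(feats)].isna().any().any():
            raise ConfigurationError("feature table contains missing values")
        expected = METHOD_FEATURE_COUNTS.get(self.method)
        if expected is not None and len(self.frame) and len(feats) != expected:
            raise ConfigurationError(
                f"method {self.method!r} declares {expected} features, "
                f"table has {len(feats)}"
            )
        bad = set(self.frame["label"]) - {"high", "low"}
        if bad:
            raise ConfigurationError(f"labels outside {{high, low}}: {bad}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c != "label")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.method == other.method
            and list(self.frame.columns) == list(other.frame.columns)
            and len(self.frame) == len(other.frame)
            and (self.frame["label"].to_numpy() == other.frame["label"].to_numpy()).all()
            and np.array_equal(self.X, other.X)
        )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV (feature columns then ``label``)."""
    path = Path(path)
    try:
        table.frame.to_csv(path, index=False)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def read_feature_table(path: str | Path, method: str = "hybrid") -> FeatureTable:
    """Read a CSV produced by :func:`write_feature_table`."""
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty and "label" not in frame.columns:
        raise FormatError(f"{path}: missing 'label' column")
    return FeatureTable(frame=frame, method=method)
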