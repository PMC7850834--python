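"""Hybrid EMD-wavelet energy features.

The proposed feature set targets low-frequency (delta) activity while
keeping the usable data volume high: each channel is first decomposed by
EMD into up to 8 intrinsic mode functions, each IMF then undergoes a
5-level db4 DWT, and the *relative energy of the coarsest approximation*
(the percentage of that IMF's coefficient energy held by A5) becomes one
feature.  With 8 channels x 8 IMFs this yields 64 percentages per
segment, each in [0, 100]; channels producing fewer than 8 IMFs (and
all-zero IMFs) contribute 0 for the missing slots.  Because every value
is a percentage the features are invariant to rescaling the signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import emd as _emd
from . import wavelet as _wavelet
from .io_signals import ConfigurationError, DomainError, FeatureTable

METHODS = ("hybrid", "emd-energy", "dwt-energy")


def emd_wavelet_features(
    seg,
    max_imfs: int = 8,
    wavelet: str = _wavelet.DEFAULT_WAVELET,
    levels: int = _wavelet.DEFAULT_LEVELS,
) -> np.ndarray:
    """Hybrid feature row: ``n_channels * max_imfs`` A_L percentages.

    Ordering is channel-major then IMF-major, matching
    :func:`hybrid_feature_names`.
    """
    data = np.asarray(seg.data, dtype=float)
    if data.size == 0:
        raise DomainError("empty segment")
    rows = []
    for ch in range(data.shape[0]):
        values = np.zeros(max_imfs)
        x = data[ch]
        if np.any(x):
            dec = _emd.emd_decompose(x, max_imfs=max_imfs)
            for j, imf in enumerate(dec.imfs[:max_imfs]):
                if not np.any(imf):
                    continue  # an all-zero IMF carries no energy anywhere
                wdec = _wavelet.dwt_decompose(imf, wavelet=wavelet,
                                              levels=levels)
                rel = _wavelet.subband_relative_energy(wdec)
                values[j] = rel[f"A{levels}"]
        rows.append(values)
    return np.concatenate(rows)


def hybrid_feature_names(channel_names, max_imfs: int = 8) -> list[str]:
    return [f"{ch}_imf{j + 1}_Arel"
            for ch in channel_names for j in range(max_imfs)]


def extract_features(seg, method: str = "hybrid", max_imfs: int = 8,
                     wavelet: str = _wavelet.DEFAULT_WAVELET,
                     levels: int = _wavelet.DEFAULT_LEVELS) -> np.ndarray:
    if method == "hybrid":
        return emd_wavelet_features(seg, max_imfs, wavelet, levels)
    if method == "emd-energy":
        return _emd.emd_energy_features(seg, max_imfs)
    if method == "dwt-energy":
        return _wavelet.dwt_energy_features(seg, wavelet, levels)
    raise ConfigurationError(f"unknown method {method!r}; expected {METHODS}")


def feature_names(channel_names, method: str = "hybrid", max_imfs: int = 8,
                  levels: int = _wavelet.DEFAULT_LEVELS) -> list[str]:
    if method == "hybrid":
        return hybrid_feature_names(channel_names, max_imfs)
    if method == "emd-energy":
        return _emd.emd_energy_feature_names(channel_names, max_imfs)
    if method == "dwt-energy":
        return _wavelet.dwt_energy_feature_names(channel_names, levels)
    raise ConfigurationError(f"unknown method {method!r}; expected {METHODS}")


def build_feature_table(
    segments,
    method: str = "hybrid",
    max_imfs: int = 8,
    wavelet: str = _wavelet.DEFAULT_WAVELET,
    levels: int = _wavelet.DEFAULT_LEVELS,
) -> FeatureTable:
    """Assemble one feature row per labeled segment into a table.

    All segments must share the montage and length, and carry a high/low
    interest label (moderate subjects are excluded before this point).
    """
    segments = list(segments)
    if not segments:
        raise ConfigurationError("no segments to featurize")
    montage = segments[0].channel_names
    n_samples = segments[0].n_samples
    for seg in segments:
        if seg.channel_names != montage:
            raise ConfigurationError(
                f"mixed montages: {seg.channel_names} vs {montage}"
            )
        if seg.n_samples != n_samples:
            raise ConfigurationError(
                f"mixed segment lengths: {seg.n_samples} vs {n_samples}"
            )
        if seg.label is None or seg.label.value not in ("high", "low"):
            raise ConfigurationError(
                f"segment {seg.subject_id!r} lacks a high/low label"
            )
    names = feature_names(montage, method, max_imfs, levels)
    rows = [extract_features(seg, method, max_imfs, wavelet, levels)
            for seg in segments]
    frame = pd.DataFrame(rows, columns=names)
    frame["label"] = [seg.label.value for seg in segments]
    return FeatureTable(
        frame=frame,
        method=method,
        subject_ids=tuple(seg.subject_id for seg in segments),
    )
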