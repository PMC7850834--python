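"""Welch band-power analysis.

Power spectral densities are estimated with Welch's averaged modified
periodogram (Hann window, 8 windows at 50% overlap by default), integrated
over the classical EEG rhythm bands, averaged over scalp regions, and
expressed as percent change of a task condition against baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_signals import ConfigurationError, DomainError

#: Rhythm band edges in Hz.  The gaps at 4-5, 7-8 and 12-13 Hz follow the
#: band table this pipeline standardises on; edges are configurable.
DEFAULT_BANDS: tuple["BandDefinition", ...]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise DomainError(f"invalid band {self.name}: "
                              f"[{self.f_lo}, {self.f_hi}]")


DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 5.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 47.0),
)

#: Scalp regions -> member channels (T7/T8 are the modern names of T3/T4).
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F3", "F4"),
    "temporal": ("T7", "T8"),
    "occipital": ("O1", "O2"),
}


@dataclass
class PSDEstimate:
    freqs: np.ndarray            # Hz, strictly increasing
    power: np.ndarray            # channels x freqs, uV^2/Hz
    n_welch_segments: int
    overlap_fraction: float
    window_name: str
    channel_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegionBandPower:
    region: str
    band: str
    value: float


def welch_psd(seg, n_welch_segments: int = 8, overlap: float = 0.5,
              window: str = "hann") -> PSDEstimate:
    """Welch PSD per channel (one-sided density, uV^2/Hz).

    The window length is chosen so exactly ``n_welch_segments`` windows at
    the given overlap tile the segment; each window is mean-detrended.
    """
    x = np.atleast_2d(np.asarray(seg.data, dtype=float))
    denom = 1 + (n_welch_segments - 1) * (1 - overlap)
    nperseg = int(x.shape[-1] // denom)
    if nperseg < 8:
        raise DomainError(
            f"segment of {x.shape[-1]} samples too short for "
            f"{n_welch_segments} Welch windows (needs >= {int(8 * denom)})"
        )
    freqs, power = sps.welch(
        x, fs=seg.fs, window=window, nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant",
        scaling="density", axis=-1,
    )
    return PSDEstimate(
        freqs=freqs, power=power, n_welch_segments=n_welch_segments,
        overlap_fraction=overlap, window_name=window,
        channel_names=tuple(getattr(seg, "channel_names", ())),
    )


def band_power(psd: PSDEstimate, band: BandDefinition) -> np.ndarray:
    """Integrate the PSD over ``[f_lo, f_hi]`` per channel (trapezoids).

    The band edges are included exactly by linear interpolation of the PSD
    at the edges, so band powers are additive over adjacent bands.
    """
    if band.f_lo < psd.freqs[0] - 1e-9 or band.f_hi > psd.freqs[-1] + 1e-9:
        raise DomainError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] outside PSD range "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}]"
        )
    inner = (psd.freqs > band.f_lo) & (psd.freqs < band.f_hi)
    f = np.concatenate(([band.f_lo], psd.freqs[inner], [band.f_hi]))
    powers = np.empty(psd.power.shape[0])
    for ch in range(psd.power.shape[0]):
        p_edge = np.interp([band.f_lo, band.f_hi], psd.freqs, psd.power[ch])
        p = np.concatenate(([p_edge[0]], psd.power[ch, inner], [p_edge[1]]))
        powers[ch] = np.trapezoid(p, f)
    return powers


def percent_change(condition_power: float, baseline_power: float) -> float:
    """Relative band-power change, in percent.

    Positive means an increase during the task condition:
    ``100 * (condition - baseline) / baseline``.
    """
    if baseline_power <= 0:
        raise DomainError(f"baseline power must be > 0, got {baseline_power}")
    return 100.0 * (condition_power - baseline_power) / baseline_power


def regional_average(
    values: dict[str, float],
    regions: dict[str, tuple[str, ...]] | None = None,
    band: str = "",
) -> list[RegionBandPower]:
    """Arithmetic mean of per-channel values over each scalp region."""
    regions = regions if regions is not None else REGIONS
    out = []
    for region, channels in regions.items():
        missing = [c for c in channels if c not in values]
        if missing:
            raise ConfigurationError(
                f"region {region!r} missing channel(s) {missing}"
            )
        out.append(RegionBandPower(
            region=region, band=band,
            value=float(np.mean([values[c] for c in channels])),
        ))
    return out
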