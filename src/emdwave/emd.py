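"""Empirical mode decomposition by cubic-spline envelope sifting.

EMD writes a signal as a finite sum of intrinsic mode functions (IMFs)
plus a monotonic residue.  An IMF is a locally zero-mean oscillation: its
numbers of extrema and zero-crossings differ by at most one, and the mean
of its upper and lower cubic-spline envelopes is (approximately) zero.
Sifting repeatedly subtracts that envelope mean until both conditions are
met; the accepted IMF is removed from the signal and the process repeats
on the remainder until it becomes monotonic or a mode cap is reached.

Numerical choices (the classical procedure leaves them open):

* stopping: Huang's aggregate standard-deviation criterion
  ``SD = sum((h_prev - h)**2) / sum(h_prev**2) < 0.2`` together with the
  IMF counting condition, capped at 100 sifting passes;
* envelopes: not-a-knot cubic splines through the extrema, with the two
  extrema nearest each edge mirrored outside the signal to tame end
  swings;
* plateaus: the first sample of a flat run counts as the extremum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .io_signals import DomainError

DEFAULT_SD_THRESHOLD = 0.2
DEFAULT_MAX_SIFT_ITERS = 100


class NotSiftableError(DomainError):
    """Signal has too few extrema to sift (treated as a residue)."""


@dataclass
class IMFSet:
    """Ordered IMFs (high to low frequency) plus the residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int]
    input_length: int

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior maxima and minima, plateau -> its first sample."""
    d = np.diff(x)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # backward-fill zero slopes with the next nonzero slope so that the
    # transition lands on the first sample of a plateau
    rev = s[::-1]
    idx = np.where(rev != 0, np.arange(rev.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = rev[idx][::-1]
    trans = np.diff(filled)
    maxima = np.flatnonzero(trans < 0) + 1
    minima = np.flatnonzero(trans > 0) + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _is_imf(x: np.ndarray, n_maxima: int, n_minima: int) -> bool:
    return abs((n_maxima + n_minima) - _zero_crossings(x)) <= 1


def _envelope(idx: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirrored at both edges."""
    k = min(2, idx.size)
    t_left = -idx[:k][::-1]
    t_right = 2 * (n - 1) - idx[-k:][::-1]
    t = np.concatenate([t_left, idx, t_right])
    v = np.concatenate([values[idx[:k]][::-1], values[idx],
                        values[idx[-k:]][::-1]])
    t, keep = np.unique(t, return_index=True)
    v = v[keep]
    return CubicSpline(t, v)(np.arange(n))


def sift_imf(
    x: np.ndarray,
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> tuple[np.ndarray, int]:
    """Extract one IMF from ``x`` by iterative envelope-mean subtraction.

    Returns the IMF and the number of sifting passes used.

    Raises
    ------
    NotSiftableError
        If ``x`` has fewer than two maxima or two minima; the caller then
        treats ``x`` as the residue.
    """
    x = np.asarray(x, dtype=float)
    h = x.copy()
    n = h.size
    maxima, minima = _local_extrema(h)
    if maxima.size < 2 or minima.size < 2:
        raise NotSiftableError(
            f"signal has {maxima.size} maxima / {minima.size} minima; "
            "cannot sift"
        )
    n_iters = 0
    for _ in range(max_sift_iters):
        upper = _envelope(maxima, h, n)
        lower = _envelope(minima, h, n)
        m = 0.5 * (upper + lower)
        denom = float(np.sum(h * h))
        h = h - m
        n_iters += 1
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break
        if sd < sd_threshold and _is_imf(h, maxima.size, minima.size):
            break
    return h, n_iters


def emd_decompose(
    x: np.ndarray,
    max_imfs: int = 8,
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> IMFSet:
    """Decompose ``x`` into at most ``max_imfs`` IMFs plus a residue.

    The residue is the running remainder of the input after subtracting
    each accepted IMF, so the additive reconstruction
    ``sum(imfs) + residue == x`` holds to floating-point round-off by
    construction.  Decomposition stops when the remainder is monotonic
    (fewer than two maxima or minima), negligibly small, or the mode cap
    is reached; remaining oscillation is folded into the residue.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DomainError("emd_decompose expects a 1-D signal")
    if x.size < 16:
        raise DomainError(f"signal of {x.size} samples too short for EMD")
    if not np.isfinite(x).all():
        raise DomainError("signal contains NaN or Inf")
    scale = float(np.max(np.abs(x)))
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    r = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(r)
        if maxima.size < 2 or minima.size < 2:
            break
        imf, n_it = sift_imf(r, max_sift_iters, sd_threshold)
        if scale > 0 and float(np.max(np.abs(imf))) < 1e-12 * scale:
            break
        imfs.append(imf)
        counts.append(n_it)
        r = r - imf
    return IMFSet(imfs=imfs, residue=r, sift_counts=counts,
                  input_length=x.size)


def imf_energies(dec: IMFSet, max_imfs: int = 8) -> np.ndarray:
    """Per-IMF energies ``sum(c_j**2)``, zero-padded to ``max_imfs``."""
    out = np.zeros(max_imfs)
    for j, imf in enumerate(dec.imfs[:max_imfs]):
        out[j] = float(np.sum(imf * imf))
    return out


def emd_energy_features(seg, max_imfs: int = 8) -> np.ndarray:
    """IMF-energy feature row: ``n_channels * max_imfs`` values.

    Per channel, the energies of IMFs 1..max_imfs (channels decomposing
    into fewer modes contribute zeros), concatenated channel-major —
    64 features for the 8-channel montage.
    """
    data = np.asarray(seg.data, dtype=float)
    if data.size == 0:
        raise DomainError("empty segment")
    rows = []
    for ch in range(data.shape[0]):
        x = data[ch]
        if not np.any(x):
            rows.append(np.zeros(max_imfs))
            continue
        rows.append(imf_energies(emd_decompose(x, max_imfs=max_imfs),
                                 max_imfs))
    return np.concatenate(rows)


def emd_energy_feature_names(channel_names, max_imfs: int = 8) -> list[str]:
    return [f"{ch}_imf{j + 1}_energy"
            for ch in channel_names for j in range(max_imfs)]
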