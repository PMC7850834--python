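"""Synthetic classroom-EEG generation.

Generates labeled 8-channel segments whose two interest classes differ
primarily in frontal delta-band power — the discriminating structure the
analysis pipeline is designed to detect.  Each channel is a sum of
band-limited Gaussian noise processes (one per EEG rhythm, scaled to a
target microvolt RMS), eye-blink transients on the frontal-polar
channels, a 50 Hz mains sinusoid, and broadband white noise.  The *low*
interest class carries ``delta_effect`` times the delta amplitude on the
frontal channels, emulating the stronger frontal delta increase reported
for unengaged students.

What this emulates and what it does not: the spectra, artifact types and
class contrast of real classroom EEG are present; volume conduction,
non-stationarity, inter-subject variability and genuine 1/f background
are not.  Pipeline results on these data demonstrate correctness of the
implementation, not field performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_signals import MONTAGE, DomainError, EEGRecording, assign_interest_label
from .preprocess import Segment, bandpass_fir
from .spectral import DEFAULT_BANDS

#: Questionnaire scores attached to generated subjects; chosen inside the
#: high (>77) and low (<69) questionnaire bands.
CLASS_SCORES = {"high": 85.0, "low": 60.0}

FRONTAL = ("Fp1", "Fp2", "F3", "F4")
BLINK_CHANNELS = ("Fp1", "Fp2")


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults emulate a 154 s classroom recording."""

    fs: float = 500.0
    channel_names: tuple[str, ...] = MONTAGE
    duration_s: float = 154.0
    #: per-band RMS amplitude in microvolts (eyes-open resting defaults)
    band_rms: dict[str, float] = field(default_factory=lambda: {
        "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 8.0,
        "gamma": 4.0,
    })
    #: frontal delta amplitude multiplier applied to the "low" class
    delta_effect: float = 3.0
    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 100.0
    line_noise_amp_uv: float = 5.0
    broadband_noise_sd_uv: float = 5.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise DomainError("fs and duration_s must be positive")
        if self.delta_effect <= 0:
            raise DomainError("delta_effect must be > 0")
        if any(v < 0 for v in self.band_rms.values()):
            raise DomainError("band RMS amplitudes must be >= 0")
        if min(self.blink_rate_per_min, self.blink_amplitude_uv,
               self.line_noise_amp_uv, self.broadband_noise_sd_uv) < 0:
            raise DomainError("rates and amplitudes must be >= 0")
        edges = {b.name: b.f_hi for b in DEFAULT_BANDS}
        unknown = set(self.band_rms) - set(edges)
        if unknown:
            raise DomainError(f"unknown band name(s): {sorted(unknown)}")
        top = max((edges[name] for name in self.band_rms), default=0.0)
        if self.band_rms and self.fs <= 2 * top:
            raise DomainError(
                f"fs={self.fs} must exceed twice the highest band edge {top}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _band_noise(rng: np.random.Generator, spec: SyntheticSpec,
                f_lo: float, f_hi: float) -> np.ndarray:
    """Band-limited unit-RMS Gaussian noise, one row per channel."""
    white = rng.standard_normal((spec.n_channels, spec.n_samples))
    shell = Segment(data=white, fs=spec.fs,
                    channel_names=spec.channel_names)
    filtered = bandpass_fir(shell, f_lo, f_hi).data
    rms = np.sqrt(np.mean(filtered**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return filtered / rms


def _blink_train(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """Bi-exponential blink pulses (50 ms rise, 300 ms decay) at Poisson times."""
    n = spec.n_samples
    out = np.zeros(n)
    n_events = rng.poisson(spec.blink_rate_per_min * spec.duration_s / 60.0)
    if n_events == 0 or spec.blink_amplitude_uv == 0:
        return out
    t_pulse = np.arange(0, 1.2, 1.0 / spec.fs)
    pulse = np.exp(-t_pulse / 0.3) - np.exp(-t_pulse / 0.05)
    pulse *= spec.blink_amplitude_uv / pulse.max()
    starts = np.sort(rng.integers(0, max(1, n - pulse.size), size=n_events))
    for s in starts:
        end = min(n, s + pulse.size)
        out[s:end] += pulse[: end - s]
    return out


def generate_segment(spec: SyntheticSpec, class_label: str,
                     seed: int) -> Segment:
    """One labeled synthetic segment; bit-reproducible from ``seed``."""
    if class_label not in CLASS_SCORES:
        raise DomainError(f"class_label must be high|low, got {class_label!r}")
    rng = np.random.default_rng(seed)
    data = np.zeros((spec.n_channels, spec.n_samples))
    frontal_idx = [i for i, c in enumerate(spec.channel_names)
                   if c in FRONTAL]
    band_edges = {b.name: (b.f_lo, b.f_hi) for b in DEFAULT_BANDS}
    for name, rms in spec.band_rms.items():
        if rms == 0:
            continue
        f_lo, f_hi = band_edges[name]
        noise = _band_noise(rng, spec, f_lo, f_hi) * rms
        if name == "delta" and class_label == "low" and frontal_idx:
            noise[frontal_idx] *= spec.delta_effect
        data += noise
    if spec.blink_amplitude_uv > 0 and spec.blink_rate_per_min > 0:
        blink = _blink_train(rng, spec)
        for i, c in enumerate(spec.channel_names):
            if c in BLINK_CHANNELS:
                data[i] += blink
    if spec.line_noise_amp_uv > 0:
        t = np.arange(spec.n_samples) / spec.fs
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_channels)
        data += spec.line_noise_amp_uv * np.sin(
            2 * np.pi * 50.0 * t[None, :] + phases[:, None]
        )
    if spec.broadband_noise_sd_uv > 0:
        data += spec.broadband_noise_sd_uv * rng.standard_normal(data.shape)
    return Segment(
        data=data,
        fs=spec.fs,
        channel_names=spec.channel_names,
        subject_id=f"{class_label}-{seed}",
        condition="lecture",
        label=assign_interest_label(CLASS_SCORES[class_label]),
    )


def generate_dataset(
    spec: SyntheticSpec, n_per_class: int, seed: int
) -> list[Segment]:
    """Balanced dataset of ``2 * n_per_class`` segments, seeds split from
    ``seed`` so streams are independent and the whole set reproducible."""
    if n_per_class < 1:
        raise DomainError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_class)
    segments = []
    for i, child in enumerate(children):
        label = "high" if i % 2 == 0 else "low"
        child_seed = int(child.generate_state(1)[0]) % (2**31)
        seg = generate_segment(spec, label, child_seed)
        seg = replace(seg, subject_id=f"{label}{i // 2:02d}")
        segments.append(seg)
    return segments


def write_dataset(segments: list[Segment], out_dir: str | Path) -> Path:
    """Write each segment as an EDF+ file plus a labels/intervals CSV."""
    from .io_signals import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id,file,label,score,start_s,end_s"]
    for seg in segments:
        rec = EEGRecording(
            data=seg.data, fs=seg.fs, channel_names=seg.channel_names,
            annotations=[("lecture", 0.0, seg.n_samples / seg.fs)],
        )
        fname = f"{seg.subject_id}.edf"
        write_edf(rec, out_dir / fname)
        rows.append(
            f"{seg.subject_id},{fname},{seg.label.value},{seg.label.score},"
            f"0.0,{seg.n_samples / seg.fs}"
        )
    manifest = out_dir / "labels.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
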