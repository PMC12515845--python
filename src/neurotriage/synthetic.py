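"""Seeded synthetic 3-channel prefrontal EEG cohorts.

The generator emulates the statistical structure the screening pipeline
assumes: two classes (healthy controls, HC, and depressed patients, MDD)
that differ in alpha/beta-band oscillatory power and in broadband signal
complexity, on top of a 1/f (pink) background.  Depressed patients show
elevated alpha/beta power and higher-entropy (noisier) traces relative to
controls, which is the contrast the downstream sample-entropy features are
designed to pick up.

Each subject draws one sinusoid per canonical band (delta, theta, alpha,
beta) with a frequency uniform inside the band; the frequency is fixed per
subject so that successive 1-s analysis windows of the same subject remain
correlated, which is exactly the leakage hazard the time-ordered split in
:mod:`neurotriage.model_eval` exists to guard against.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .recording import (
    DEFAULT_CHANNELS,
    LABEL_HC,
    LABEL_MDD,
    MultichannelRecording,
    VALID_LABELS,
)

#: Canonical EEG frequency bands (Hz), inside the 1-45 Hz analysis band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Spectral recipe for one class of subjects.

    ``band_amplitudes`` maps band name to sinusoid amplitude in microvolts;
    ``pink_noise_scale`` / ``white_noise_scale`` are the standard deviations
    (microvolts) of the 1/f and white background components;
    ``amplitude_jitter`` is the fractional per-subject multiplicative
    variation applied independently to each band amplitude.
    """

    band_amplitudes: dict[str, float]
    pink_noise_scale: float = 2.0
    white_noise_scale: float = 1.0
    amplitude_jitter: float = 0.1
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))

    def __post_init__(self) -> None:
        for name, amp in self.band_amplitudes.items():
            if name not in self.bands:
                raise ValueError(f"unknown band {name!r}")
            if amp < 0:
                raise ValueError(f"band amplitude for {name!r} must be >= 0")
        if self.pink_noise_scale < 0 or self.white_noise_scale < 0:
            raise ValueError("noise scales must be >= 0")
        if self.amplitude_jitter < 0:
            raise ValueError("amplitude_jitter must be >= 0")
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi <= 45.0):
                raise ValueError(f"band {name!r} edges must satisfy 0 < lo < hi <= 45")


def default_profile(label: str) -> ClassSpectralProfile:
    """Default class profiles.

    Controls carry (delta, theta, alpha, beta) amplitudes (4, 3, 3, 2) uV;
    patients (4, 3, 5, 4) uV with 1.5x the white-noise floor, so the classes
    are separable in alpha/beta power and entropy but overlap at the subject
    level through the per-subject amplitude jitter.
    """
    if label == LABEL_HC:
        return ClassSpectralProfile(
            band_amplitudes={"delta": 4.0, "theta": 3.0, "alpha": 3.0, "beta": 2.0},
            pink_noise_scale=2.0,
            white_noise_scale=1.0,
        )
    if label == LABEL_MDD:
        return ClassSpectralProfile(
            band_amplitudes={"delta": 4.0, "theta": 3.0, "alpha": 5.0, "beta": 4.0},
            pink_noise_scale=2.0,
            white_noise_scale=1.5,
        )
    raise ValueError(f"label must be one of {VALID_LABELS}")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance pink noise via 1/sqrt(f) spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spec[0] = 0.0  # no DC
    spec[1:] /= np.sqrt(f[1:])
    pink = np.fft.irfft(spec, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def generate_recording(
    label: str,
    duration_s: float,
    fs: float,
    profile: ClassSpectralProfile | None = None,
    seed: int = 0,
    subject_id: str | None = None,
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS,
) -> MultichannelRecording:
    """Generate one subject's synthetic recording.

    Each channel is the sum, over bands, of a sinusoid with frequency
    drawn uniformly inside the band (independently per channel, so the
    three prefrontal sites behave as distinct local oscillators), a random
    phase, and amplitude equal to the band amplitude times a per-subject
    jitter factor, plus pink and white noise.  The same ``seed`` yields a
    bitwise-identical recording.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if profile is None:
        profile = default_profile(label)
    highest_edge = max(hi for _, hi in profile.bands.values())
    if fs <= 2 * highest_edge:
        raise ValueError(
            f"fs={fs} must exceed twice the highest band edge ({highest_edge} Hz)"
        )

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    n_ch = len(channel_names)
    t = np.arange(n) / fs

    band_names = sorted(profile.band_amplitudes)
    x = np.zeros((n_ch, n))
    for name in band_names:
        lo, hi = profile.bands[name]
        # one independent oscillator per channel, fixed for the whole
        # recording (per subject, not per window)
        freqs = rng.uniform(lo, hi, size=n_ch)
        j = profile.amplitude_jitter
        jitter = rng.uniform(1.0 - j, 1.0 + j) if j > 0 else 1.0
        amp = profile.band_amplitudes[name] * jitter
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
        x += amp * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    for c in range(n_ch):
        if profile.pink_noise_scale > 0:
            x[c] += profile.pink_noise_scale * _pink_noise(rng, n)
        if profile.white_noise_scale > 0:
            x[c] += profile.white_noise_scale * rng.standard_normal(n)

    if subject_id is None:
        subject_id = f"{label}-s{seed}"
    return MultichannelRecording(
        samples=x, fs=fs, channel_names=channel_names,
        subject_id=subject_id, label=label,
    )


def generate_cohort(
    n_hc: int,
    n_mdd: int,
    duration_s: float = 90.0,
    fs: float = 250.0,
    seed: int = 0,
    hc_profile: ClassSpectralProfile | None = None,
    mdd_profile: ClassSpectralProfile | None = None,
) -> list[MultichannelRecording]:
    """Generate ``n_hc`` control then ``n_mdd`` patient recordings.

    Subject ``i`` (0-based over the whole cohort) uses sub-seed
    ``seed + i``, so cohorts are reproducible and subjects distinct.
    """
    if n_hc < 0 or n_mdd < 0:
        raise ValueError("cohort counts must be non-negative")
    if n_hc + n_mdd < 1:
        raise ValueError("cohort must contain at least one subject")
    recs: list[MultichannelRecording] = []
    for i in range(n_hc + n_mdd):
        label = LABEL_HC if i < n_hc else LABEL_MDD
        k = i if i < n_hc else i - n_hc
        recs.append(
            generate_recording(
                label,
                duration_s,
                fs,
                profile=hc_profile if label == LABEL_HC else mdd_profile,
                seed=seed + i,
                subject_id=f"{label}{k + 1:02d}",
            )
        )
    return recs


# ---------------------------------------------------------------------------
# Writers (CSV and EDF); the matching readers live in neurotriage.preprocess.
# ---------------------------------------------------------------------------

def write_csv(rec: MultichannelRecording, path: str | Path) -> None:
    """Write one subject as CSV: header row of channel names, one row per
    time point, full float precision (lossless round-trip)."""
    header = ",".join(rec.channel_names)
    np.savetxt(path, rec.samples.T, delimiter=",", header=header,
               comments="", fmt="%.17g")


def write_edf(rec: MultichannelRecording, path: str | Path) -> None:
    """Write one subject as a 16-bit EDF file.

    Minimal EDF encoder: one 1-s data record per second when the duration
    is a whole number of seconds with an integer sampling rate, otherwise a
    single record spanning the recording.  Physical dimension is uV;
    amplitudes are quantized to 16 bits over a symmetric range, so the
    round-trip is accurate to ~0.01% of the peak amplitude.
    """
    n_sig = rec.n_channels
    n = rec.n_samples
    fs = rec.fs
    whole_seconds = (
        float(fs).is_integer() and n % int(fs) == 0 and n // int(fs) >= 1
    )
    if whole_seconds:
        n_records = n // int(fs)
        record_dur = 1.0
        spr = int(fs)  # samples per record per signal
    else:
        n_records = 1
        record_dur = n / fs
        spr = n

    pmax = float(np.max(np.abs(rec.samples)))
    if pmax == 0.0:
        pmax = 1.0
    dig = np.clip(np.round(rec.samples / pmax * 32767.0), -32768, 32767).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),
        pad(rec.subject_id or "X", 80),
        pad(f"Startdate 01-JAN-2000 {rec.label or 'X'}", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (n_sig + 1)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad(f"{record_dur:g}", 8),
        pad(str(n_sig), 4),
    ])
    fields = [
        (16, list(rec.channel_names)),
        (80, ["synthetic EEG"] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [f"{-pmax:.6g}"[:8]] * n_sig),
        (8, [f"{pmax:.6g}"[:8]] * n_sig),
        (8, ["-32768"] * n_sig),
        (8, ["32767"] * n_sig),
        (80, [""] * n_sig),
        (8, [str(spr)] * n_sig),
        (32, [""] * n_sig),
    ]
    sig_header = b"".join(
        b"".join(pad(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = dig[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
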