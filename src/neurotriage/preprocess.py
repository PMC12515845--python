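"""Recording I/O, band-pass filtering and fixed-length windowing.

The screening protocol records 90 s of resting-state EEG at 250 Hz from
Fp1/Fpz/Fp2, band-passes it to 1-45 Hz with a linear-phase FIR filter, and
cuts each recording into non-overlapping 1-s analysis windows (90 windows
per subject; 4,950 over a 55-subject cohort).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import DEFAULT_CHANNELS, MultichannelRecording


class RecordingIOError(Exception):
    """A recording file could not be read as requested."""


class ChannelCountError(RecordingIOError):
    """The file does not contain the expected number of channels."""


def read_recording(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    n_channels: int | None = None,
    subject_id: str | None = None,
    label: str | None = None,
) -> MultichannelRecording:
    """Read one subject's recording from ``csv`` or ``edf``.

    CSV files carry no sampling-rate metadata, so ``fs`` must be supplied
    (the CLI exposes it as ``--fs``); EDF files carry their own rate and
    channel names.  ``n_channels`` enforces the expected channel count.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingIOError(f"no such recording file: {path}")
    if format == "csv":
        if fs is None:
            raise RecordingIOError("CSV carries no rate metadata; supply fs")
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # malformed text
            raise RecordingIOError(f"could not parse {path} as CSV: {exc}") from exc
        if frame.empty or frame.shape[1] == 0:
            raise RecordingIOError(f"{path} contains no samples")
        if not all(frame.dtypes.apply(lambda d: np.issubdtype(d, np.number))):
            raise RecordingIOError(f"{path} has non-numeric columns")
        samples = frame.to_numpy(dtype=np.float64).T
        names = tuple(str(c) for c in frame.columns)
    elif format == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:
            raise RecordingIOError(f"could not parse {path} as EDF: {exc}") from exc
        samples = raw.get_data() * 1e6  # mne returns volts; the package uses uV
        names = tuple(raw.ch_names)
        fs = float(raw.info["sfreq"])
    else:
        raise RecordingIOError(f"unknown recording format {format!r}")

    if n_channels is not None and samples.shape[0] != n_channels:
        raise ChannelCountError(
            f"{path}: expected {n_channels} channels, found {samples.shape[0]}"
        )
    if not np.all(np.isfinite(samples)):
        raise RecordingIOError(f"{path} contains non-finite samples")
    return MultichannelRecording(
        samples=samples, fs=fs, channel_names=names,
        subject_id=subject_id if subject_id is not None else path.stem,
        label=label,
    )


def design_bandpass(low_hz: float, high_hz: float, fs: float,
                    order: int = 250) -> np.ndarray:
    """Window-method linear-phase FIR band-pass (Hamming), ``order`` taps + 1.

    The default order of 250 puts the filter length at 1 s for 250 Hz data,
    giving a ~3 Hz transition band and >50 dB stopband per pass.
    """
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2, got "
            f"({low_hz}, {high_hz}) at fs={fs}"
        )
    return sps.firwin(order + 1, [low_hz, high_hz], pass_zero=False,
                      window="hamming", fs=fs)


def bandpass_filter(
    rec: MultichannelRecording,
    low_hz: float = 1.0,
    high_hz: float = 45.0,
    order: int = 250,
) -> MultichannelRecording:
    """Zero-phase 1-45 Hz FIR band-pass.

    The linear-phase kernel is applied forward-backward (``filtfilt``) so
    the net phase is zero; entropy features downstream are sensitive to
    waveform shape, which latency distortion would corrupt.  Output length
    equals input length.
    """
    taps = design_bandpass(low_hz, high_hz, rec.fs, order=order)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    filtered = sps.filtfilt(taps, [1.0], rec.samples, axis=-1, padlen=padlen)
    return MultichannelRecording(
        samples=filtered, fs=rec.fs, channel_names=rec.channel_names,
        subject_id=rec.subject_id, label=rec.label,
    )


@dataclass
class WindowSet:
    """Fixed-length analysis windows in acquisition order.

    ``data`` has shape ``(n_windows, n_channels, window_samples)``; the
    parallel arrays give each window's source subject, within-subject index
    and class label.  ``order_index`` is the global acquisition order,
    monotone over subjects then windows — row ``i`` of any feature table
    derived from this set was recorded no later than row ``i+1``.
    """

    data: np.ndarray
    fs: float
    subject_ids: np.ndarray
    window_indices: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("window data must be (n_windows, channels, samples)")
        n = self.data.shape[0]
        for arr_name in ("subject_ids", "window_indices", "labels"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length does not match window count")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def order_index(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    @classmethod
    def concatenate(cls, parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            raise ValueError("cannot concatenate an empty list of window sets")
        fs = parts[0].fs
        names = parts[0].channel_names
        for p in parts:
            if p.fs != fs or p.channel_names != names:
                raise ValueError("window sets disagree on fs or channel names")
        return cls(
            data=np.concatenate([p.data for p in parts], axis=0),
            fs=fs,
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            window_indices=np.concatenate([p.window_indices for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            channel_names=names,
        )


def segment_windows(
    rec: MultichannelRecording,
    window_s: float = 1.0,
    step_s: float = 1.0,
) -> WindowSet:
    """Cut one recording into sliding windows of ``window_s`` seconds.

    Windows start at 0, step, 2*step, ... and are emitted only when fully
    inside the recording (no padding), so the count is
    ``floor((duration - window)/step) + 1``.  The default step equals the
    window (non-overlapping), which yields 90 windows from a 90-s
    recording.  Sample coordinates are 0-based half-open.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    win = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    if win < 1 or step < 1:
        raise ValueError("window and step must be at least one sample")
    if win > rec.n_samples:
        raise ValueError(
            f"window of {win} samples exceeds recording length {rec.n_samples}"
        )
    n_win = (rec.n_samples - win) // step + 1
    starts = np.arange(n_win) * step
    data = np.stack([rec.samples[:, s:s + win] for s in starts], axis=0)
    return WindowSet(
        data=data,
        fs=rec.fs,
        subject_ids=np.array([rec.subject_id] * n_win, dtype=object),
        window_indices=np.arange(n_win, dtype=np.int64),
        labels=np.array([rec.label] * n_win, dtype=object),
        channel_names=rec.channel_names,
    )


def segment_cohort(
    recs: list[MultichannelRecording],
    window_s: float = 1.0,
    step_s: float = 1.0,
) -> WindowSet:
    """Segment every recording and concatenate, subjects in list order."""
    return WindowSet.concatenate(
        [segment_windows(r, window_s, step_s) for r in recs]
    )
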