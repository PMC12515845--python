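"""Labeled multichannel EEG recording container.

Amplitudes are in microvolts throughout the package; sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Prefrontal electrode sites of the 10-20 system used by 3-lead headsets.
DEFAULT_CHANNELS: tuple[str, ...] = ("Fp1", "Fpz", "Fp2")

#: Class labels: healthy controls and major depressive disorder patients.
LABEL_HC = "HC"
LABEL_MDD = "MDD"
VALID_LABELS = (LABEL_HC, LABEL_MDD)


@dataclass
class MultichannelRecording:
    """One subject's EEG time series.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz, strictly positive.
    channel_names
        Ordered channel labels; length must equal ``n_channels``.
    subject_id
        Free-form subject identifier.
    label
        ``"HC"``, ``"MDD"`` or ``None`` when unknown.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        self.channel_names = tuple(self.channel_names)
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS} or None")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds."""
        return self.samples.shape[1] / self.fs
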