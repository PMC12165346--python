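"""Core container for multichannel EEG recordings.

A recording is a channels-by-samples matrix in microvolts together with its
sampling rate, electrode labels, a binary class label (0 = pre sleep
deprivation, 1 = post) and an opaque subject identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGRecording"]


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG signal with metadata.

    Parameters
    ----------
    signal
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz; must be positive.
    channel_names
        Unique electrode labels, one per row of ``signal``.
    label
        Class identifier (0 = pre-deprivation, 1 = post-deprivation).
    subject_id
        Opaque subject identifier.
    """

    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    label: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError(f"signal must be 2-D (channels x samples), got shape {sig.shape}")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if sig.shape[0] < 1 or sig.shape[1] < 1:
            raise ValueError("recording must contain at least one channel and one sample")
        if len(self.channel_names) != sig.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {sig.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray) -> "EEGRecording":
        """Return a copy carrying ``signal`` with the same metadata."""
        return replace(self, signal=signal)

    def pick(self, names: list[str] | tuple[str, ...]) -> "EEGRecording":
        """Restrict to the named channels, in the requested order."""
        idx = []
        for name in names:
            if name not in self.channel_names:
                raise KeyError(f"unknown channel {name!r}")
            idx.append(self.channel_names.index(name))
        return replace(
            self, signal=self.signal[idx, :], channel_names=tuple(names)
        )
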