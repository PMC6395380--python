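"""Core containers for continuous recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import normalize_label

#: The four reach directions.
DIRECTIONS: tuple[str, ...] = ("L", "R", "T", "B")

CONDITIONS: tuple[str, ...] = ("visual", "auditory")


@dataclass
class Event:
    """One trial: premovement onset sample, direction label, condition tag."""

    onset: int
    label: str
    condition: str


@dataclass
class RawSession:
    """Continuous multichannel EEG with trial events.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    channel_labels : list of str
        Montage labels in acquisition order (includes the reference).
    events : list of Event
        Trial onsets, strictly increasing.
    sample_rate : float
        Sampling frequency in Hz.
    """

    data: np.ndarray
    channel_labels: list[str]
    events: list[Event]
    sample_rate: float
    epoch_length: float = 4.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_labels = [normalize_label(c) for c in self.channel_labels]
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data rows")
        onsets = [ev.onset for ev in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def condition(self) -> str:
        return self.events[0].condition if self.events else "visual"
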