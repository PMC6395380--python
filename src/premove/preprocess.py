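"""Band-pass filtering, premovement epoch extraction, noisy channel/trial rejection.

The 1.5-4 Hz band isolates the slow components that carry direction
information when raw time-point amplitudes are used as features; the
high-pass edge also conditions the data for ICA. Rejection replaces manual
visual inspection with a deterministic robust-threshold procedure so runs
are reproducible; every removal is logged with the statistic that caused it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .montage import REFERENCE_CHANNEL, normalize_label
from .session import RawSession


@dataclass
class EpochSet:
    """Premovement trials: trials x channels x samples plus labels and a
    rejection log that fully reconstructs what was kept and why."""

    data: np.ndarray
    labels: np.ndarray                    # per-trial direction in {L,R,T,B}
    condition: str
    sample_rate: float
    kept_channel_labels: list[str]
    rejection_log: list[dict] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def bandpass_filter(raw: RawSession, low: float = 1.5, high: float = 4.0) -> RawSession:
    """Zero-phase 4th-order Butterworth band-pass, applied per channel.

    Forward-backward filtering keeps window boundaries time-locked (no group
    delay). Output length equals input length.
    """
    nyq = raw.sample_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < {nyq}")
    sos = scipy.signal.butter(
        4, [low, high], btype="bandpass", fs=raw.sample_rate, output="sos"
    )
    out = RawSession(
        data=scipy.signal.sosfiltfilt(sos, raw.data, axis=-1),
        channel_labels=list(raw.channel_labels),
        events=list(raw.events),
        sample_rate=raw.sample_rate,
        epoch_length=raw.epoch_length,
        meta=dict(raw.meta),
    )
    return out


def extract_epochs(raw: RawSession, drop_reference: bool = True) -> EpochSet:
    """Slice one epoch per event, sample 0 at premovement onset, half-open
    [0, epoch_length) in seconds.

    The reference channel (A2) is dropped from the analysis set. Trials
    truncated by the recording edge are dropped and logged.
    """
    n_ep = int(round(raw.epoch_length * raw.sample_rate))
    keep_idx = [
        i
        for i, ch in enumerate(raw.channel_labels)
        if not (drop_reference and normalize_label(ch) == REFERENCE_CHANNEL)
    ]
    kept_labels = [raw.channel_labels[i] for i in keep_idx]

    log: list[dict] = []
    trials = []
    labels = []
    for t, ev in enumerate(raw.events):
        if ev.onset < 0 or ev.onset + n_ep > raw.n_samples:
            log.append(
                {
                    "entity": "trial",
                    "index": t,
                    "reason": "truncated at recording edge",
                    "statistic": float(ev.onset),
                }
            )
            continue
        trials.append(raw.data[np.ix_(keep_idx, range(ev.onset, ev.onset + n_ep))])
        labels.append(ev.label)

    data = (
        np.stack(trials)
        if trials
        else np.empty((0, len(keep_idx), n_ep))
    )
    return EpochSet(
        data=data,
        labels=np.asarray(labels, dtype=object),
        condition=raw.condition,
        sample_rate=raw.sample_rate,
        kept_channel_labels=kept_labels,
        rejection_log=log,
    )


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = np.std(x) or 1.0
    return (x - med) / scale


def reject_noisy(
    epochs: EpochSet,
    z_channel: float = 4.0,
    ptp_trial: float = 6.0,
    min_per_class: int = 8,
) -> EpochSet:
    """Remove outlier channels then outlier trials, by robust z-scores.

    Channels: log-variance (pooled over trials) whose robust z across
    channels exceeds ``z_channel``. Trials: max peak-to-peak over the
    remaining channels whose robust z exceeds ``ptp_trial``. Raises if all
    channels would be removed or if any class drops below ``min_per_class``
    trials (8-fold cross-validation needs at least 8 per class).
    """
    log = list(epochs.rejection_log)
    if epochs.n_trials == 0:
        return epochs

    logvar = np.log(np.maximum(np.var(epochs.data, axis=(0, 2)), 1e-300))
    zc = _robust_z(logvar)
    bad_ch = np.where(zc > z_channel)[0]
    keep_ch = np.setdiff1d(np.arange(epochs.n_channels), bad_ch)
    if keep_ch.size == 0:
        raise ValueError("all channels rejected")
    for i in bad_ch:
        log.append(
            {
                "entity": "channel",
                "index": int(i),
                "label": epochs.kept_channel_labels[i],
                "reason": "log-variance outlier",
                "statistic": float(zc[i]),
            }
        )

    data = epochs.data[:, keep_ch, :]
    ptp = np.max(np.ptp(data, axis=2), axis=1)
    zt = _robust_z(ptp)
    bad_tr = np.where(zt > ptp_trial)[0]
    keep_tr = np.setdiff1d(np.arange(epochs.n_trials), bad_tr)
    for t in bad_tr:
        log.append(
            {
                "entity": "trial",
                "index": int(t),
                "reason": "peak-to-peak outlier",
                "statistic": float(zt[t]),
            }
        )

    labels = epochs.labels[keep_tr]
    classes, counts = np.unique(labels.astype(str), return_counts=True)
    if counts.size and counts.min() < min_per_class:
        raise ValueError(
            f"fewer than {min_per_class} trials remain for class "
            f"{classes[counts.argmin()]!r}; cannot cross-validate"
        )
    return EpochSet(
        data=data[keep_tr],
        labels=labels,
        condition=epochs.condition,
        sample_rate=epochs.sample_rate,
        kept_channel_labels=[epochs.kept_channel_labels[i] for i in keep_ch],
        rejection_log=log,
    )
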