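"""Shared in-memory containers for cardiac time series and PR-interval epochs.

Conventions
-----------
* Amplitudes are in arbitrary units (fT for MCG, uV for BSPM); all algorithms
  are scale-covariant so the unit never matters.
* Time is handled in milliseconds at the API surface and in samples internally.
* A PR-interval epoch stack is aligned on the QRS onset: every row ends just
  before (or at) ventricular depolarisation, so per-beat timing measurements
  (e.g. the HV interval) are differences to a single fixed sample index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampledTrace", "BeatSeries", "EpochStack"]


@dataclass
class SampledTrace:
    """One channel's uniformly sampled amplitude series.

    Parameters
    ----------
    samples : ndarray, shape (n,)
        Amplitude values.
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("SampledTrace expects a 1-D sample array")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n / self.fs * 1000.0

    def times_ms(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.n) / self.fs * 1000.0


@dataclass
class BeatSeries:
    """A continuous multichannel cardiac recording (channels x time)."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            bad = np.argwhere(~np.isfinite(self.samples))[0]
            raise ValueError(
                f"non-finite sample at channel {bad[0]}, index {bad[1]}"
            )
        if not self.channel_labels:
            self.channel_labels = [
                f"ch{i + 1:02d}" for i in range(self.samples.shape[0])
            ]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str | int) -> SampledTrace:
        """Return a single channel as a :class:`SampledTrace`."""
        if isinstance(label, str):
            try:
                idx = self.channel_labels.index(label)
            except ValueError:
                raise KeyError(f"unknown channel {label!r}") from None
        else:
            idx = int(label)
        return SampledTrace(self.samples[idx].copy(), self.fs)


@dataclass
class EpochStack:
    """m QRS-onset-aligned PR-interval epochs (rows are beats).

    ``qrs_onset_idx`` is the sample index of the QRS onset shared by every
    row.  Epochs cut from a continuous series use the exclusive-end
    convention (``qrs_onset_idx == T``: the onset is the sample just after
    the last epoch sample); simulated epochs, whose final sample *is* the
    onset, use ``qrs_onset_idx == T - 1``.
    """

    epochs: np.ndarray
    fs: float
    qrs_onset_idx: int
    beat_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        if self.epochs.shape[0] < 1:
            raise ValueError("an epoch stack needs at least one beat")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.beat_indices is None:
            self.beat_indices = np.arange(self.epochs.shape[0])
        else:
            self.beat_indices = np.asarray(self.beat_indices, dtype=int)
        if self.beat_indices.size != self.epochs.shape[0]:
            raise ValueError("beat_indices must have one entry per epoch")

    @property
    def m(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the QRS onset (<= 0 before it)."""
        return (np.arange(self.n_samples) - self.qrs_onset_idx) / self.fs * 1000.0
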