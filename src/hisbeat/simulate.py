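"""Synthetic PR-interval epochs with known His bundle timing.

The generator emulates the structure of a PR interval seen in averaged
MCG/BSPM traces: a P wave (modelled as a Gaussian bump), a ramp-like atrial
repolarisation wave (PTa) running from the P-wave offset to the QRS onset, a
compact ~100 Hz biphasic His bundle deflection at a chosen HV interval before
the QRS onset, and additive white Gaussian noise whose level is set by an SNR
referenced to the P-wave peak.  Three PTa configurations are distinguished by
the extreme of the ramp relative to the P-wave peak:

* Type 1 - one third of the P amplitude, opposite polarity (ratio -1/3),
* Type 2 - one half of the P amplitude, same polarity (ratio +1/2),
* Type 3 - exceeding one half in the positive direction (default +0.6).

Every epoch comes with a :class:`GroundTruth` (clean component traces and the
exact HBS onset sample) so each downstream stage can be tested without
recorded data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BeatSeries, EpochStack, SampledTrace
from .epochs import TemplateAnnotation

__all__ = [
    "PTaType",
    "SimConfig",
    "GroundTruth",
    "SeriesGroundTruth",
    "make_atrial",
    "make_reference_hbs",
    "simulate_pr_epoch",
    "simulate_beat_series",
    "template_from_truth",
]


class PTaType(enum.Enum):
    """Atrial-repolarisation ramp configuration."""

    TYPE1 = 1
    TYPE2 = 2
    TYPE3 = 3


_DEFAULT_RATIOS = {PTaType.TYPE1: -1.0 / 3.0, PTaType.TYPE2: 0.5, PTaType.TYPE3: 0.6}


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic PR-interval epoch.

    Parameters
    ----------
    fs : float
        Sampling rate (Hz).
    epoch_len : float
        Epoch duration (ms); the QRS onset is the final sample.
    p_center, p_width, p_amp
        P-wave Gaussian bump: peak time (ms), half-width (ms; the bump's
        support is ~``p_center +/- p_width``, Gaussian sigma ``p_width/3``)
        and peak amplitude (arbitrary units).
    pta_type : PTaType
        Ramp configuration; fixes ``pta_ratio`` unless given explicitly.
    pta_ratio : float or None
        PTa extreme as a signed fraction of ``p_amp``.  Must equal -1/3 for
        Type 1 and +1/2 for Type 2, and exceed +1/2 for Type 3.
    pta_end_frac : float
        Ramp value at the QRS onset as a fraction of its extreme; values != 1
        give the ramp a nonzero slope after the His deflection.
    hbs_hv : float
        HV interval (ms): distance from the His deflection onset to the QRS
        onset.
    hbs_freq, hbs_amp
        Centre frequency (Hz) and peak amplitude of the biphasic deflection.
    snr_db : float
        Target SNR in dB, P-wave peak versus noise RMS; ``inf`` = noiseless.
    seed : int
        RNG seed for the noise realisations.
    n_epochs : int
        Number of independent noise realisations sharing one clean signal.
    """

    fs: float = 1000.0
    epoch_len: float = 350.0
    p_center: float = 100.0
    p_width: float = 50.0
    p_amp: float = 1.0
    pta_type: PTaType = PTaType.TYPE1
    pta_ratio: float | None = None
    pta_end_frac: float = 0.5
    hbs_hv: float = 60.0
    hbs_freq: float = 100.0
    hbs_amp: float = 0.2
    snr_db: float = 20.0
    seed: int = 0
    n_epochs: int = 1

    def __post_init__(self) -> None:
        if not (self.fs > 0 and self.epoch_len > 0):
            raise ValueError("fs and epoch_len must be positive")
        if not (0 < self.p_center < self.epoch_len) or self.p_width <= 0:
            raise ValueError("P wave must lie inside the epoch")
        if self.pta_ratio is None:
            # canonical ratios: -1/3 (Type 1), +1/2 (Type 2), +0.6 (Type 3);
            # an explicit ratio overrides them for custom morphologies
            object.__setattr__(self, "pta_ratio", _DEFAULT_RATIOS[self.pta_type])
        if not math.isfinite(self.pta_ratio):
            raise ValueError("pta_ratio must be finite")
        if not self.hbs_hv < self.epoch_len - self.p_center - self.p_width:
            raise ValueError(
                "hbs_hv must place the His deflection after the P-wave offset"
            )
        if self.hbs_freq >= self.fs / 2:
            raise ValueError("hbs_freq must be below the Nyquist frequency")
        if self.hbs_amp < 0:
            raise ValueError("hbs_amp must be non-negative")
        if not (math.isinf(self.snr_db) or math.isfinite(self.snr_db)):
            raise ValueError("snr_db must be finite or +inf")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len / 1000.0 * self.fs))

    @property
    def qrs_onset_idx(self) -> int:
        """Sample index of the QRS onset (the epoch's final sample)."""
        return self.n_samples - 1

    @property
    def p_offset_ms(self) -> float:
        """Nominal P-wave offset: where the PTa ramp starts."""
        return self.p_center + self.p_width

    @property
    def noise_rms(self) -> float:
        """Noise RMS implied by ``snr_db`` (P peak / 10^(SNR/20))."""
        if math.isinf(self.snr_db):
            return 0.0
        return self.p_amp / 10.0 ** (self.snr_db / 20.0)


@dataclass
class GroundTruth:
    """Noiseless components and exact His timing of a simulated epoch."""

    hbs_onset_idx: int
    hv_ms: float
    clean_hbs: np.ndarray
    clean_atrial: np.ndarray

    @property
    def clean_epoch(self) -> np.ndarray:
        return self.clean_hbs + self.clean_atrial


@dataclass
class SeriesGroundTruth:
    """Per-beat annotations of a simulated continuous recording."""

    qrs_onsets: np.ndarray
    hv_ms: float
    epoch_truths: list[GroundTruth] = field(default_factory=list)


def _times_ms(config: SimConfig) -> np.ndarray:
    return np.arange(config.n_samples) / config.fs * 1000.0


def make_atrial(config: SimConfig) -> SampledTrace:
    """Noiseless atrial trace: P-wave bump plus the PTa ramp.

    The ramp is piecewise linear: zero up to the P-wave offset, reaching its
    extreme ``pta_ratio * p_amp`` at the His onset time, then relaxing toward
    ``pta_end_frac`` of the extreme at the QRS onset (atrial repolarisation
    dominates the early PR segment and subsides after the His deflection).
    """
    t = _times_ms(config)
    sigma = config.p_width / 3.0
    p = config.p_amp * np.exp(-0.5 * ((t - config.p_center) / sigma) ** 2)
    extreme = config.pta_ratio * config.p_amp
    t_off = config.p_offset_ms
    t_end = t[-1]
    t_peak = t_end - config.hbs_hv
    if t_peak <= t_off:  # HV reaching back to the P offset: single ramp
        nodes_t = [t_off, t_end]
        nodes_v = [0.0, extreme]
    else:
        nodes_t = [t_off, t_peak, t_end]
        nodes_v = [0.0, extreme, extreme * config.pta_end_frac]
    ramp = np.interp(t, nodes_t, nodes_v, left=0.0)
    return SampledTrace(p + ramp, config.fs)


def make_reference_hbs(config: SimConfig) -> tuple[SampledTrace, GroundTruth]:
    """Clean biphasic His deflection placed ``hbs_hv`` ms before the QRS onset.

    The deflection is one Hann-windowed cycle of a sine at ``hbs_freq`` (10 ms
    support at 100 Hz, always <= 20 ms), starting with its downward lobe: the
    first sample of the support is the HBS onset recorded in the ground truth.
    """
    n = config.n_samples
    onset_idx = config.qrs_onset_idx - int(round(config.hbs_hv / 1000.0 * config.fs))
    if onset_idx < 0:
        raise ValueError("HV interval longer than the epoch")
    dur_s = 1.0 / config.hbs_freq
    k = max(2, int(round(dur_s * config.fs)))
    tau = np.arange(k + 1) / config.fs
    w = -np.sin(2 * np.pi * config.hbs_freq * tau)
    w *= 0.5 - 0.5 * np.cos(2 * np.pi * tau / dur_s)
    peak = np.abs(w).max()
    if peak > 0 and config.hbs_amp > 0:
        w = w / peak * config.hbs_amp
    else:
        w = np.zeros_like(w)
    trace = np.zeros(n)
    stop = min(n, onset_idx + w.size)
    trace[onset_idx:stop] = w[: stop - onset_idx]
    hv_ms = (n - 1 - onset_idx) / config.fs * 1000.0
    atrial = make_atrial(config).samples
    gt = GroundTruth(
        hbs_onset_idx=onset_idx, hv_ms=hv_ms, clean_hbs=trace, clean_atrial=atrial
    )
    return SampledTrace(trace.copy(), config.fs), gt


def simulate_pr_epoch(config: SimConfig) -> tuple[EpochStack, GroundTruth]:
    """Simulate ``n_epochs`` noisy PR epochs sharing one clean signal.

    The additive white Gaussian noise of each realisation is scaled to the
    exact target RMS ``p_amp / 10^(snr_db/20)``, so the realised SNR equals
    ``snr_db`` for every epoch.
    """
    _, gt = make_reference_hbs(config)
    clean = gt.clean_epoch
    sigma = config.noise_rms
    rng = np.random.default_rng(config.seed)
    rows = np.empty((config.n_epochs, clean.size))
    for i in range(config.n_epochs):
        if sigma > 0:
            w = rng.standard_normal(clean.size)
            w *= sigma / np.sqrt(np.mean(w**2))
        else:
            w = 0.0
        rows[i] = clean + w
    stack = EpochStack(rows, config.fs, qrs_onset_idx=config.qrs_onset_idx)
    return stack, gt


def simulate_beat_series(
    config: SimConfig,
    n_beats: int,
    rr_ms: float = 750.0,
    rr_jitter_ms: float = 0.0,
    multichannel: int = 1,
) -> tuple[BeatSeries, SeriesGroundTruth]:
    """Concatenate beats into a continuous (multi)channel recording.

    Each beat is a PR epoch followed by a stylised high-amplitude QRS complex
    (piecewise-linear R/S deflection, peak ``8 * p_amp``), at RR spacings
    jittered by a Gaussian of SD ``rr_jitter_ms``.  In multichannel mode the
    PTa ramp's slope after the His deflection alternates sign across
    channels (the polarity-reversal signature used by criterion 4) while the
    His timing is identical everywhere.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if rr_ms <= config.epoch_len:
        raise ValueError("rr_ms must exceed the PR epoch length")
    if multichannel < 1:
        raise ValueError("multichannel must be >= 1")
    fs = config.fs
    rng = np.random.default_rng(config.seed)
    n_epoch = config.n_samples
    qrs_dur_ms = 80.0
    qrs_n = int(round(qrs_dur_ms / 1000.0 * fs))
    tq = np.arange(qrs_n) / fs * 1000.0
    qrs_shape = np.interp(
        tq, [0.0, 20.0, 35.0, 60.0, qrs_dur_ms], [0.0, 8.0, -2.4, 0.0, 0.0]
    ) * config.p_amp

    rr = rr_ms + rr_jitter_ms * rng.standard_normal(max(0, n_beats - 1))
    rr = np.maximum(rr, config.epoch_len + qrs_dur_ms + 10.0)
    # 10 ms lead-in so detector jitter cannot push the first PR window
    # past the series start
    onsets_ms = config.epoch_len + 10.0 + np.concatenate([[0.0], np.cumsum(rr)])
    onsets = np.round(onsets_ms / 1000.0 * fs).astype(int)
    # pad short series to >= 2.2 s so the QRS detector's preconditions hold
    total = max(onsets[-1] + qrs_n + int(round(0.05 * fs)), int(round(2.2 * fs)))

    sigma = config.noise_rms
    data = np.zeros((multichannel, total))
    truths: list[GroundTruth] = []
    for c in range(multichannel):
        # alternate the post-His ramp end level so its slope flips sign
        ch_cfg = replace(
            config, pta_end_frac=0.5 if c % 2 == 0 else 1.5, snr_db=np.inf
        )
        _, gt = make_reference_hbs(ch_cfg)
        if c == 0:
            truths = [gt] * n_beats
        clean = gt.clean_epoch
        for o in onsets:
            data[c, o - n_epoch : o] += clean
            data[c, o : o + qrs_n] += qrs_shape
        if sigma > 0:
            w = rng.standard_normal(total)
            w *= sigma / np.sqrt(np.mean(w**2))
            data[c] += w
    series = BeatSeries(data, fs)
    return series, SeriesGroundTruth(
        qrs_onsets=onsets, hv_ms=truths[0].hv_ms, epoch_truths=truths
    )


def template_from_truth(
    stack: EpochStack,
    gt: GroundTruth,
    *,
    pre_pad_ms: float = 10.0,
    post_pad_ms: float = 10.0,
) -> TemplateAnnotation:
    """Annotate a simulated stack's average using the known His timing.

    Stands in for the manual T1/T2 placement done on measured traces: the
    preserved window spans the His deflection's support padded by
    ``pre_pad_ms``/``post_pad_ms`` on either side.
    """
    fs = stack.fs
    onset_ms = gt.hbs_onset_idx / fs * 1000.0
    support_ms = (np.flatnonzero(gt.clean_hbs).size or 10) / fs * 1000.0
    t1 = max(0.0, onset_ms - pre_pad_ms)
    t2 = min((stack.n_samples - 1) / fs * 1000.0, onset_ms + support_ms + post_pad_ms)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-window segment-count advisory
        return TemplateAnnotation(
            avg_trace=stack.epochs.mean(axis=0),
            fs=fs,
            t1_ms=t1,
            t2_ms=t2,
            hbs_onset_ms=onset_ms,
            preserve_intervals=[(t1, t2)],
        )
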