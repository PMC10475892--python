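"""Interval-dependent wavelet thresholding (IDWT).

The averaged PR trace is decomposed with the ``coif5`` wavelet into five
levels of detail coefficients.  Each detail level is denoised by fixed-form
(universal) soft thresholding, ``t_j = sigma_j * sqrt(2 ln N_j)``, *except*
inside manually chosen time intervals around the His bundle deflection whose
coefficients are left untouched.  Detail levels holding only very-low-
frequency content (d4 and d5 at 1 kHz sampling) are zeroed outright.  The
resulting specification - wavelet, per-level thresholds, preserved intervals,
zeroed levels - is stored once, built from the template, and applied
unchanged to every raw single-beat epoch.

The deepest-level approximation coefficients are never touched: the slow
atrial ramps they carry are removed later by signal space projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt

from .core import SampledTrace
from .epochs import TemplateAnnotation

__all__ = ["ThresholdSpec", "soft_threshold", "build_threshold_spec", "apply_threshold"]


def soft_threshold(x, t):
    """Soft shrinkage ``sign(x) * max(|x| - t, 0)`` (elementwise).

    ``t`` may be a scalar or array; negative thresholds are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("threshold must be non-negative")
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):  # |x| - inf is a valid full kill
        shrunk = np.maximum(np.abs(x) - t_arr, 0.0)
    out = np.sign(x) * np.where(np.isfinite(shrunk), shrunk, 0.0)
    return out if out.ndim else float(out)


def _wavedec(x: np.ndarray, wavelet: str, levels: int) -> list[np.ndarray]:
    import warnings

    with warnings.catch_warnings():
        # five levels on a ~350-sample epoch is the intended operating point;
        # pywt warns that deep-level coefficients feel the boundary handling
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec(x, wavelet, mode="symmetric", level=levels)


def _detail_masks(
    wavelet: str,
    levels: int,
    n_samples: int,
    fs: float,
    intervals_ms: list[tuple[float, float]],
    zeroed_levels: frozenset[int],
) -> list[np.ndarray]:
    """Per-level boolean masks (d1..dL) marking coefficients to preserve.

    A level-``j`` detail coefficient at index ``k`` is assigned the time
    support ``[k * 2^j - L_j, k * 2^j]`` samples, with ``L_j`` the effective
    filter length ``(2^j - 1)(L - 1) + 1``; it is preserved when that support
    intersects any preserve interval.  Zeroed levels get all-false masks.
    """
    filt_len = pywt.Wavelet(wavelet).dec_len
    coeffs = _wavedec(np.zeros(n_samples), wavelet, levels)
    masks: list[np.ndarray] = []
    for j in range(1, levels + 1):  # d1 .. dL
        n_j = coeffs[levels + 1 - j].size
        if j in zeroed_levels:
            masks.append(np.zeros(n_j, dtype=bool))
            continue
        L_j = (2**j - 1) * (filt_len - 1) + 1
        k = np.arange(n_j)
        hi_ms = k * 2**j / fs * 1000.0
        lo_ms = np.maximum(0.0, (k * 2**j - L_j) / fs * 1000.0)
        mask = np.zeros(n_j, dtype=bool)
        for a, b in intervals_ms:
            mask |= (hi_ms >= a) & (lo_ms < b)
        masks.append(mask)
    return masks


@dataclass
class ThresholdSpec:
    """The stored IDWT "function": everything needed to denoise one epoch.

    Thresholds and masks are indexed d1 (finest) .. dL (coarsest).  The spec
    is serialisable; masks are recompiled from the preserve intervals on
    load, so one JSON file reproduces the identical operation.
    """

    wavelet: str
    levels: int
    fs: float
    n_samples: int
    level_thresholds: list[float]
    preserve_masks: list[np.ndarray]
    zeroed_levels: frozenset[int]
    preserve_intervals_ms: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.level_thresholds) != self.levels:
            raise ValueError("one threshold per detail level required")
        if len(self.preserve_masks) != self.levels:
            raise ValueError("one mask per detail level required")
        for j, t in enumerate(self.level_thresholds, start=1):
            if t < 0:
                raise ValueError(f"negative threshold at level d{j}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "wavelet": self.wavelet,
            "levels": self.levels,
            "fs": self.fs,
            "n_samples": self.n_samples,
            "level_thresholds": [
                None if np.isinf(t) else float(t) for t in self.level_thresholds
            ],
            "zeroed_levels": sorted(self.zeroed_levels),
            "preserve_intervals_ms": [[a, b] for a, b in self.preserve_intervals_ms],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ThresholdSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        zeroed = frozenset(int(z) for z in d["zeroed_levels"])
        intervals = [(float(a), float(b)) for a, b in d["preserve_intervals_ms"]]
        masks = _detail_masks(
            d["wavelet"], d["levels"], d["n_samples"], d["fs"], intervals, zeroed
        )
        thresholds = [
            np.inf if t is None else float(t) for t in d["level_thresholds"]
        ]
        return cls(
            wavelet=d["wavelet"],
            levels=int(d["levels"]),
            fs=float(d["fs"]),
            n_samples=int(d["n_samples"]),
            level_thresholds=thresholds,
            preserve_masks=masks,
            zeroed_levels=zeroed,
            preserve_intervals_ms=intervals,
        )


def build_threshold_spec(
    template: TemplateAnnotation,
    fs: float | None = None,
    *,
    wavelet: str = "coif5",
    levels: int = 5,
    zeroed_levels: tuple[int, ...] = (4, 5),
    noise_ref: np.ndarray | None = None,
) -> ThresholdSpec:
    """Compile the template annotation into a reusable :class:`ThresholdSpec`.

    Per level the fixed-form threshold is ``sigma_j * sqrt(2 ln N_j)`` with
    ``sigma_j`` the robust MAD estimate ``median(|d_j|) / 0.6745``; zeroed
    levels get an infinite threshold and an all-false mask.

    By default ``sigma_j`` comes from the template's own detail
    coefficients.  ``noise_ref`` (an epochs x samples array of the raw beats
    the spec will be applied to) instead estimates ``sigma_j`` as the median
    of per-epoch MADs: the universal threshold is defined against the noise
    level of the signal being denoised, and a signal-averaged template
    understates the single-beat noise by ~sqrt(m).
    """
    fs = template.fs if fs is None else fs
    n = template.avg_trace.size
    zset = frozenset(int(z) for z in zeroed_levels)
    if any(z < 1 or z > levels for z in zset):
        raise ValueError("zeroed_levels must name detail levels 1..levels")
    if noise_ref is not None:
        ref_rows = np.atleast_2d(np.asarray(noise_ref, dtype=float))
        if ref_rows.shape[1] != n:
            raise ValueError("noise_ref epochs must match the template length")
        ref_coeffs = [_wavedec(row, wavelet, levels) for row in ref_rows]
    coeffs = _wavedec(template.avg_trace, wavelet, levels)
    thresholds: list[float] = []
    for j in range(1, levels + 1):
        if j in zset:
            thresholds.append(np.inf)
            continue
        d_j = coeffs[levels + 1 - j]
        if noise_ref is None:
            sigma = float(np.median(np.abs(d_j)) / 0.6745)
        else:
            mads = [
                np.median(np.abs(c[levels + 1 - j])) / 0.6745
                for c in ref_coeffs
            ]
            sigma = float(np.median(mads))
        thresholds.append(sigma * np.sqrt(2.0 * np.log(d_j.size)))
    masks = _detail_masks(wavelet, levels, n, fs, template.preserve_intervals, zset)
    return ThresholdSpec(
        wavelet=wavelet,
        levels=levels,
        fs=fs,
        n_samples=n,
        level_thresholds=thresholds,
        preserve_masks=masks,
        zeroed_levels=zset,
        preserve_intervals_ms=list(template.preserve_intervals),
    )


def apply_threshold(epoch: SampledTrace | np.ndarray, spec: ThresholdSpec):
    """Apply a stored :class:`ThresholdSpec` to one raw epoch.

    Decompose, soft-threshold every unmasked detail coefficient (zeroing the
    fully-thresholded levels), keep masked coefficients verbatim, leave the
    approximation untouched, reconstruct.  Output length equals input length.
    """
    x = epoch.samples if isinstance(epoch, SampledTrace) else np.asarray(epoch, float)
    if x.size != spec.n_samples:
        raise ValueError(
            f"epoch length {x.size} does not match the spec's {spec.n_samples}"
        )
    coeffs = _wavedec(x, spec.wavelet, spec.levels)
    out = [coeffs[0]]  # approximation passes through
    for j in range(spec.levels, 0, -1):  # coeffs order: dL .. d1
        d = coeffs[spec.levels + 1 - j]
        mask = spec.preserve_masks[j - 1]
        if mask.size != d.size:
            raise ValueError(f"mask length mismatch at level d{j}")
        if j in spec.zeroed_levels:
            new = np.where(mask, d, 0.0)
        else:
            new = np.where(mask, d, soft_threshold(d, spec.level_thresholds[j - 1]))
        out.append(new)
    rec = pywt.waverec(out, spec.wavelet, mode="symmetric")[: x.size]
    if isinstance(epoch, SampledTrace):
        return SampledTrace(rec, epoch.fs)
    return rec
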