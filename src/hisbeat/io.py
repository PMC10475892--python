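"""File formats and the inter-beat contour artifact.

Numeric matrices travel as delimited CSV with a one-line JSON header comment
(``# {...}``) carrying the sampling rate and axis metadata; values are
written at full double precision so every writer/reader pair round-trips
losslessly.  Continuous recordings can additionally be ingested from EDF
(via :mod:`mne`, read-only).  Reports, threshold specs and ground-truth
sidecars are plain JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import BeatSeries, EpochStack
from .ssp import HbsStack

__all__ = [
    "ContourMatrix",
    "interbeat_contour",
    "read_series",
    "write_series",
    "read_stack",
    "write_stack",
    "write_contour",
    "write_curve_csv",
    "write_json",
]

_FMT = "%.17g"


@dataclass
class ContourMatrix:
    """Beats x time matrix of extracted-HBS amplitudes for contour plotting.

    ``time_axis`` is in ms relative to the QRS onset (negative before it,
    final sample at 0); ``beat_axis`` holds the original beat ordinals.
    """

    values: np.ndarray
    beat_axis: np.ndarray
    time_axis: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.beat_axis = np.asarray(self.beat_axis, dtype=int)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.shape != (self.beat_axis.size, self.time_axis.size):
            raise ValueError("axes do not match the value matrix")
        if np.any(np.diff(self.time_axis) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if abs(self.time_axis[-1]) > 1e-9:
            raise ValueError("time axis must end at 0 ms (the QRS onset)")


def interbeat_contour(
    stack: EpochStack | HbsStack, segment: tuple[int, int] | None = None
) -> ContourMatrix:
    """Select a beat range (default ~25 beats) as a contour matrix.

    Rows are the selected epochs verbatim, in beat order; no smoothing is
    applied across beats.
    """
    if segment is None:
        segment = (0, min(25, stack.m))
    lo, hi = int(segment[0]), int(segment[1])
    if not (0 <= lo < hi <= stack.m):
        raise ValueError(f"segment [{lo}, {hi}) outside the stack's {stack.m} beats")
    t_ms = (np.arange(stack.n_samples) - (stack.n_samples - 1)) / stack.fs * 1000.0
    return ContourMatrix(
        values=stack.epochs[lo:hi].copy(),
        beat_axis=stack.beat_indices[lo:hi].copy(),
        time_axis=t_ms,
    )


# ---------------------------------------------------------------------------
# Delimited matrices with a JSON header line
# ---------------------------------------------------------------------------

def _write_matrix(path: Path, header: dict, matrix: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, matrix, fmt=_FMT, delimiter=",")


def _read_matrix(path: Path) -> tuple[dict, np.ndarray]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        try:
            header = json.loads(first.lstrip("#").strip())
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed JSON header: {exc}") from exc
        matrix = np.loadtxt(fh, delimiter=",", ndmin=2)
    return header, matrix


def write_series(path: str | Path, series: BeatSeries) -> None:
    """Write a recording as CSV: one column per channel, JSON header with fs."""
    header = {"fs": series.fs, "channels": list(series.channel_labels)}
    _write_matrix(Path(path), header, series.samples.T)


def _read_series_csv(path: Path) -> BeatSeries:
    header, matrix = _read_matrix(path)
    if "fs" not in header:
        raise ValueError(f"{path}: header is missing the required key 'fs'")
    labels = header.get("channels") or []
    return BeatSeries(matrix.T, float(header["fs"]), list(labels))


def _read_series_edf(path: Path) -> BeatSeries:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an extra
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return BeatSeries(raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names))


def read_series(path: str | Path, format: str | None = None) -> BeatSeries:
    """Read a continuous recording from CSV or EDF (format inferred from suffix)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = (format or p.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_series_csv(p)
    if fmt == "edf":
        return _read_series_edf(p)
    raise ValueError(f"unsupported series format {fmt!r} (use 'csv' or 'edf')")


def write_stack(path: str | Path, stack: EpochStack) -> None:
    """Write an epoch stack (rows are beats) with alignment metadata."""
    header = {
        "fs": stack.fs,
        "qrs_onset_idx": int(stack.qrs_onset_idx),
        "beat_indices": [int(b) for b in stack.beat_indices],
    }
    if isinstance(stack, HbsStack):
        header["provenance"] = stack.provenance
    _write_matrix(Path(path), header, stack.epochs)


def read_stack(path: str | Path) -> EpochStack:
    header, matrix = _read_matrix(Path(path))
    for key in ("fs", "qrs_onset_idx"):
        if key not in header:
            raise ValueError(f"{path}: header is missing the required key {key!r}")
    beat_idx = header.get("beat_indices")
    kwargs = dict(
        fs=float(header["fs"]),
        qrs_onset_idx=int(header["qrs_onset_idx"]),
        beat_indices=None if beat_idx is None else np.asarray(beat_idx, int),
    )
    if "provenance" in header:
        return HbsStack(matrix, provenance=header["provenance"], **kwargs)
    return EpochStack(matrix, **kwargs)


def write_contour(
    path: str | Path, contour: ContourMatrix, png: str | Path | None = None
) -> None:
    """Export a contour matrix as CSV (and optionally a non-contractual PNG)."""
    header = {
        "beat_axis": [int(b) for b in contour.beat_axis],
        "time_axis_ms": [float(t) for t in contour.time_axis],
    }
    _write_matrix(Path(path), header, contour.values)
    if png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        mesh = ax.pcolormesh(
            contour.time_axis, contour.beat_axis, contour.values, shading="nearest"
        )
        fig.colorbar(mesh, ax=ax, label="amplitude (a.u.)")
        ax.set_xlabel("time to QRS onset (ms)")
        ax.set_ylabel("beat number")
        fig.tight_layout()
        fig.savefig(png, dpi=120)
        plt.close(fig)


def read_contour(path: str | Path) -> ContourMatrix:
    header, matrix = _read_matrix(Path(path))
    return ContourMatrix(
        values=matrix,
        beat_axis=np.asarray(header["beat_axis"], int),
        time_axis=np.asarray(header["time_axis_ms"], float),
    )


def write_curve_csv(path: str | Path, curve) -> None:
    """Write a correlation-vs-SNR curve as CSV (snr_db, mean_r, sd_r, n)."""
    with open(path, "w") as fh:
        fh.write("snr_db,mean_r,sd_r,n\n")
        for s, m, sd, k in curve.rows():
            fh.write(f"{s:.17g},{m:.17g},{sd:.17g},{k}\n")


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
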