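"""Shared fixtures: small simulated stacks and a minimal EDF encoder."""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pytest

import hisbeat as hb

# the five-level decomposition of a ~350-sample epoch intentionally reaches
# into boundary-affected levels; silence pywt's advisory globally for tests
warnings.filterwarnings(
    "ignore", message="Level value of .* is too high", category=UserWarning
)


@pytest.fixture(scope="session")
def noiseless_stack():
    cfg = hb.SimConfig(snr_db=np.inf, n_epochs=10, seed=0)
    stack, gt = hb.simulate_pr_epoch(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def noisy_stack_28db():
    cfg = hb.SimConfig(snr_db=28.0, n_epochs=100, seed=1)
    stack, gt = hb.simulate_pr_epoch(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def pipeline_28db(noisy_stack_28db):
    """Full IDWT -> SSP run on the 28 dB Type-1 stack."""
    cfg, stack, gt = noisy_stack_28db
    template = hb.template_from_truth(stack, gt)
    spec = hb.build_threshold_spec(template, noise_ref=stack.epochs)
    hbs = hb.run_pipeline(stack, spec)
    return cfg, stack, gt, template, spec, hbs


def write_minimal_edf(path: Path, data: np.ndarray, fs: float) -> None:
    """Emit a minimal, standard-compliant EDF file (synthetic test fixture).

    16-bit encoding, one data record holding the whole signal; amplitudes
    are scaled to the full digital range per channel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ns, n = data.shape
    spr = n  # samples per record (single record)
    dur = n / fs

    def pad(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad("1", 8),
            pad(f"{dur:g}", 8),
            pad(str(ns), 4),
        ]
    )
    labels = [f"sig{i + 1}" for i in range(ns)]
    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    # avoid a degenerate physical range
    flat = pmaxs - pmins < 1e-12
    pmaxs[flat] = pmins[flat] + 1.0
    sig_hdr = b"".join(
        [
            b"".join(pad(lab, 16) for lab in labels),
            b"".join(pad("", 80) for _ in labels),
            b"".join(pad("uV", 8) for _ in labels),
            b"".join(pad(f"{v:.6g}", 8) for v in pmins),
            b"".join(pad(f"{v:.6g}", 8) for v in pmaxs),
            b"".join(pad("-32768", 8) for _ in labels),
            b"".join(pad("32767", 8) for _ in labels),
            b"".join(pad("", 80) for _ in labels),
            b"".join(pad(str(spr), 8) for _ in labels),
            b"".join(pad("", 32) for _ in labels),
        ]
    )
    body = bytearray()
    for c in range(ns):
        scaled = (data[c] - pmins[c]) / (pmaxs[c] - pmins[c])
        dig = np.round(scaled * 65535.0 - 32768.0).astype("<i2")
        body += struct.pack(f"<{spr}h", *dig)
    path.write_bytes(hdr + sig_hdr + bytes(body))
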