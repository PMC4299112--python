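"""Minimal WFDB record I/O (format 16 only).

Reads and writes the classic PhysioBank record layout: a text header
``<record>.hea`` whose first line is ``name nsig fs nsamp`` followed by
one signal-spec line per channel, and a binary ``<record>.dat`` holding
little-endian int16 samples interleaved by channel.  Physical units are
recovered as ``(adc - baseline) / gain``.  Only what the package needs —
single- or multi-channel format-16 records — is supported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

DEFAULT_GAIN = 10000.0


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int


def read_record(path: str) -> tuple[np.ndarray, float, int]:
    """Read a WFDB record; returns (signals [nsamp, nsig], fs, nsig).

    `path` may be the header path or the record name without extension.
    """
    hea_path = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"malformed WFDB header line: {lines[0]!r}")
    record_name, nsig, fs, nsamp = head[0], int(head[1]), float(head[2]), int(head[3])
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + nsig]:
        toks = ln.split()
        if len(toks) < 3:
            raise ValueError(f"malformed WFDB signal line: {ln!r}")
        fmt = int(toks[1])
        if fmt != 16:
            raise ValueError(f"unsupported WFDB format {fmt}; only format 16 is supported")
        gain_tok = toks[2]
        baseline = 0
        if "(" in gain_tok:
            g, rest = gain_tok.split("(", 1)
            baseline = int(rest.split(")", 1)[0])
            gain_tok = g
        gain = float(gain_tok.split("/")[0]) or DEFAULT_GAIN
        specs.append(_SignalSpec(toks[0], fmt, gain, baseline))
    dat_path = os.path.join(os.path.dirname(hea_path), specs[0].file_name)
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < nsamp * nsig:
        raise ValueError(
            f"WFDB signal file {dat_path} too short: {raw.size} < {nsamp * nsig} samples"
        )
    adc = raw[: nsamp * nsig].reshape(nsamp, nsig)
    phys = np.empty((nsamp, nsig), dtype=float)
    for j, sp in enumerate(specs):
        phys[:, j] = (adc[:, j].astype(float) - sp.baseline) / sp.gain
    return phys, fs, nsig


def write_record(path: str, samples: np.ndarray, fs: float, gain: float = DEFAULT_GAIN) -> None:
    """Write a single-channel format-16 record (header + .dat pair).

    Samples are quantized to int16 at the given gain; values must fit in
    [-32768/gain, 32767/gain] (the default gain stores +/-1-normalized
    segments with ~1e-4 resolution).
    """
    base = path[:-4] if path.endswith(".hea") else path
    record_name = os.path.basename(base)
    x = np.asarray(samples, dtype=float).ravel()
    adc = np.rint(x * gain)
    if adc.max() > 32767 or adc.min() < -32768:
        raise ValueError("samples overflow int16 at this gain; lower the gain")
    with open(base + ".hea", "w") as fh:
        fh.write(f"{record_name} 1 {fs:g} {x.size}\n")
        fh.write(f"{record_name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 ch0\n")
    adc.astype("<i2").tofile(base + ".dat")
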