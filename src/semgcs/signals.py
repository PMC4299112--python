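"""Synthetic sEMG segments, exactly-sparse test vectors, dynamic
thresholding, and segment I/O.

A surface EMG trace is modeled as a superposition of motor unit action
potential (MUAP) trains: each active motor unit fires quasi-periodically
(a renewal process with jittered inter-spike intervals) and contributes a
short biphasic waveform at every firing.  The three diagnostic classes
differ in motor-unit recruitment and MUAP morphology:

* healthy    — intermediate number of units, medium-amplitude,
               medium-duration MUAPs;
* myopathy   — many small, short MUAPs firing densely (loss of muscle
               fibers per unit, compensatory recruitment);
* neuropathy — few large, long MUAPs firing sparsely (loss of motor
               units, collateral reinnervation enlarges survivors).

These morphology contrasts are what the class-aware reconstruction
router and the K-NN classification check rely on; no attempt is made at
electrode-level realism.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from semgcs import _wfdb
from semgcs.basis import real_fourier_basis

LABELS = ("healthy", "myopathy", "neuropathy", "sparse-test")
DOMAIN_HINTS = ("time-sparse", "frequency-sparse", "block-sparse", "unknown")

#: Per-class MUAP-train parameters: number of recruited motor units,
#: mean firing rate per unit (Hz), MUAP amplitude scale (a.u.), and MUAP
#: duration (ms).  Chosen to make the class-discriminative features
#: (RMS, mean frequency, firing density) ordered in the clinically
#: expected directions; see docs/methods.md.
CLASS_PARAMS: dict[str, dict[str, float]] = {
    "healthy": {"n_units": 20, "rate_hz": 15.0, "amp": 0.5, "dur_ms": 8.0},
    "myopathy": {"n_units": 40, "rate_hz": 25.0, "amp": 0.25, "dur_ms": 4.0},
    "neuropathy": {"n_units": 6, "rate_hz": 10.0, "amp": 1.0, "dur_ms": 14.0},
}

#: Additive broadband noise level relative to unit MUAP amplitude.
NOISE_SIGMA = 0.02


@dataclass
class SignalSegment:
    """An N-sample real-valued sEMG window.

    ``samples`` are in arbitrary units normalized to [-1, 1]; ``events``
    is the generator's event log (sample onsets of MUAP firings), kept
    so downstream code and tests can count firings without re-detecting
    them.
    """

    samples: np.ndarray
    fs: float
    label: str = "sparse-test"
    domain_hint: str = "unknown"
    events: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 2:
            raise ValueError("segment must have N >= 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be > 0")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.domain_hint not in DOMAIN_HINTS:
            raise ValueError(f"domain_hint must be one of {DOMAIN_HINTS}")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class ThresholdConfig:
    """Dynamic-thresholding settings: sliding-average window length and
    the threshold as a fraction of the peak-to-peak amplitude."""

    window_w: int = 8
    threshold_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.window_w < 1:
            raise ValueError("window_w must be >= 1")
        if not 0.0 <= self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must lie in [0, 1]")


@dataclass
class SparsityReport:
    """Nonzero count K and sparsity level SP = (N - K)/N after thresholding."""

    K: int
    N: int

    @property
    def SP(self) -> float:
        return (self.N - self.K) / self.N


def _muap_template(fs: float, dur_ms: float) -> np.ndarray:
    """Biphasic MUAP waveform: first derivative of a Gaussian, peak-normalized."""
    half = max(2, int(round(dur_ms * 1e-3 * fs / 2)))
    t = np.arange(-half, half + 1, dtype=float)
    sigma = half / 2.5
    w = -t * np.exp(-0.5 * (t / sigma) ** 2)
    return w / np.max(np.abs(w))


def generate_semg(label: str, N: int = 1024, fs: float = 2000.0, seed: int = 0) -> SignalSegment:
    """Generate one synthetic sEMG segment of class ``label``.

    Builds per-unit renewal firing trains (inter-spike intervals jittered
    by 15% around the class mean rate), superposes the class MUAP template
    at each firing with per-unit amplitude variation, adds broadband
    Gaussian noise, and normalizes to unit peak amplitude.  Deterministic
    given ``seed``; firing onsets are logged in ``events``.
    """
    if label not in CLASS_PARAMS:
        raise ValueError(
            f"invalid label {label!r}; allowed labels: {tuple(CLASS_PARAMS)}"
        )
    if N < 64:
        raise ValueError("N must be >= 64 for a meaningful MUAP train")
    rng = np.random.default_rng(seed)
    p = CLASS_PARAMS[label]
    template = _muap_template(fs, p["dur_ms"])
    x = np.zeros(N + template.size)
    events: list[int] = []
    mean_isi = fs / p["rate_hz"]
    for _ in range(int(p["n_units"])):
        unit_amp = p["amp"] * rng.uniform(0.7, 1.3)
        # random phase start, then renewal firings across the window
        t = rng.uniform(0, mean_isi)
        while t < N:
            onset = int(t)
            x[onset : onset + template.size] += unit_amp * template * rng.uniform(0.9, 1.1)
            events.append(onset)
            t += mean_isi * rng.normal(1.0, 0.15)
    x = x[:N]
    x += NOISE_SIGMA * rng.standard_normal(N)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return SignalSegment(x, fs=fs, label=label, domain_hint="time-sparse", events=sorted(events))


def generate_ksparse(
    N: int,
    K: int,
    domain: str = "time",
    seed: int = 0,
    fs: float = 2000.0,
    block_size: int = 16,
) -> SignalSegment:
    """Generate a unit-l2-norm segment with exactly K nonzero coefficients
    in the stated domain.

    ``time``      — K nonzero samples at random positions;
    ``frequency`` — K nonzero coefficients under the orthonormal real
                    Fourier basis;
    ``block``     — the K nonzeros are packed into ceil(K / block_size)
                    blocks of the uniform block partition; all other
                    blocks are exactly zero.

    Nonzero magnitudes are drawn uniformly from [0.5, 1.5] with random
    sign (bounded away from zero before the final unit-norm scaling).
    """
    if not 1 <= K <= N:
        raise ValueError(f"K must satisfy 1 <= K <= N, got K={K}, N={N}")
    if domain not in ("time", "frequency", "block"):
        raise ValueError("domain must be one of {'time', 'frequency', 'block'}")
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.5, 1.5, size=K) * rng.choice([-1.0, 1.0], size=K)
    coefs = np.zeros(N)
    if domain in ("time", "frequency"):
        support = rng.choice(N, size=K, replace=False)
        coefs[support] = values
    else:
        if block_size < 1 or N % block_size:
            raise ValueError("block_size must divide N")
        g = N // block_size
        n_active = math.ceil(K / block_size)
        if n_active > g:
            raise ValueError("K too large for the requested block partition")
        active = rng.choice(g, size=n_active, replace=False)
        slots = np.concatenate([np.arange(b * block_size, (b + 1) * block_size) for b in active])
        coefs[slots[:K]] = values
    if domain == "frequency":
        x = real_fourier_basis(N).T @ coefs
        hint = "frequency-sparse"
    elif domain == "block":
        x = coefs
        hint = "block-sparse"
    else:
        x = coefs
        hint = "time-sparse"
    x = x / np.linalg.norm(x)
    return SignalSegment(x, fs=fs, label="sparse-test", domain_hint=hint)


def _sliding_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with truncated (shrinking) edge windows.

    Index i averages samples max(0, i - (w-1)//2) .. min(N-1, i + w//2).
    """
    n = x.size
    lo = np.maximum(0, np.arange(n) - (w - 1) // 2)
    hi = np.minimum(n, np.arange(n) + w // 2 + 1)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def dynamic_threshold(
    segment: SignalSegment, config: ThresholdConfig | None = None
) -> tuple[SignalSegment, SparsityReport]:
    """Sparsify a segment by DC removal plus peak-to-peak thresholding.

    The running DC level (sliding average over ``window_w`` samples) is
    subtracted, then every sample smaller in magnitude than
    ``threshold_fraction`` x (max - min) of the DC-removed signal is set
    to exactly zero.  Raising the fraction never decreases the sparsity
    level SP.
    """
    config = config or ThresholdConfig()
    x = segment.samples
    if x.size < config.window_w:
        raise ValueError(
            f"segment length {x.size} shorter than window_w={config.window_w}"
        )
    dc_removed = x - _sliding_mean(x, config.window_w)
    ptp = float(dc_removed.max() - dc_removed.min())
    thr = config.threshold_fraction * ptp
    out = np.where(np.abs(dc_removed) < thr, 0.0, dc_removed)
    # fraction 0 keeps the DC-removed signal untouched (thr == 0 zeroes nothing)
    k = int(np.count_nonzero(out))
    seg = SignalSegment(out, fs=segment.fs, label=segment.label,
                        domain_hint=segment.domain_hint, events=list(segment.events))
    return seg, SparsityReport(K=k, N=x.size)


# ---------------------------------------------------------------------------
# I/O: one-column CSV with a two-line header, or minimal WFDB (format 16)


def write_segment(segment: SignalSegment, path: str, format: str = "CSV") -> None:
    fmt = format.upper()
    if fmt == "CSV":
        with open(path, "w", newline="") as fh:
            fh.write(f"# fs={segment.fs:g}\n")
            fh.write(f"# label={segment.label}\n")
            writer = csv.writer(fh)
            for v in segment.samples:
                writer.writerow([repr(float(v))])
    elif fmt == "WFDB":
        _wfdb.write_record(path, segment.samples, segment.fs)
    else:
        raise ValueError("format must be 'CSV' or 'WFDB'")


def read_segment(
    path: str, format: str = "CSV", label: str | None = None, channel: int = 0
) -> SignalSegment:
    """Read a segment from CSV or a WFDB record.

    Multi-channel WFDB records default to channel 0 (the choice is noted
    in the returned segment only through this documented default).
    """
    fmt = format.upper()
    if fmt == "CSV":
        fs = 2000.0
        file_label = "sparse-test"
        values: list[float] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if body.startswith("fs="):
                        fs = float(body[3:])
                    elif body.startswith("label="):
                        file_label = body[6:]
                    continue
                try:
                    values.append(float(line.split(",")[0]))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric sample at row {lineno}: {line!r}"
                    ) from exc
        return SignalSegment(np.array(values), fs=fs, label=label or file_label)
    if fmt == "WFDB":
        phys, fs, nsig = _wfdb.read_record(path)
        if not 0 <= channel < nsig:
            raise ValueError(f"channel {channel} out of range for {nsig}-channel record")
        return SignalSegment(phys[:, channel], fs=fs, label=label or "sparse-test")
    raise ValueError("format must be 'CSV' or 'WFDB'")
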