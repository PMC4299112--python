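"""Random sensing matrices, suitability checks, the random-demodulator
front end, and measurement generation.

The measurement model is C = Phi D with an M x N operator Phi, M < N.
Three matrix families are supported — i.i.d. Bernoulli +/-1/sqrt(M),
i.i.d. Gaussian N(0, 1/M), and Binary Toeplitz (+/-1 entries constant
along diagonals, M rows selected, scaled 1/sqrt(M)) — plus the
``rd_structured`` matrices produced by the random-demodulator
simulation.  Suitability is probed with mutual coherence and a
randomized restricted-isometry surrogate (exact RIP verification is
combinatorial).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from semgcs.signals import SignalSegment, SparsityReport, ThresholdConfig, dynamic_threshold

logger = logging.getLogger(__name__)

FAMILIES = ("bernoulli", "gaussian", "binary_toeplitz", "rd_structured")


@dataclass
class SensingMatrix:
    """An M x N measurement operator with provenance.

    For the Binary-Toeplitz family the pre-selection N x N square matrix
    is retained in ``square_entries`` so the diagonal-constant structure
    remains verifiable after row selection.
    """

    entries: np.ndarray
    family: str
    seed: int
    column_normalized: bool = False
    square_entries: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entries = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("matrix entries must be finite")

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]


@dataclass
class CompressedSegment:
    """M compressive measurements of an N-sample segment."""

    measurements: np.ndarray
    matrix_id: str
    source_n: int

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, dtype=float).ravel()

    @property
    def m(self) -> int:
        return self.measurements.size


@dataclass
class MeasurementBound:
    """The compressive-sampling measurement-count condition
    M >= beta * K * log(N / M) (natural log)."""

    beta: float = 2.0
    satisfied: bool = False
    required: float = 0.0

    @staticmethod
    def check(M: int, N: int, K: int, beta: float = 2.0) -> "MeasurementBound":
        required = beta * K * math.log(N / M) if M < N else 0.0
        return MeasurementBound(beta=beta, satisfied=M >= required, required=required)


def make_matrix(family: str, M: int, N: int, seed: int = 0) -> SensingMatrix:
    """Draw an M x N sensing matrix of the given family, reproducibly.

    bernoulli: i.i.d. +/-1/sqrt(M) (every column has exactly unit norm);
    gaussian: i.i.d. N(0, 1/M); binary_toeplitz: first column and row
    i.i.d. +/-1, Toeplitz-completed to N x N, M rows drawn without
    replacement, scaled 1/sqrt(M).
    """
    if not 1 <= M <= N:
        raise ValueError(f"need 1 <= M <= N, got M={M}, N={N}")
    rng = np.random.default_rng(seed)
    if family == "bernoulli":
        entries = rng.choice([-1.0, 1.0], size=(M, N)) / math.sqrt(M)
        return SensingMatrix(entries, family, seed, column_normalized=True)
    if family == "gaussian":
        entries = rng.standard_normal((M, N)) / math.sqrt(M)
        return SensingMatrix(entries, family, seed)
    if family == "binary_toeplitz":
        col = rng.choice([-1.0, 1.0], size=N)
        row = rng.choice([-1.0, 1.0], size=N)
        row[0] = col[0]
        square = toeplitz(col, row)
        rows = np.sort(rng.choice(N, size=M, replace=False))
        entries = square[rows] / math.sqrt(M)
        return SensingMatrix(entries, family, seed, column_normalized=True,
                             square_entries=square)
    raise ValueError(f"unknown family {family!r}; rd_structured matrices come from "
                     "simulate_random_demodulator")


def coherence(phi: SensingMatrix | np.ndarray, psi: np.ndarray) -> float:
    """Mutual coherence mu = sqrt(N) * max |<row_i(Phi), col_j(Psi)>|
    over unit-normalized rows/columns; lies in [1, sqrt(N)] when Psi is
    a basis.  Psi may be complex (e.g. the unitary DFT), in which case
    the magnitude of the Hermitian inner product is used."""
    a = phi.entries if isinstance(phi, SensingMatrix) else np.asarray(phi, dtype=float)
    b = np.asarray(psi)
    n = a.shape[1]
    if b.shape[0] != n:
        raise ValueError("row length of Phi must match column length of Psi")
    row_norms = np.linalg.norm(a, axis=1)
    col_norms = np.linalg.norm(b, axis=0)
    if np.any(row_norms == 0) or np.any(col_norms == 0):
        raise ValueError("coherence undefined for zero rows/columns")
    inner = (a / row_norms[:, None]) @ (b / col_norms[None, :])
    return float(math.sqrt(n) * np.max(np.abs(inner)))


def rip_surrogate(
    phi: SensingMatrix | np.ndarray, K: int, trials: int = 100, seed: int = 0
) -> tuple[float, bool]:
    """Randomized restricted-isometry probe.

    Samples ``trials`` random K-subsets of (unit-normalized) columns and
    records the worst deviation of the squared singular values of the
    submatrix from 1; passes when the estimated constant is < 0.5.
    A lower bound on the true RIP constant, not a certificate.
    """
    if K < 1 or trials < 1:
        raise ValueError("K and trials must be >= 1")
    a = phi.entries if isinstance(phi, SensingMatrix) else np.asarray(phi, dtype=float)
    m, n = a.shape
    if K > n:
        raise ValueError("K cannot exceed the number of columns")
    if K > m:
        return float("inf"), False  # submatrix rank-deficient by construction
    norms = np.linalg.norm(a, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero column in sensing matrix")
    cols = a / norms[None, :]
    rng = np.random.default_rng(seed)
    delta = 0.0
    for _ in range(trials):
        sub = cols[:, rng.choice(n, size=K, replace=False)]
        s = np.linalg.svd(sub, compute_uv=False)
        delta = max(delta, abs(s[0] ** 2 - 1.0), abs(1.0 - s[-1] ** 2))
    return float(delta), delta < 0.5


def simulate_random_demodulator(
    segment: SignalSegment, M: int, seed: int = 0, chips: np.ndarray | None = None
) -> tuple[CompressedSegment, SensingMatrix]:
    """Analog random-demodulator front end: chip, integrate, dump.

    The sample stream is multiplied by an i.i.d. +/-1 chipping sequence
    at the input rate (the Gilbert-multiplier stage) and accumulated by
    an integrate-and-dump over M consecutive windows of length N/M.  If
    M does not divide N the tail is zero-padded (logged).  Also returns
    the equivalent ``rd_structured`` matrix — one chip-filled window per
    row — such that measurements == matrix @ samples exactly.  An
    explicit +/-1 ``chips`` sequence may be supplied in place of the
    seeded draw (e.g. to model a fixed hardware chipping register).
    """
    x = segment.samples
    n = x.size
    if M > n:
        raise ValueError("M cannot exceed the segment length")
    win = math.ceil(n / M)
    n_pad = win * M
    if n_pad != n:
        logger.info("random demodulator: zero-padding segment %d -> %d samples", n, n_pad)
        x = np.concatenate([x, np.zeros(n_pad - n)])
    if chips is None:
        rng = np.random.default_rng(seed)
        chips = rng.choice([-1.0, 1.0], size=n_pad)
    else:
        chips = np.asarray(chips, dtype=float).ravel()
        if chips.size != n_pad or not np.all(np.abs(chips) == 1.0):
            raise ValueError(f"chips must be a +/-1 sequence of length {n_pad}")
    meas = (chips * x).reshape(M, win).sum(axis=1)
    matrix = np.zeros((M, n_pad))
    for i in range(M):
        matrix[i, i * win : (i + 1) * win] = chips[i * win : (i + 1) * win]
    phi = SensingMatrix(matrix[:, :n], "rd_structured", seed)
    return CompressedSegment(meas, matrix_id=f"rd_structured:{seed}", source_n=n), phi


def compress(
    segment: SignalSegment,
    phi: SensingMatrix,
    threshold_config: ThresholdConfig | None = None,
    sp_target: float = 0.98,
    fraction_cap: float = 0.40,
    beta: float = 2.0,
    check_rip: bool = True,
    rip_seed: int = 0,
) -> tuple[CompressedSegment, SparsityReport, list[str]]:
    """Transmitter-side compression: sparsify, verify, measure.

    Applies dynamic thresholding and, while the sparsity level falls
    short of ``sp_target``, raises the threshold fraction in steps of
    0.01 up to ``fraction_cap``.  Verifies the measurement-count bound
    M >= beta*K*log(N/M) and (optionally) the RIP surrogate at the
    achieved K; violations are recorded as warnings, not fatal.  Returns
    the measurement vector C = Phi D_thresholded, the sparsity report,
    and the warning list.
    """
    if phi.n != segment.n:
        raise ValueError(f"matrix has N={phi.n} but segment has N={segment.n}")
    cfg = threshold_config or ThresholdConfig()
    warnings: list[str] = []
    sparse_seg, report = dynamic_threshold(segment, cfg)
    frac = cfg.threshold_fraction
    while report.SP < sp_target and frac < fraction_cap - 1e-12:
        frac = min(frac + 0.01, fraction_cap)
        sparse_seg, report = dynamic_threshold(segment, ThresholdConfig(cfg.window_w, frac))
    if report.SP < sp_target:
        raise RuntimeError(
            f"sparsity target {sp_target} unreachable at fraction cap {fraction_cap}; "
            f"achieved SP={report.SP:.4f}"
        )
    k = max(report.K, 1)
    bound = MeasurementBound.check(phi.m, phi.n, k, beta)
    if not bound.satisfied:
        warnings.append(
            f"measurement bound violated: M={phi.m} < {bound.required:.1f} "
            f"= beta*K*log(N/M) with K={k}"
        )
    if check_rip:
        delta, ok = rip_surrogate(phi, min(k, phi.m), trials=20, seed=rip_seed)
        if not ok:
            warnings.append(f"RIP surrogate failed: delta_hat={delta:.3f} >= 0.5")
    for w in warnings:
        logger.warning("%s", w)
    meas = phi.entries @ sparse_seg.samples
    comp = CompressedSegment(meas, matrix_id=f"{phi.family}:{phi.seed}", source_n=segment.n)
    return comp, report, warnings


def save_matrix(phi: SensingMatrix, path: str) -> None:
    """Save a matrix as plain-text CSV plus a JSON sidecar (family, seed, M, N)."""
    np.savetxt(path, phi.entries, delimiter=",")
    sidecar = {"family": phi.family, "seed": phi.seed, "M": phi.m, "N": phi.n,
               "column_normalized": phi.column_normalized}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_matrix(path: str) -> SensingMatrix:
    entries = np.loadtxt(path, delimiter=",")
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return SensingMatrix(entries, sidecar["family"], sidecar["seed"],
                         column_normalized=sidecar.get("column_normalized", False))
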