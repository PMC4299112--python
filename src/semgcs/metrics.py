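"""Compression/reconstruction quality metrics, the Monte-Carlo sweep
harness, and a lightweight K-NN classification check.

Conventions: PRD is the percentage root-mean-square difference,
100 * sqrt(sum (D - D_hat)^2 / sum D^2); SNR = 20 log10(||D|| / ||D - D_hat||)
in dB (capped at 300 dB for exact recovery); reconstruction accuracy is
the relative-error complement max(0, 100 * (1 - ||D - D_hat|| / ||D||));
the compression factor CF = (Db - Cb)/Db * 100 compares bit budgets.
Because the literature sometimes prints variant formulas, ``prd`` and
``sen_spe`` expose a ``paper_literal`` flag computing the uncorrected
printed ratios for comparison.  Both the sub-sampling ratio SSR = M/N
and its reciprocal compression ratio CR = N/M are always reported
explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from semgcs.basis import real_fourier_basis
from semgcs.reconstruction import BlockModel, SolverConfig, reconstruct
from semgcs.sensing import make_matrix
from semgcs.signals import SignalSegment, ThresholdConfig, dynamic_threshold, generate_ksparse, generate_semg

SNR_CAP_DB = 300.0


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def prd(D: np.ndarray, D_hat: np.ndarray, paper_literal: bool = False) -> float:
    """Percentage root-mean-square difference.

    Standard form 100*sqrt(sum(D-D_hat)^2 / sum D^2); with
    ``paper_literal`` the bare squared-error ratio (no sqrt, no x100)."""
    d = np.asarray(D, dtype=float).ravel()
    dh = np.asarray(D_hat, dtype=float).ravel()
    if d.size != dh.size:
        raise ValueError("signals must have equal length")
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("PRD undefined for a zero reference signal")
    ratio = float(np.sum((d - dh) ** 2)) / denom
    return ratio if paper_literal else 100.0 * math.sqrt(ratio)


def rmse_mc(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Monte-Carlo RMSE: mean over repetitions of ||D_l - D_hat_l|| / ||D_hat_l||."""
    if not pairs:
        raise ValueError("need at least one (D, D_hat) pair")
    vals = []
    for d, dh in pairs:
        d = np.asarray(d, dtype=float).ravel()
        dh = np.asarray(dh, dtype=float).ravel()
        denom = np.linalg.norm(dh)
        if denom == 0.0:
            raise ValueError("RMSE undefined for a zero reconstruction")
        vals.append(np.linalg.norm(d - dh) / denom)
    return float(np.mean(vals))


def snr_db(D: np.ndarray, D_hat: np.ndarray) -> float:
    """Reconstruction SNR = 20 log10(||D|| / ||D - D_hat||), capped at 300 dB."""
    d = np.asarray(D, dtype=float).ravel()
    dh = np.asarray(D_hat, dtype=float).ravel()
    sig = np.linalg.norm(d)
    if sig == 0.0:
        raise ValueError("SNR undefined for a zero reference signal")
    err = np.linalg.norm(d - dh)
    if err == 0.0:
        return SNR_CAP_DB
    return float(min(20.0 * math.log10(sig / err), SNR_CAP_DB))


def accuracy(D: np.ndarray, D_hat: np.ndarray) -> float:
    """Reconstruction accuracy in percent: max(0, 100*(1 - relative l2 error))."""
    d = np.asarray(D, dtype=float).ravel()
    dh = np.asarray(D_hat, dtype=float).ravel()
    sig = np.linalg.norm(d)
    if sig == 0.0:
        raise ValueError("accuracy undefined for a zero reference signal")
    return max(0.0, 100.0 * (1.0 - np.linalg.norm(d - dh) / sig))


def cf(Db_bits: float, Cb_bits: float) -> float:
    """Compression factor (Db - Cb)/Db * 100; for equal per-sample bit
    depth this equals (1 - M/N) * 100."""
    if Db_bits <= 0 or Cb_bits < 0 or Cb_bits > Db_bits:
        raise ValueError("need Db >= Cb >= 0 and Db > 0")
    return (Db_bits - Cb_bits) / Db_bits * 100.0


def sen_spe(counts: ConfusionCounts, paper_literal: bool = False) -> tuple[float, float]:
    """Sensitivity and specificity.

    Standard SEN = TP/(TP+FN), SPE = TN/(TN+FP).  ``paper_literal``
    computes SEN with a TP+TN denominator instead (the variant form
    sometimes printed)."""
    sen_den = counts.TP + (counts.TN if paper_literal else counts.FN)
    spe_den = counts.TN + counts.FP
    if sen_den == 0:
        raise ValueError("SEN undefined: no positive examples")
    if spe_den == 0:
        raise ValueError("SPE undefined: no negative examples")
    return counts.TP / sen_den, counts.TN / spe_den


# ---------------------------------------------------------------------------
# K-NN classification check


def segment_features(segment: SignalSegment) -> np.ndarray:
    """Per-segment feature vector: RMS, mean absolute value,
    zero-crossing count, and mean (spectral centroid) frequency in Hz."""
    x = segment.samples
    rms = float(np.sqrt(np.mean(x**2)))
    mav = float(np.mean(np.abs(x)))
    zc = int(np.count_nonzero(np.diff(np.signbit(x))))
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / segment.fs)
    mean_freq = float(np.sum(freqs * spec) / np.sum(spec)) if np.sum(spec) > 0 else 0.0
    return np.array([rms, mav, float(zc), mean_freq])


def knn_classify(
    train_segments: list[SignalSegment],
    test_segments: list[SignalSegment],
    k: int = 5,
) -> dict[str, ConfusionCounts]:
    """K-NN majority vote on segment features; one-vs-rest confusion
    counts per class.  Ties go to the alphabetically lowest label.
    Features are standardized by the training mean/std."""
    labels = sorted({s.label for s in train_segments})
    for lab in labels:
        if sum(1 for s in train_segments if s.label == lab) < k:
            raise ValueError(f"class {lab!r} has fewer than k={k} training segments")
    xtr = np.vstack([segment_features(s) for s in train_segments])
    ytr = np.array([s.label for s in train_segments])
    mean, std = xtr.mean(axis=0), xtr.std(axis=0)
    std[std == 0] = 1.0
    xtr = (xtr - mean) / std
    xte = (np.vstack([segment_features(s) for s in test_segments]) - mean) / std
    yte = np.array([s.label for s in test_segments])

    nn = NearestNeighbors(n_neighbors=k).fit(xtr)
    _, idx = nn.kneighbors(xte)
    preds = []
    for row in idx:
        votes = ytr[row]
        uniq, cnt = np.unique(votes, return_counts=True)
        preds.append(sorted(uniq[cnt == cnt.max()])[0])  # lowest label wins ties
    preds = np.array(preds)

    out: dict[str, ConfusionCounts] = {}
    for lab in labels:
        out[lab] = ConfusionCounts(
            TP=int(np.sum((preds == lab) & (yte == lab))),
            TN=int(np.sum((preds != lab) & (yte != lab))),
            FP=int(np.sum((preds == lab) & (yte != lab))),
            FN=int(np.sum((preds != lab) & (yte == lab))),
        )
    return out


def classification_accuracy(counts: dict[str, ConfusionCounts]) -> float:
    """Overall accuracy in percent from one-vs-rest confusion counts."""
    correct = sum(c.TP for c in counts.values())
    total = next(iter(counts.values())).TP + next(iter(counts.values())).FN + \
        next(iter(counts.values())).FP + next(iter(counts.values())).TN
    return 100.0 * correct / total


# ---------------------------------------------------------------------------
# Monte-Carlo sweep harness


@dataclass
class SweepSpec:
    """Grid definition for the Monte-Carlo harness.

    ``signal`` is either ``"ksparse"`` (exactly-K-sparse unit-norm test
    vectors; grid over ``K_grid``) or a clinical class label (segments
    from the generator, thresholded at ``threshold.threshold_fraction``,
    with K taken post-threshold).  One row is emitted per (K or class,
    M) grid cell, aggregating L repetitions.
    """

    N: int = 1024
    signal: str = "ksparse"
    K_grid: list[int] = field(default_factory=lambda: [11])
    M_grid: list[int] = field(default_factory=lambda: [250])
    family: str = "bernoulli"
    route: str = "l1"
    L: int = 50
    seed: int = 0
    bits_per_sample: int = 10
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    epsilon: float | None = 1e-8
    block_size: int = 16


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the Monte-Carlo grid and return one tidy row per cell.

    Each cell runs L independent repetitions (fresh signal and sensing
    matrix per repetition, seeded from the spec seed so reruns reproduce
    the table exactly) and reports mean accuracy, Monte-Carlo RMSE,
    median SNR, mean PRD, the compression factor, SSR and CR.
    """
    if not spec.K_grid or not spec.M_grid:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    for ci, k in enumerate(spec.K_grid):
        for mj, m in enumerate(spec.M_grid):
            pairs = []
            snrs = []
            prds = []
            for rep in range(spec.L):
                ss = np.random.SeedSequence([spec.seed, ci, mj, rep])
                sig_seed, mat_seed = [int(s) % (2**31) for s in ss.generate_state(2)]
                if spec.signal == "ksparse":
                    seg = generate_ksparse(spec.N, k, "time", seed=sig_seed)
                    d = seg.samples
                else:
                    seg = generate_semg(spec.signal, spec.N, seed=sig_seed)
                    d = dynamic_threshold(seg, spec.threshold)[0].samples
                    d = d / (np.linalg.norm(d) or 1.0)
                phi = make_matrix(spec.family, m, spec.N, seed=mat_seed)
                c = phi.entries @ d
                cfg = SolverConfig(route=spec.route, epsilon=spec.epsilon)
                res = reconstruct(c, phi, {"label": seg.label, "domain_hint": seg.domain_hint},
                                  cfg, BlockModel(block_size=spec.block_size))
                pairs.append((d, res.d_hat))
                snrs.append(snr_db(d, res.d_hat))
                prds.append(prd(d, res.d_hat))
            accs = [accuracy(d, dh) for d, dh in pairs]
            rows.append({
                "signal": spec.signal,
                "K": k,
                "M": m,
                "N": spec.N,
                "ssr": m / spec.N,
                "cr": spec.N / m,
                "srd_percent": 100.0 * m / spec.N,
                "sparsity_percent": 100.0 * (spec.N - k) / spec.N,
                "L": spec.L,
                "accuracy_percent": float(np.mean(accs)),
                "rmse": rmse_mc(pairs),
                "snr_db": float(np.median(snrs)),
                "prd_percent": float(np.mean(prds)),
                "cf_percent": cf(spec.N * spec.bits_per_sample, spec.M_grid[mj] * spec.bits_per_sample),
                "route": spec.route,
                "seed": spec.seed,
            })
    return pd.DataFrame(rows)
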