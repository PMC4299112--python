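"""Sensing-dictionary selection: OMP sparse coding, K-SVD-style atom
updates, row selection, and nomination against a Binary-Toeplitz
reference.

The selection procedure learns an N x N candidate dictionary from
thresholded training segments by alternating orthogonal matching
pursuit (sparse coding) with per-atom rank-1 SVD refits, selects M of
its rows, and nominates either the learned candidate or a freshly drawn
Binary-Toeplitz matrix — whichever is less coherent with the sparsity
basis (ties go to the simpler BT reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from semgcs.basis import dct_basis
from semgcs.sensing import SensingMatrix, coherence, make_matrix
from semgcs.signals import SignalSegment, ThresholdConfig, dynamic_threshold

logger = logging.getLogger(__name__)


@dataclass
class SparseDictionary:
    """A learned sensing-dictionary candidate.

    ``atoms`` holds unit-norm columns of the square N x N dictionary;
    ``selected_rows`` indexes the M retained rows; ``history`` records
    total squared representation error after each learning sweep (non-
    increasing); ``verdict`` says which candidate was nominated.
    """

    atoms: np.ndarray
    selected_rows: list[int] = field(default_factory=list)
    history: list[float] = field(default_factory=list)
    verdict: str = "learned"
    coherence_learned: float = float("nan")
    coherence_bt: float = float("nan")

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("dictionary atoms must have unit l2 norm")
        if self.verdict not in ("learned", "bt_reference"):
            raise ValueError("verdict must be 'learned' or 'bt_reference'")

    @property
    def sensing_rows(self) -> np.ndarray:
        """The row-selected M x N operator (unscaled)."""
        return self.atoms[self.selected_rows, :]


def omp(
    dictionary: np.ndarray, signal: np.ndarray, K_max: int, tol: float = 1e-6
) -> np.ndarray:
    """Orthogonal matching pursuit sparse coding.

    Greedily adds the atom most correlated with the current residual
    (ties broken toward the lowest index), refits all active
    coefficients by least squares each iteration, and stops after
    ``K_max`` atoms or when the residual norm drops to ``tol``.
    """
    atoms = np.asarray(dictionary, dtype=float)
    y = np.asarray(signal, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("signal must be finite")
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    n_atoms = atoms.shape[1]
    coefs = np.zeros(n_atoms)
    residual = y.copy()
    support: list[int] = []
    for _ in range(min(K_max, n_atoms)):
        if np.linalg.norm(residual) <= tol:
            break
        corr = np.abs(atoms.T @ residual)
        corr[support] = -1.0
        best = int(np.argmax(corr))  # argmax returns the lowest index on ties
        support.append(best)
        sub = atoms[:, support]
        sol, *_ = np.linalg.lstsq(sub, y, rcond=None)
        residual = y - sub @ sol
    if support:
        coefs[support] = sol
    return coefs


def _fix_sign(u: np.ndarray) -> float:
    """Sign convention: the largest-magnitude entry of an atom is positive."""
    return 1.0 if u[np.argmax(np.abs(u))] >= 0 else -1.0


def svd_update(
    dictionary: np.ndarray, training_set: np.ndarray, codes: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """K-SVD-style dictionary update.

    For each atom used by at least one training signal, the restricted
    residual matrix (signals minus all other atoms' contributions,
    columns restricted to this atom's users) is replaced by its best
    rank-1 approximation: the atom becomes the leading left singular
    vector and the users' coefficients become sigma_1 times the leading
    right singular vector.  Unused atoms are re-seeded from the worst-
    represented training signal.  Returns the updated (dictionary,
    codes); total representation error never increases.
    """
    d = np.asarray(dictionary, dtype=float).copy()
    y = np.atleast_2d(np.asarray(training_set, dtype=float))
    x = np.asarray(codes, dtype=float).copy()
    if y.size == 0:
        raise ValueError("training set is empty")
    if y.shape[1] != x.shape[1]:
        raise ValueError("codes must have one column per training signal")
    rng = np.random.default_rng(seed)
    for j in range(d.shape[1]):
        users = np.flatnonzero(x[j, :] != 0.0)
        if users.size == 0:
            err = y - d @ x
            worst = int(np.argmax(np.linalg.norm(err, axis=0)))
            atom = y[:, worst] + 1e-12 * rng.standard_normal(y.shape[0])
            d[:, j] = atom / np.linalg.norm(atom)
            continue
        e_restricted = y[:, users] - d @ x[:, users] + np.outer(d[:, j], x[j, users])
        u, s, vt = np.linalg.svd(e_restricted, full_matrices=False)
        sign = _fix_sign(u[:, 0])
        d[:, j] = sign * u[:, 0]
        x[j, users] = sign * s[0] * vt[0, :]
    return d, x


def row_select(
    square_matrix: np.ndarray, M: int, strategy: str = "uniform_random", seed: int = 0
) -> list[int]:
    """Pick M of N rows: uniformly at random without replacement, or by
    leverage score (squared row norms of the left singular matrix, top M)."""
    a = np.asarray(square_matrix, dtype=float)
    n = a.shape[0]
    if M > n:
        raise ValueError(f"cannot select M={M} rows from {n}")
    if strategy == "uniform_random":
        rng = np.random.default_rng(seed)
        return sorted(int(i) for i in rng.choice(n, size=M, replace=False))
    if strategy == "leverage":
        u, s, _ = np.linalg.svd(a, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        scores = np.sum(u[:, :rank] ** 2, axis=1)
        order = np.argsort(-scores, kind="stable")
        return sorted(int(i) for i in order[:M])
    raise ValueError("strategy must be 'uniform_random' or 'leverage'")


@dataclass
class SelectionConfig:
    sweeps: int = 10
    K_max: int | None = None  # default ceil(0.05 N)
    tol: float = 1e-6
    row_strategy: str = "uniform_random"
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0


def select_sensing_dictionary(
    training_set: list[SignalSegment],
    M: int,
    config: SelectionConfig | None = None,
    sparsity_basis: np.ndarray | None = None,
) -> SparseDictionary:
    """End-to-end dictionary selection.

    Thresholds the training segments, initializes a square dictionary
    (training-data columns when enough signals are available, else a
    seeded-noise-perturbed DCT basis), alternates OMP coding and SVD
    atom updates for ``sweeps`` iterations, row-selects M rows, and
    nominates the candidate — learned vs a same-size Binary-Toeplitz
    draw — with the lower mutual coherence against the sparsity basis.

    Each sweep keeps, per training signal, whichever code (fresh OMP fit
    or the carried-over SVD-updated code) leaves the smaller residual,
    so the recorded error history is non-increasing by construction.
    """
    cfg = config or SelectionConfig()
    if not training_set:
        raise ValueError("training set must contain at least one segment")
    n = training_set[0].n
    if any(seg.n != n for seg in training_set):
        raise ValueError("training segments must all have the same length")
    k_max = cfg.K_max or max(1, int(np.ceil(0.05 * n)))
    basis = sparsity_basis if sparsity_basis is not None else np.eye(n)

    thresholded = [dynamic_threshold(seg, cfg.threshold)[0].samples for seg in training_set]
    y = np.column_stack(thresholded)

    rng = np.random.default_rng(cfg.seed)
    if y.shape[1] >= n:
        init = y[:, :n].copy()
    else:
        init = dct_basis(n).T + 0.01 * rng.standard_normal((n, n))
    norms = np.linalg.norm(init, axis=0)
    norms[norms == 0] = 1.0
    d = init / norms

    codes = np.column_stack([omp(d, y[:, i], k_max, cfg.tol) for i in range(y.shape[1])])
    history = [float(np.sum((y - d @ codes) ** 2))]
    for sweep in range(cfg.sweeps):
        d, codes = svd_update(d, y, codes, seed=cfg.seed + sweep + 1)
        for i in range(y.shape[1]):
            cand = omp(d, y[:, i], k_max, cfg.tol)
            if np.linalg.norm(y[:, i] - d @ cand) <= np.linalg.norm(y[:, i] - d @ codes[:, i]):
                codes[:, i] = cand
        history.append(float(np.sum((y - d @ codes) ** 2)))

    rows = row_select(d.T, M, cfg.row_strategy, cfg.seed)  # select rows of the operator D^T
    learned_op = d.T[rows, :]
    bt = make_matrix("binary_toeplitz", M, n, seed=cfg.seed)
    mu_learned = coherence(learned_op, basis)
    mu_bt = coherence(bt, basis)
    verdict = "learned" if mu_learned < mu_bt else "bt_reference"
    logger.info("dictionary selection: mu_learned=%.3f mu_bt=%.3f -> %s",
                mu_learned, mu_bt, verdict)
    return SparseDictionary(
        atoms=d, selected_rows=rows, history=history, verdict=verdict,
        coherence_learned=mu_learned, coherence_bt=mu_bt,
    )


def nominated_matrix(sel: SparseDictionary, M: int, n: int, seed: int = 0) -> SensingMatrix:
    """Materialize the nominated candidate as a SensingMatrix."""
    if sel.verdict == "bt_reference":
        return make_matrix("binary_toeplitz", M, n, seed=seed)
    op = sel.sensing_rows
    return SensingMatrix(op / np.sqrt(M), "rd_structured", seed)
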