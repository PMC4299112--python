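"""Orthonormal transform bases used as sparsity dictionaries.

All bases are returned as real N x N orthogonal matrices whose *rows* are
the analysis functions, so ``coefficients = basis @ signal`` and
``signal = basis.T @ coefficients``.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct


def real_fourier_basis(n: int) -> np.ndarray:
    """Orthonormal real Fourier (cosine/sine pair) analysis matrix.

    Row 0 is the DC vector 1/sqrt(N); subsequent rows come in
    cos/sin pairs at integer frequencies k = 1 .. floor((N-1)/2) with
    amplitude sqrt(2/N); for even N the last row is the Nyquist
    alternating vector (+1, -1, ...)/sqrt(N).  The result F is orthogonal
    (F F^T = I), so a signal sparse in this basis has few nonzero entries
    of ``F @ x`` — the real-arithmetic stand-in for DFT-domain sparsity.
    """
    if n < 1:
        raise ValueError("basis size must be >= 1")
    t = np.arange(n)
    rows = [np.full(n, 1.0 / np.sqrt(n))]
    for k in range(1, (n - 1) // 2 + 1):
        ang = 2.0 * np.pi * k * t / n
        rows.append(np.sqrt(2.0 / n) * np.cos(ang))
        rows.append(np.sqrt(2.0 / n) * np.sin(ang))
    if n % 2 == 0 and n > 1:
        rows.append(np.where(t % 2 == 0, 1.0, -1.0) / np.sqrt(n))
    f = np.vstack(rows)
    assert f.shape == (n, n)
    return f


def dct_basis(n: int) -> np.ndarray:
    """Orthonormal DCT-II analysis matrix (rows are DCT basis functions)."""
    return dct(np.eye(n), norm="ortho", axis=1)
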