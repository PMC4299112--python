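"""Recover compressed segments through all three solver routes.

Time-sparse signals go to l1 (basis pursuit), frequency-sparse signals
to l1-l1 (an extra Fourier-domain l1 term), and block-sparse signals to
block sparse Bayesian learning (BSBL).  All three run here on exactly-
sparse test vectors in the matching domain.
"""

import numpy as np

from semgcs import (
    BlockModel,
    SolverConfig,
    generate_ksparse,
    make_matrix,
    reconstruct,
)
from semgcs.metrics import accuracy, snr_db

N = 256
for domain, m in (("time", 64), ("frequency", 96), ("block", 96)):
    seg = generate_ksparse(N, K=16, domain=domain, seed=4, block_size=16)
    phi = make_matrix("bernoulli", m, N, seed=11)
    c = phi.entries @ seg.samples
    res = reconstruct(c, phi, {"domain_hint": seg.domain_hint},
                      SolverConfig(epsilon=1e-8, lam=5.0),
                      BlockModel(block_size=16))
    err = np.linalg.norm(res.d_hat - seg.samples)
    print(f"{domain:>9}-sparse, M={m:3d}: route={res.route_taken:5s} "
          f"err={err:.2e}  accuracy={accuracy(seg.samples, res.d_hat):6.2f}%  "
          f"SNR={snr_db(seg.samples, res.d_hat):6.1f} dB")

print()
print("Each route recovers its matching sparsity structure essentially exactly")
print("from M << N measurements; accuracy is 100*(1 - relative l2 error) and")
print("SNR is capped at 300 dB for perfect recovery.")
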