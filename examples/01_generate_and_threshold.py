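"""Generate synthetic sEMG segments and sparsify them by dynamic thresholding.

Three diagnostic classes are emulated as motor-unit action potential
(MUAP) trains; thresholding removes the running DC level and zeroes
everything below a fraction of the peak-to-peak amplitude, which is what
makes the segment compressible.
"""

import numpy as np

from semgcs import ThresholdConfig, dynamic_threshold, generate_semg

for label in ("healthy", "myopathy", "neuropathy"):
    seg = generate_semg(label, N=1024, fs=2000.0, seed=1)
    _, at10 = dynamic_threshold(seg, ThresholdConfig(window_w=8, threshold_fraction=0.10))
    _, at30 = dynamic_threshold(seg, ThresholdConfig(window_w=8, threshold_fraction=0.30))
    print(f"{label:>10}: {len(seg.events):3d} MUAP firings, "
          f"peak {np.max(np.abs(seg.samples)):.2f}; "
          f"SP@10%={at10.SP:.3f} (K={at10.K}), SP@30%={at30.SP:.3f} (K={at30.K})")

print()
print("SP is the sparsity level (N-K)/N: the fraction of samples zeroed out.")
print("Raising the threshold fraction from 10% to 30% of peak-to-peak never")
print("lowers SP — the knob the transmitter turns to hit its sparsity target.")
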