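"""Monte-Carlo sweep: reconstruction quality vs number of measurements.

Runs L repetitions per grid cell (fresh K-sparse signal and Bernoulli
matrix each time) and tabulates accuracy, Monte-Carlo RMSE, and median
SNR as the sub-sampling ratio M/N grows.
"""

from semgcs.metrics import SweepSpec, run_sweep

spec = SweepSpec(N=256, K_grid=[8], M_grid=[24, 32, 48, 64, 96], L=5, seed=3)
table = run_sweep(spec)
cols = ["M", "ssr", "cr", "accuracy_percent", "rmse", "snr_db", "cf_percent"]
print(table[cols].to_string(index=False,
                            float_format=lambda v: f"{v:.4g}"))
print()
print("Accuracy climbs and RMSE falls monotonically as the sub-sampling ratio")
print("M/N increases, saturating once the l1 program enters its exact-recovery")
print("region; CF is the bit-budget reduction (1 - M/N) x 100.")
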