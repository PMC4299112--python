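# Methods

This note documents the models, algorithms, and numerical choices behind
`semgcs`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what is computed, under which assumptions, and
where the design was genuinely open.

## Problem setting

A surface EMG (sEMG) segment is an N-sample window `D ∈ R^N` (default
N = 1024, nominal sampling 2–8 kHz, amplitudes normalized to [−1, 1]).
A compressive sensor measures

    C = Φ D,     Φ ∈ R^{M×N},  M < N,

and the receiver recovers `D̂` from `C` by exploiting sparsity. The
package implements the full chain — sparsification, sensing, dictionary
selection, recovery, scoring — entirely in software; the analog front
end is represented by its mathematical equivalent (the random
demodulator), not by circuit models.

## Synthetic sEMG generator

Real sEMG is a superposition of motor unit action potential (MUAP)
trains. The generator (`signals.generate_semg`) draws, per motor unit,
a renewal firing train (inter-spike interval = class mean with 15%
Gaussian jitter, random initial phase), superposes a biphasic MUAP
template (first derivative of a Gaussian, peak-normalized) with ±30%
per-unit and ±10% per-firing amplitude variation, adds broadband
Gaussian noise (σ = 0.02 relative to unit template amplitude), and
peak-normalizes. Class parameters (package constants, `CLASS_PARAMS`):

| class      | units | rate (Hz) | MUAP amp (a.u.) | MUAP duration (ms) |
|------------|------:|----------:|----------------:|-------------------:|
| healthy    |    20 |        15 |            0.50 |                  8 |
| myopathy   |    40 |        25 |            0.25 |                  4 |
| neuropathy |     6 |        10 |            1.00 |                 14 |

The orderings encode the clinical picture: myopathy recruits many
small, short MUAPs densely; neuropathy has few, large, long MUAPs.
These values are package choices — they produce class-separable
morphology (firing density, spectral centroid) sufficient for the
routing and K-NN checks, nothing more. The generator does **not**
emulate electrode lift-off, motion artifact, power-line interference,
inter-subject variability, or force-dependent recruitment, so passing
tests demonstrate correctness of the compression/recovery machinery on
MUAP-train-like signals, not clinical performance on recorded data.
Real records can be substituted through `read_segment` (CSV or minimal
WFDB format-16, single channel, default channel 0).

Exactly-sparse test vectors (`generate_ksparse`) have exactly K nonzero
coefficients in the time domain, under the orthonormal real Fourier
basis, or packed into ⌈K/h⌉ blocks of a uniform partition. Magnitudes
are drawn uniformly from ±[0.5, 1.5] — bounded away from zero — before
the final unit-ℓ2 scaling (after scaling the smallest magnitude is
≥ 0.5/(1.5√K), so the "away from zero" guarantee is a statement about
the pre-normalization draw).

## Dynamic thresholding

`dynamic_threshold` subtracts a running DC estimate (centered moving
average over `window_w` samples, edge windows truncated; default
window 8, the midpoint of the plausible 5–10 range) and zeroes every
sample with magnitude below `threshold_fraction` × (max − min) of the
DC-removed signal. Default fraction 0.10; 0.30 is the aggressive
setting that pushes typical segments past 98% sparsity. The sparsity
level is SP = (N − K)/N with K the surviving nonzero count. SP is
monotone non-decreasing in the fraction, which the transmitter
algorithm exploits: `sensing.compress` raises the fraction in steps of
0.01 (cap 0.40) until SP ≥ 0.98, then measures.

## Sensing matrices and suitability checks

Families: Bernoulli ±1/√M (unit-norm columns), Gaussian N(0, 1/M), and
Binary Toeplitz — first row/column i.i.d. ±1, Toeplitz completion to
N×N, M rows drawn without replacement, scaled 1/√M. The ±1 (rather
than 0/1) convention matches the chipping interpretation of the analog
front end. The random-demodulator simulation multiplies the stream by
an i.i.d. ±1 chip sequence and integrates-and-dumps over M windows of
length N/M (tail zero-padded when M ∤ N, logged); it returns the exact
equivalent `rd_structured` matrix, and streaming vs matrix-product
agreement to 1e−12 is a tested invariant.

Suitability is probed two ways:

* **Mutual coherence** μ = √N · max |⟨row(Φ), col(Ψ)⟩| over
  unit-normalized rows/columns, μ ∈ [1, √N] for a basis Ψ.
* **RIP surrogate**: exact verification of the restricted isometry
  property is combinatorial, so `rip_surrogate` samples random
  K-column submatrices (unit-normalized columns) and records the worst
  deviation of squared singular values from 1, passing at δ̂ < 0.5.
  This is a lower bound on the true constant, used as a sanity gate: a
  failed probe in `compress` is a recorded warning, not an error. At
  the operating point (K = 11 columns of a 250×1024 Bernoulli matrix)
  the worst-over-200-draws statistic sits almost exactly at the 0.5
  gate (measured 0.47–0.52 across matrix draws), so the gate outcome
  there is draw-dependent; recovery itself is unaffected, as the
  phase-transition tests show.
* **Measurement-count bound** M ≥ β·K·ln(N/M) with β = 2 by default
  (the constant is conventional; natural logarithm).

## Dictionary selection

`select_sensing_dictionary` learns an N×N candidate from thresholded
training segments: initialization from training-data columns when ≥ N
signals are available, otherwise a DCT basis perturbed by seeded 1%
noise; then alternating OMP sparse coding (K_max = ⌈0.05 N⌉ by
default, tolerance 1e−6, correlation ties broken toward the lowest
index) and K-SVD-style atom updates (per used atom, rank-1 SVD of the
restricted residual; sign fixed so the atom's largest-magnitude entry
is positive; unused atoms re-seeded from the worst-represented
signal). Because a fresh OMP pass after an atom update is not
guaranteed to improve on the carried-over updated coefficients, each
sweep keeps per signal whichever code has the smaller residual; the
recorded error history is therefore non-increasing by construction.
Rows are then selected (uniform random, or deterministic leverage
scores), and the candidate is nominated against a freshly drawn
same-size Binary-Toeplitz matrix by comparing mutual coherence with
the sparsity basis — the comparison criterion and row-selection scheme
are package interpretations, since only the comparison step itself is
prescribed. Ties go to the BT reference as the simpler candidate.

## Recovery

Routing follows the class-aware rule: healthy and myopathy segments
(time-sparse) → ℓ1; neuropathy segments (frequency-sparse) → ℓ1-ℓ1;
block-sparse or not-otherwise-sparse segments → BSBL. Explicit route
overrides are available, including the alternative reading that sends
neuropathy to plain ℓ1.

**ℓ1 / ℓ1-ℓ1.** The programs

    min ‖D‖₁                    s.t. ‖C − ΦD‖₂ ≤ ε
    min ‖D‖₁ + λ‖FD‖₁           s.t. ‖C − ΦD‖₂ ≤ ε
    min Σᵢ λᵢ‖ΨᵢD‖₁             s.t. ‖C − ΦD‖₂ ≤ ε

use the orthonormal *real* Fourier matrix for F (cos/sin pairs), which
keeps all arithmetic real; λ defaults to 1, ε to 1e−6·‖C‖ (noiseless
setting). When ε ≤ 1e−5·‖C‖ the constraint is treated as an equality
and the program is solved as a linear program with HiGHS (the pure-ℓ1
case via positive/negative parts D = p − q, the multi-term case via
auxiliary bound variables); otherwise an ADMM splitting with
per-term soft thresholding and an ℓ2-ball projection is used
(ρ = 1, tolerance 1e−8 on scaled primal/dual residuals, iteration cap
20000, 1e−12 ridge jitter on the Gram factorization). λ = 0 terms are
dropped algebraically, which realizes the exact reduction of ℓ1-ℓ1 to
ℓ1. Fixed solver settings make results deterministic.

**BSBL.** The block model places a zero-mean Gaussian prior on each of
g = N/h non-overlapping blocks (default h = 16, chosen to divide 1024;
h = 1 degenerates to entry-wise sparse Bayesian learning):
Σ₀ = blockdiag(γᵢ·B), where B = Toeplitz(1, r, r², …) is a *shared*
intra-block AR(1) correlation matrix — one r for all blocks keeps the
hyperparameter count at g + 2, and per-block correlation rarely
identifiable at these block sizes. EM iterates: (a) Gaussian posterior
mean/covariance of D given C (M×M system solved by Cholesky with 1e−10
jitter); (b) γᵢ ← tr(B⁻¹ Mᵢ)/h with Mᵢ the blockwise posterior second
moment; r ← (mean lag-1)/(mean lag-0) of the γ-normalized average
block moment, clipped to |r| ≤ 0.99; noise variance by its EM update
with floor 1e−12. Blocks with γᵢ < 1e−8·max γ are pruned to exactly
zero. Convergence when the largest relative γ change drops below 1e−4
(cap 300 iterations).

## Metrics

PRD = 100·√(Σ(D−D̂)²/ΣD²); Monte-Carlo RMSE = mean over L repetitions
of ‖D_l − D̂_l‖/‖D̂_l‖ (L = 50 by default); SNR = 20·log₁₀(‖D‖/‖D−D̂‖)
dB, capped at 300 dB for exact recovery; reconstruction accuracy =
max(0, 100·(1 − ‖D−D̂‖/‖D‖)) — the relative-error complement, defined
here because "accuracy" has no unique convention; CF = (D_b−C_b)/D_b·100
on bit budgets, equal to (1 − M/N)·100 at equal per-sample depth.
SEN = TP/(TP+FN) and SPE = TN/(TN+FP) in the standard form; `prd` and
`sen_spe` expose `paper_literal` flags computing the variant printed
forms (squared-error ratio without root/percent; TP+TN sensitivity
denominator) seen in parts of the compression literature. Because
"compression ratio" is used inconsistently in that literature, tables
always carry both SSR = M/N and CR = N/M and never a bare "CR". The
measurement-count reduction M/N is the only power proxy reported;
power in watts and wall-clock timing are out of scope.

The K-NN check classifies segments by (RMS, mean absolute value,
zero-crossing count, spectral-centroid frequency), standardized by the
training statistics, Euclidean metric, k = 5, majority vote with ties
to the alphabetically lowest label.

## Monte-Carlo harness and problem sizes

`metrics.run_sweep` emits one tidy row per (sparsity, M) grid cell,
each aggregating L independent repetitions with per-repetition seeds
derived from a `SeedSequence` of (spec seed, cell indices, repetition),
so identical specs reproduce tables byte-for-byte. The shipped test
suite and the acceptance script use the sensor's operating point
(N = 1024, K = 11, M ∈ {102, 250, 256}, 20–50 repetitions) for the
headline quantities and scaled-down grids (N = 64–256, L = 2–5) for
directional and structural properties; the scaled grids sit well away
from saturation so monotone trends (RMSE falling and accuracy rising
with more measurements) are actually exercised.

## Degenerate inputs and tie-breaks

Zero measurement vectors return exact-zero reconstructions without
invoking a solver. Zero reference signals make PRD/SNR/accuracy
undefined and raise. Constant segments threshold to all-zero (DC
removal eliminates them). OMP correlation ties and K-NN vote ties
break toward the lowest index/label; SVD sign ambiguity is fixed by
the largest-magnitude entry. The WFDB writer quantizes to int16 at
gain 10⁴ (resolution 1e−4 on ±1-normalized data); round-trips are
exact only to that declared precision.

## Known limitations

* The generator's class separation is deliberately idealized; K-NN
  accuracies near 100% on synthetic data say nothing about clinical
  discrimination.
* The RIP surrogate is a randomized lower bound; it cannot certify
  recovery, only flag clearly bad draws.
* BSBL learns a single shared r; signals with strongly heterogeneous
  intra-block correlation are fit conservatively.
* The ADMM path inherits first-order convergence: very small ε with
  ill-conditioned Φ may hit the iteration cap (reported via
  `converged=False` and the `reason` field rather than raising).
* Only format-16 single-.dat WFDB records are supported.
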