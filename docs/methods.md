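# Methods

This note records the models, numerical choices, and open design
decisions behind `thznitro`, and what the synthetic benchmarks do and do
not establish.

## The synthetic stated world

The generator (`thznitro.synthetic`) draws an 80-leaf nitrogen-stress
experiment: 4 gradients × 20 samples, nitrogen per sample
`N_i = max(0, μ_g + ε)`, `ε ~ N(0, 0.3²)`, gradient means
{1.5, 2.5, 3.5, 4.5} % mass — a plausible leaf-nitrogen range producing
a response spread comparable to the ~0.18 % RMSE regime typical of THz
leaf calibration. The spectrum of sample *i* on a 682-point grid over
(0, 1.4] THz (so 22 equal intervals of 31 points tile it exactly) is

    x_i(f) = G(f; 0.7, 0.25) · (1 + a·N_i)                    (peak)
           − Σ_b e·N_i · G(f; f_b, σ_b)                       (N bands)
           − Σ_k z_ik  · G(f; f_k, σ_w)                       (interferents)
           + ε(f),    ε ~ N(0, 0.05²) i.i.d.

with `G` a unit-height Gaussian bump.

**Nitrogen bands.** Five centers (0.574, 0.624, 0.642, 0.704, 0.817 THz)
with depth gain `e = 0.2` per % nitrogen. The declared half-width
`band_width = 0.02 THz` defines the ground-truth window of
`true_informative_indices` (points within ±band_width of a center); the
bump's σ is `band_width/1.5`, so the window edge sits at 1.5 σ and the
feature's support lies essentially inside the window. This alignment is
deliberate: if σ equaled the window half-width, the Gaussian tails
outside the window would carry real nitrogen signal, any sound selector
would pick them, and the benchmark would count correct physics as false
positives.

**Baseline stratification.** The peak amplitude grows by `a = 0.005` per
% nitrogen — visible when gradient-mean curves are overlaid (the
stratified-fan appearance of real nitrogen-stress power spectra), but
deliberately below the per-frequency noise floor. A strong baseline
pathway would make *every* under-peak frequency nitrogen-informative and
the notion of a planted ground truth meaningless.

**Interferents.** Twelve bands (σ from width 0.03 THz) with per-sample
half-normal strengths `z_ik = |N(0, 0.3²)|`, independent of nitrogen,
emulating the leaf constituents — chiefly water — that dominate THz
absorption and vary from leaf to leaf. This term is load-bearing: we
measured that with white-noise-only off-band variables, adding hundreds
of junk columns to the true band set does **not** raise 10-fold RMSECV
at n = 60–80 (a latent-variable regression weights them ≈ 0), so
discarding them confers no measurable benefit and subset-size selection
is unidentifiable. Structured, y-independent interferent variance gives
retained junk a real cross-validation cost, which is the regime in which
frequency-band selection earns its keep on real spectra.

**What the generator does not emulate:** instrument line shapes, ATR
optics, water-vapor absorption lines, wavelength-dependent noise,
scattering baselines, or reference-chemistry error (nitrogen values are
exact). A green benchmark establishes that the algorithms recover
structure *of this kind*; it says nothing about absolute accuracy on
real leaves.

## Preprocessing

Savitzky–Golay with window 7 (the workflow's stated width) and
polynomial order 2 (conventional; the order is not stated in the
emulated workflow and is exposed). A single pass is applied. Edges are
handled by evaluating the boundary window's polynomial at the edge
positions (scipy `mode="interp"`), keeping the grid length unchanged so
iPLS interval arithmetic stays aligned.

## PLS engine

Single-response NIPALS with column centering, no scaling: per component
`w ∝ X'y`, scores `t = Xw`, loadings `p = X't/t't`, `q = y't/t't`,
deflation of X and y; `b = W(P'W)⁻¹q`. If the residual is exhausted
early the remaining components are zero. The engine agrees with
scikit-learn's `PLSRegression(scale=False)` to machine precision and
with OLS at full rank (both asserted in tests); it is hand-rolled only
because the selectors fit tens of thousands of small models and
per-call overhead dominates otherwise.

Cross-validation: leave-one-out, or k-fold with a seeded shuffle and
contiguous folds (`n_folds = n` reduces exactly to LOO). Component
counts are silently clipped to `min(n_train − 1, p)` inside CV loops.

RMSE uses an `(n−1)` denominator — unconventional, but it is the form
this workflow reports; `denominator="n"` restores the standard form.
R² is `1 − SSE/SST` (the printed alternative form of the source formula
is internally inconsistent).

## Selectors

**UVE.** Artificial noise `U(0, 1e-10)` (scale-free for the stability
ratio; small enough not to perturb the fit), LOO coefficient matrix on
the augmented data, threshold = max |noise stability| (factor 1.0,
exposed). The stability statistic is computed at latent rank 2 rather
than the modeling rank: at higher ranks NIPALS coefficients compete
within a collinear band and per-frequency stability turns erratic
(measured recall on planted bands: 0.94 at rank 2 vs 0.53 at rank 5).
Stabilities with zero coefficient variance are set to 0 with a warning.

**SCARS.** 50 runs. Per run: Monte-Carlo stability from 50 draws of
*half* the calibration samples (half-size draws let chance
interferent–nitrogen correlations flip across draws instead of looking
"stable"); an exponential decay schedule `r_i = a·e^(−k·i)` with
endpoints `r_1 = (P−1)/P`, `r_50 = 2/P` sets the run's quota; half the
quota is force-kept by stability rank and the rest drawn without
replacement from the remaining survivors with probability ∝ c_j, so
subset sizes follow the schedule exactly (with-replacement ARS plus
deduplication would shrink sizes ~0.6× per run and break the schedule).
Every run is scored by tenfold RMSECV on **one shared fold partition**,
so differences between runs reflect the subsets rather than fold luck;
the subset with minimal RMSECV is returned.

*Known limitation (measured, and visible as the one red acceptance
check):* the RMSECV-versus-run trace is nearly flat across a several-fold
range of subset sizes — in-band frequencies are mutually redundant, so
dropping window-edge points is almost free, and even interferent-laden
junk costs little at the margin. The argmin therefore lands at subset
sizes varying roughly two-fold across seeds. SCARS reliably concentrates
its subset on the planted bands (band-level recovery is tested and
green), but simultaneous index-level recall ≥ 0.8 and FPR ≤ 0.1 is met
in only about half of seeds. Sharpening this would require a parsimony
rule (e.g. smallest subset within one standard error of the minimum)
instead of the plain minimum-RMSECV rule this workflow specifies.

**iPLS.** Contiguous interval blocks whose sizes differ by at most one
(`682/22` → exactly 31 points each), LOO RMSECV per block, argmin wins.
The printed THz bounds reproduce the conventional interval-table
arithmetic: the interval width is rounded to 4 decimals before
multiplying out boundaries (1.4/22 → 0.0636; interval 12 is labeled
0.6996–0.7632 THz) with the final bound capped at the band edge;
selected indices always use the true grid. The interval-count search
simply re-runs the selection for each candidate count (10–45 by
default) and returns the count whose best interval cross-validates best.

## Calibration models

**Exact-design RBF network.** Centers = all calibration samples;
activations `a_i(x) = exp(−(0.8326·‖x − c_i‖/spread)²)` so a unit falls
to 0.5 at distance `spread` ("expansion speed"); output weights and bias
solve the Q×(Q+1) system by min-norm least squares (SVD), tolerating —
and warning about — numerical rank deficiency at large spreads. The
design interpolates its calibration set, so calibration RMSE is ~0 at
*every* spread; consequently the spread sweep reports RMSEC per spread
as a diagnostic but cannot select on it, and the pipeline's
`spread="auto"` adds an internal 80/20 hold-out of the calibration set
and picks the spread by validation RMSE.

**BPNN.** One tanh hidden layer (6 units), linear output, min–max
scaling of inputs and output to [−1, 1] on calibration statistics only,
full-batch gradient descent at rate 0.01, seeded initialization, early
stop on relative loss change < 1e-8. The default budget of 22 epochs
mirrors the emulated workflow's reported iteration count, which came
from a second-order MATLAB trainer; plain gradient descent needs far
more (the convergence test uses thousands), so the default-budget BPNN
underfits by design and `max_epochs` is the first knob to raise.

## Reproducibility

All randomness flows from numpy `default_rng` seeds. The pipeline
derives one sub-seed per stage by hashing the global seed with a stage
tag (SHA-256, reduced below 2³¹), so stages are independently
reproducible and a rerun of the same configuration writes byte-identical
artifacts. KS splitting is fully deterministic with ties broken toward
the lower sample index.
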