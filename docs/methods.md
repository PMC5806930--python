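# Methods

`sozloc` localizes the seizure onset zone (SOZ) from multichannel ECoG by
(1) estimating a pairwise causal-influence graph from short ictal windows,
(2) ranking electrodes with a hub-minus-authority personalized PageRank, and
(3) keeping only electrodes whose rank is simultaneously high among the
ictal scores and significant against an empirical null built from rest
windows. This note records the model, the tunable parameters, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Block design

The pipeline analyzes 10-second windows. One *ictal block* is anchored at
the annotated start of each seizure: at seizure onset the abnormal activity
is assumed not to have spread, so electrodes over the SOZ should exert
disproportionate causal influence on the rest of the grid. *Rest blocks*
are sampled uniformly at random from the part of the recording that is at
least `guard` seconds (default 120 s) away from any seizure and outside all
annotated artifact intervals; rest blocks may overlap one another. Ten
seconds trades off approximate stationarity of ECoG against the sample size
the pairwise estimators need. Sample indices are 0-based and intervals are
half-open `[start, end)` in seconds.

Signals are restricted to sub-100 Hz activity with a 4th-order Butterworth
low-pass applied forward-backward (zero phase — phase distortion would shift
apparent lead-lag relations), decimated to a working rate of 200 Hz
(polyphase resampling when the ratio is not an integer; reflect padding at
the edges), and standardized per channel within each block. Recordings
already at or below the working rate are standardized only. A constant
(flat) channel is an error naming the channel.

## Causal-influence graphs

For an N-channel block the complete directed graph G (zero diagonal) holds
one of two measures for every ordered pair (i, j):

* **Granger causality (GC)** — `ln(var_reduced / var_full)`, residual
  variances of channel j regressed on `gc_order` of its own lags without /
  with the same number of lags of channel i. `gc_order` may be fixed or
  `"auto"` (BIC over orders 1–10 on the own-lags model, resolved per target
  channel). All pairs in a block share one set of lagged second moments, so
  the N(N−1) regressions cost one Gram matrix plus small solves.
* **Directed information rate (DI)** — the conditional mutual information
  `I(Y_t ; X_{t−m..t−1} | Y_{t−m..t−1})` estimated with the
  Frenzel–Pompe / Kraskov k-nearest-neighbour construction: max-norm balls
  sized by the k-th neighbour in the joint space, neighbour counts in the
  (W,Z), (X,Z), (Z) marginals, digamma corrections, averaged over the
  block. Defaults m = 2, k = 4. `max_eval` optionally evaluates the average
  on an evenly strided subset of time points (neighbour searches still use
  the whole block) to bound cost on large grids.

For linear Gaussian processes the DI rate equals half the Granger
causality; the test suite uses this identity, plus the Yule–Walker closed
form on a specified bivariate VAR(1), as independent oracles. Negative
estimates are clipped at zero because the PageRank normalizations require
nonnegative weights. Estimates are deterministic given the block and
parameters, and pair order never matters. Graphs from multiple seizures are
combined by element-wise averaging (single-focus assumption).

## Ranking

Row-normalizing G (column i of P is row i of G normalized; all-zero rows
become uniform columns 1/N) gives a column-stochastic matrix P. The
authority vector solves `(I − αP) a = (1 − α) v_a` with the teleportation
vector `v_a` proportional to total inflow per node; the hub vector repeats
the computation on Gᵀ with `v_h` proportional to outflow (Reverse
PageRank). The damping factor defaults to α = 0.85; as α → 0 the scores
reduce to normalized in/out-flow, and larger α weights the global graph
structure. The node score is s = h − a (sums to zero; exactly zero for
symmetric G; invariant to rescaling G). Grids are small, so the linear
system is solved densely; power iteration is kept as an independent route
and agrees to 1e-10.

## Inference and the empirical null

`S0` is the set of nodes in the top `p0` percentile of the ictal scores
(default p0 = 10). Percentiles use linear interpolation between order
statistics, and the threshold is closed (ties included) so quantized scores
never drop a genuinely top-ranked node. High scores can also reflect a
patient-specific rest-state network structure rather than seizure dynamics,
so each node's score is additionally compared with its own empirical null:
R times (default 200) the pipeline samples N_S rest blocks (N_S = number of
seizures), runs the identical graph/scoring machinery, and stores the
score vector; `S1` keeps nodes whose ictal score reaches the top `p1`
percentile (default 5) of their own null row. The inference is S = S0 ∩ S1.
The DI graph is tried first; if S is empty the entire procedure, including
a fresh null, is repeated with GC, and the algorithm terminates even if
that set is empty too. Failed null repetitions (e.g. a flat channel in an
unlucky window) are resampled and counted, so R is always met. One master
seed drives all sampling through a single generator, making runs
bit-reproducible.

`build_null` defaults to fully independent rest-block draws per repetition.
With `null_pool = B` it instead precomputes B single-block graphs and lets
each repetition average N_S of them drawn without replacement — an
approximation that reuses graphs across repetitions, used where the k-NN DI
measure makes 200 × N_S independent graph estimates impractical.

## Evaluation

An inference is *successful* when strictly more than 50% of its nodes lie
in the protected set — the expert-marked electrodes of interest (EOI) plus
the grid nodes strictly adjacent to them (8-neighbourhood by default; the
convention is configurable). An exactly-50% overlap does not count. The
false-positive rate V_p divides inferred nodes outside the protected set by
all grid nodes outside it. Baselines for comparison: *net-flow* (outgoing
minus incoming total weight) and the *no-null top-5%* variant (p0 = 5,
p1 = 100, skipping the empirical-distribution comparison).

## Synthetic benchmark

The generator draws a stable linear Gaussian VAR on an electrode grid:
per-channel AR(2) self terms (0.5, −0.2), nearest-neighbour (4-adjacency)
cross-coupling of magnitude 0.05 at lag 1, unit-variance innovations.
During each annotated seizure the planted source node's outgoing coupling
row is multiplied by `source_gain` (hard switch at the boundaries; the
pipeline reads windows away from boundaries except the ictal block itself).
Both regimes must have companion spectral radius < 1 or the configuration
is rejected. The linear Gaussian choice makes population GC and DI
available in closed form (Lyapunov/Yule–Walker), so the generator doubles
as the oracle for the estimator tests, and ground truth (SOZ = source node)
is exact by construction. What it does not emulate: nonstationary seizure
evolution, interictal discharges, line noise, volume conduction, or any
biophysical (neural-mass) realism — passing tests show the pipeline's
statistical machinery works, not that it handles every artifact of real
ECoG.

## Problem sizes used by the test suite

Simulations in the suite are sized for a single CPU: synthetic sessions are
generated directly at 50 Hz (10-s blocks of T = 500 samples, no decimation
step), null calibration uses the GC measure (the significance rule being
calibrated is estimator-agnostic, and GC graphs are orders of magnitude
cheaper than k-NN DI graphs) on 50 sessions of 4×4 grids with R = 200, and
the planted-source recovery cohort runs 20 sessions of 6×6 grids with
R = 50 repetitions resampled from an 8-graph rest pool and the DI average
evaluated on 128 strided centers.

## Known limitations

* **Desk-scale power of the DI route.** With the default rest coupling
  (0.05) and `source_gain = 3`, each strengthened edge carries a population
  DI of ≈ 0.015 nats (closed form). The sampling error of a k-NN conditional
  mutual information estimate at a few hundred to a few thousand samples is
  of the same order as that effect, so per-edge detection through the
  nonparametric route is marginal, whereas the parametric GC estimator
  resolves the same effect with a large margin and localizes the source
  essentially always (see the GC-route test). Because the DI-first
  algorithm only falls back to GC when S_DI is *empty* — and percentile
  selection plus per-node significance applied to a noisy score vector
  returns a nonempty (wrong) set far more often than an empty one —
  end-to-end recovery through the DI route fails at weak effect sizes; the
  recovery test documents the measured rates at the suite's problem sizes.
  This is a property of the nonparametric estimator class at these sample
  sizes, not of the ranking or null machinery.
* Pairwise measures cannot separate direct influence from common input;
  causally conditioned (multivariate) DI is out of scope by design.
* No multiple-testing correction beyond the percentile rules, matching the
  procedure the package implements.
* No line-noise notch or re-referencing; recordings are assumed referenced
  sensibly upstream.
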