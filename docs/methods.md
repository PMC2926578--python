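# Methods

## The coupling estimator

`gammasync` measures synchrony between band-limited oscillatory
signals as *instantaneous coupling* (IC): the maximum, over a small
range of integer sample lags, of the Pearson correlation between a
base segment and a lag-shifted segment of another channel, computed on
a window whose width is set by the base signal's own half-cycles. The
underlying assumptions are that (i) synchrony episodes last only a few
cycles, so the window must be short; (ii) the signals' frequency
drifts, so a window fixed in samples is calibrated only for one
frequency, whereas a window fixed in half-cycles tracks the local
period; and (iii) allowing roughly one half-cycle of lag in each
direction converts strong antiphase alignment into a positive
correlation, so IC is effectively nonnegative except for near-zero
noise values.

Conventions pinned down where the construction leaves freedom:

- **Half-cycle boundaries.** A boundary is the first sample whose sign
  differs from its predecessor's; a sample exactly at zero belongs to
  the *following* half-cycle. No sub-sample interpolation is done —
  windows are defined in whole samples. For band-passed recordings
  whose cycles need not cross zero, boundaries can instead be taken at
  upward crossings of π/2 + kπ in the unwrapped Hilbert phase, which
  coincide with the zeros of a clean A·cos φ signal.
- **Lag range.** lag_bound = round((Z_{i+w} − Z_i)/w) + 1,
  round-half-away-from-zero: the window's mean half-cycle length in
  samples, plus one ("a little more than one half-cycle"), computed
  per window and therefore adaptive.
- **Means per lag.** Both segment means are recomputed inside the
  window for every lag; the correlation at lag h is the ordinary
  Pearson correlation of {x_t} and {y_{t+h}}.
- **Ties.** If several lags attain the maximum exactly, the smallest
  |h| wins; between +h and −h, +h wins. Deterministic and favoring
  zero lag.
- **Edges.** A window whose shifted range would leave the epoch is
  dropped, not truncated; the counts of windows dropped at either end
  are reported on the IC series. Filter edge transients are likewise
  not trimmed automatically — indexing stays transparent, and callers
  can discard ~0.05 s.
- **Defaults** w = 6 half-cycles (three cycles) and m = 2 (overlap of
  two cycles): small enough to resolve episodes a few cycles long,
  large enough not to inflate the correlation of unrelated signals.
  The w-sensitivity is real and tested: on independent noise, mean IC
  decreases strictly as w grows through {3, 6, 18}.

Fisher-z intervals use half-width z_{α/2}/√(n−1) with n the window's
sample count — the only sample size in play. At n ≈ 200 and true
correlation 0.5 the 95% interval covers at 95.35% in a 2000-replicate
Monte-Carlo check. The interval ignores the maximization over lags, so
it should be read as an interval for the correlation at the selected
lag, not a selection-corrected bound.

## Preprocessing

Gamma extraction is a 4th-order Butterworth band-pass with corners
exactly at (40, 100) Hz, applied forward–backward (zero phase). The
attenuation of the doubled pass exceeds 20 dB at half the low corner
and at 1.5× the high corner. Forward–backward filtering commutes with
time reversal up to edge transients that decay with the filter's time
constant (below 1e−9 of signal scale after ~0.3 s at 1500 Hz); the
property test checks the interior.

## The multivariate beta layer

IC vectors live in (0,1)^J, so each latent coupling state is modeled
by a multivariate beta (MVB) distribution: u_j = v_j/(1 + v_j) for an
inverted-Dirichlet v, equivalently u_j = G_j/(G_j + G_{J+1}) with
independent unit-scale gamma variates G_j ~ Gamma(θ_j). Its J = 1 case
is Beta(θ_1, θ_2); the log-density is evaluated directly (see
`gammasync.mvb`) and is verified in tests by quadrature normalization
for J ∈ {1, 2} and pointwise agreement with the scipy beta for J = 1.
The printed form of the density carries the exponent −(θ_j + 1) on
(1 − u_j); only that sign normalizes, which the quadrature check
enforces. The gamma-ratio sampler is validated against the density
(Kolmogorov–Smirnov on marginals; mean log-density maximized at the
generating parameters) rather than by derivation.

Before fitting, IC values are clipped into [0.00001, 0.99999] — beta
densities are undefined at the boundary, and the handful of
nonpositive IC estimates seen in practice are all near zero. Clipping
is an explicit, idempotent step; the raw series keeps unclipped values
and maximizing lags for diagnostics.

Maximum likelihood (weighted, for the M-step) is solved over
η = log θ with L-BFGS-B and an analytic gradient. The weighted
log-likelihood depends on the data only through sufficient statistics
(Σ w log u_j, Σ w log(1−u_j), Σ w log(1 + Σ u/(1−u)), Σ w), so each
solve costs O(J) per iteration regardless of N. The solver never
returns a point below its starting likelihood; a positivity floor of
1e−6 guards the back-transform.

## Mixture fitting and model selection

The EM loop computes responsibilities in the log domain with
per-observation max subtraction (shape values near 40, as arise for
sharply peaked states, overflow raw densities), then updates mixing
probabilities as responsibility means and component parameters by
weighted MLE warm-started from the previous iterate. Stopping is
likelihood-based — relative |Δℓ_mix| < 1e−6, max 500 iterations —
because the likelihood is invariant to the parameterization. The trace
of ℓ_mix is stored and asserted nondecreasing (tolerance 1e−8 per
step) on every tested run.

Initialization follows cluster-then-fit: Euclidean k-means on the raw
IC values (25 restarts, best within-cluster sum of squares), then per
cluster a univariate Beta(α_j, β_j) MLE per dimension. The MVB couples
every dimension's second shape to the shared θ_{J+1}, so the J pairs
are combined as θ^(0) = (α_1, …, α_J, mean_j β_j) and refined by one
MVB MLE on the cluster before EM starts. In tests this start reaches
the same final log-likelihood as the best of 10 random starts to
within 1e−3.

A component whose effective weight Σ_i r_{k,i} falls below J + 1
cannot support a (J+1)-parameter fit; the EM run is restarted with a
fresh initialization (up to 3 retries) and otherwise fails that p.
Model selection minimizes BIC_p = −2ℓ_mix + [p(J+2) − 1] log N′ over
p (default 2–8; p = 1 on request); ties within 1e−6 go to the smaller
p, and candidate p values whose fit failed are excluded and logged.
Hard states take the largest responsibility, ties to the smallest
label. Mixture labels are not identifiable, so recovery tests match
components by the permutation minimizing total |θ| error.

## Synthetic data

The generator provides the study's two self-contained data sources.

**Signal pair.** X(t) = sin{2π[70 + 10 sin(0.5πt)]t} and
Y(t) = sin{2π[50 + 10 sin(0.5π(t−2))]t} on t ∈ [0, 20] s at 1500
samples/s. The grid is t_k = k/rate *inclusive* of the endpoint
(30001 samples), which makes integer-cycle instants exact zeros; the
summary statistics are insensitive to this choice. The signals'
instantaneous frequencies (60–80 Hz and 40–60 Hz) meet at 60 Hz
simultaneously, but their *observed* frequencies — zero crossings
counted in [t − 0.05, t + 0.05], halved, divided by 0.1, with both
endpoint samples included and the first/last 0.05 s excluded — swing
between 0 and ~385 Hz (X) and 0 and 340 Hz (Y), with medians 95 and
85 Hz. Their difference (median 120 Hz, max 130 Hz in absolute value)
divided by 130 gives a −1..1 synchrony index: zero at synchrony. The
counting window spans 151 crossing slots, one slot over 0.1 s, so a
pure tone reads one 5 Hz quantization step high at a few percent of
alignments; this is inherent to whole-sample counting.

**Mixture datasets.** States drawn from Categorical(π), rows from the
gamma-ratio MVB sampler, with ground-truth labels returned. The
recovery conditions exercised in tests are: a two-state J = 2 design
(π = (0.3, 0.7), θ_1 = (8, 2, 3), θ_2 = (2, 9, 3), N′ = 3000), chosen
so the two states concentrate on different channels with realistic
overlap, and a three-state J = 4 design with one dominant shape (12)
per state's coupled channels and θ_{J+1} = 3, separated to the degree
that distinct coupling patterns separate in practice. At these sizes
EM recovers π within 0.05 and θ within 20%, and BIC selects the true
p = 3 in 20 of 20 seeded replicates.

Problem sizes throughout (20 s of signal, N′ in the low thousands,
20 replicates for selection studies) are the package's chosen test
conditions: large enough for the asymptotics the estimators rely on,
small enough that the whole suite runs in about a minute and a half on
one core.

## What the synthetic data does and does not show

The signal pair is noiseless and perfectly band-limited by
construction; it validates the *windowing geometry* — that a
half-cycle-locked window tracks drifting frequency where fixed windows
miscalibrate — but not robustness to measurement noise, amplitude
nonstationarity, volume conduction, or artifacts in real EEG. The
mixture datasets draw i.i.d. rows, whereas consecutive IC windows
overlap and are serially dependent; the EM layer's consistency under
that dependence rests on large N′, not on the tests here. Passing
tests therefore demonstrate correctness of the estimators and fitting
machinery under the stated models, not end-to-end performance on
recordings.

## Known limitations

- The IC is computed from one base signal's perspective; couplings
  among non-base channels require re-running with those channels as
  base, and no fusion across perspectives is provided.
- The Fisher interval is not corrected for lag selection or for
  within-window autocorrelation of band-passed signals.
- BIC's parameter count treats observations as independent; with
  heavily overlapping windows (m ≪ w) the effective sample size is
  smaller than N′ and BIC may over-select states.
- EM finds local optima; the k-means/beta start is good in the tested
  regimes but multimodality grows with p and J.
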