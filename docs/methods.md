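# Methods

This note documents the models, procedures, parameters, and design
choices behind `bifurcell`, in the order data flows through the package.

## 1. Normal-form training corpus (`bifurcell.maps`, `bifurcell.dataset`)

### Model family

Each training model is a one-dimensional discrete-time map built from the
normal form of a local bifurcation plus random higher-order terms and
additive white noise:

- fold: `x' = -mu + x - x^2 + sum_{i=3}^{10} a_i (x - sqrt(-mu))^i + s e`
- transcritical: `x' = (1 + mu) x - x^2 + sum_{i=3}^{10} a_i x^i + s e`
- pitchfork: `x' = (1 + mu) x +/- x^3 + sum_{i=4}^{10} a_i x^i + s e`

with `a_i ~ N(0, 1)`, noise amplitude `s ~ U(0.005, 0.015)`,
`e ~ N(0, 1)`, and the pitchfork cubic sign a fair coin per model.  The
higher-order terms are centered on the tracked equilibrium (`sqrt(-mu)`
for the fold, the origin otherwise), so they vanish there to second
order: the equilibrium and the dominant eigenvalue (`1 - 2 sqrt(-mu)`,
fold; `1 + mu` otherwise) are exact regardless of the random
coefficients.  The bifurcation is at `mu = 0`, where the eigenvalue
reaches 1.

`mu0` is sampled so the initial eigenvalue lies in [0, 0.8]: fold
`mu0 ~ U(-0.25, -0.01)`, transcritical/pitchfork `mu0 ~ U(-1, -0.2)`.

### Simulation and the pseudotime construction

Forced runs ramp `mu` linearly (inclusive grid) from `mu0` to 0 over 600
steps starting at the equilibrium; null runs hold `mu = mu0`.  A
noise-induced transition is declared at the first step whose deviation
from the deterministic equilibrium at the *current* `mu` exceeds
`10 s`; the series is truncated strictly before that step.  A run is
valid when at least 500 points remain; the trailing 500 are kept.

Twenty replicate runs of one model are combined into twenty pseudotime
series by the wrapped-diagonal rule `y[i, t] = x[(i + t) mod 20, t]`,
so consecutive points come from different replicates — emulating
pseudotime data, where each observation is a distinct cell rather than
one system evolving over time.  This removes single-trajectory temporal
autocorrelation while preserving ensemble signatures of the approaching
bifurcation (most prominently the variance profile).

The default corpus is 1000 models per bifurcation class x 20 series
(forced), plus an equal number of null series whose models are assigned
round-robin over the three classes (the null count is fixed; the class
mixture of null models is a free choice, and round-robin keeps it even), for 80 000 series total, shuffled and
split 0.95 / 0.025 / 0.025.  A model with any invalid replicate is
discarded and replaced, up to 100 attempts per slot.  All randomness
flows from one `SeedSequence` hierarchy (per-class streams; per-model
integer seeds define model parameters), making the corpus
bit-reproducible from `shuffle_seed`.

## 2. Classifier (`bifurcell.nn`)

Layer stack (both variants): conv1d(kernel 12, same zero padding, ReLU)
-> dropout 0.10 -> maxpool(2, 2) -> conv1d -> dropout -> maxpool ->
LSTM(U1, full sequence) -> LSTM(U2 = 20, final hidden state) -> dense
softmax over the four classes.  Variant 1: 50 filters, U1 = 100;
variant 2: 100 filters, U1 = 50.  Trainable-parameter totals are exactly
100 864 and 157 364, matching the analytic count

    (K+1) F + (K F + 1) F + 4 (F + U1 + 1) U1 + 4 (U1 + U2 + 1) U2 + (U2 + 1) 4.

The implementation is plain NumPy — forward pass, backpropagation
through time, and Adam — with float32 arithmetic.  Gradient correctness
is tested against a numerical directional derivative.  The even kernel
(12) is padded 5 left / 6 right, the convention under which output
position `i` sees inputs `i-5 .. i+6`.  After two pool layers the LSTM
input length is 125.  The forget-gate bias initializes to 1; other
weights are Glorot-uniform from a seeded generator, so builds are
deterministic per seed.  Dropout is active only during training.

### Input contract and censoring

A classifier input is a censored segment of a 500-point series: length
`L ~ U{50..500}`; variant 1 draws the start uniformly in `[0, 500-L]`
(censored at both ends), variant 2 anchors the segment at the series end
(censored only at the beginning), so it learns from data right up to the
bifurcation.  Segments are normalized by their mean absolute value and
left-padded with zeros to 500.  Censoring is re-drawn every epoch as
data augmentation (per-epoch re-drawing extracts more value from each
series than a single fixed censoring would).
The validation partition is censored once per run so the checkpoint
metric is comparable across epochs.

### Training and evaluation

Adam (lr 0.0005), batch size 1024, categorical cross-entropy, maximum
200 epochs with early stopping at patience 20, returning the checkpoint
with the lowest validation loss.  The desk-scale profile used by the
test suite and the acceptance script reduces this to 50 models per class
(4000 series), narrow networks (variant 1: 8 filters / 16 + 8 LSTM
units; variant 2: 16 filters / 8 + 8 units), batch 256, up to 60 epochs,
patience 10 — sizes chosen so a full generate-train-predict cycle runs
on one CPU in minutes while leaving the learning problem non-trivial.

Multiclass F1 is macro-averaged (the classes are balanced); binary F1
collapses fold/TC/PF into "bifurcation" as the positive class.  The
confusion matrix is row-normalized by true class.  Out-of-sample
predictions average the member probability vectors (5 + 5 networks at
full scale; 1 + 1 in the desk-scale profile).

## 3. EWS baselines (`bifurcell.ews`)

Rolling statistics over right-aligned windows of 0.25 of the series
(so each value uses only past data): sample variance (ddof 1), lag-1
autocorrelation (Pearson correlation of the window with its one-step
shift; undefined for constant windows, emitted as NaN), sample entropy,
and Lempel-Ziv complexity.  Trends are scored by Kendall tau-b against
time (ties corrected; all-tied series score 0).

Sample entropy uses m = 2, r = 0.2 x window SD, Chebyshev distance,
self-matches excluded, with both template orders drawn from the first
N - m windows; zero matches at either order yield NaN.  "Kolmogorov
complexity" is realized the standard way for this EWS: binarize at the
window median, parse with LZ76 (Kaspar-Schuster), normalize by
`n / log2(n)`.  Both implementations are tested for equality against
brute-force oracles (a double-loop transcription of the SampEn
definition; exhaustive small binary instances and a hand-traced parse
for LZ76).

ROC curves sweep the observed scores as thresholds (classifier score:
`1 - p_null` at the prediction time; baseline score: the Kendall tau of
the statistic on data up to that time); AUC is trapezoidal and is tested
to equal the pairwise Mann-Whitney statistic.

## 4. Expression pipeline (`bifurcell.pipeline`)

PC1 is the leading axis of the column-centered cells x genes matrix
(exact SVD, no randomized solver, for determinism), with the sign pinned
so scores correlate positively with pseudotime; ties in pseudotime are
broken by stable input order.  The trajectory is smoothed with a Lowess
filter — local-linear, tricube weights, span 0.2 of the points, 0
robustness iterations — and `trend + residuals` reconstructs PC1
exactly.  Long cell sequences are down-sampled by a factor of 100;
the factor phases partition the cell sequence and yield up to 100
distinct trajectories.  For biological-scale data the order is
down-sample, then detrend each phase trajectory.

Null trajectories resample residuals (with replacement) from the first
20% of the series onto the original trend: same trend, no approach-to-
transition signature in the fluctuations.

A prediction at pseudotime `t` uses residuals strictly before `t`,
tail-cropped to the most recent 500 points, normalized and zero-
prepended; times with fewer than 50 preceding points are marked
unavailable rather than predicted.  Causality (predictions invariant to
any modification of data at times >= t) is property-tested.

Perturbations rank genes by absolute loading on the *unperturbed* PC1,
zero (knockout) or scale by 2 (overexpression) the top k columns, and
recompute PC1 and the bundle from scratch.  Inputs are assumed already
log-normalized; `preprocess` (library-size scaling, log1p, top-3000
genes by dispersion) is provided but off by default.

## 5. Two-gene GRN fixture (`bifurcell.grn`)

The deterministic skeleton is the mutual-repression motif

    dg1/dt = m1 / (1 + g2^2)   - kD g1
    dg2/dt = m2 / (1 + c g1^2) - kD g2

(the Hill-repression reading is the only one with the fold/pitchfork
structure the scenarios require).  Scenario presets: fold — `m1` ramps
1 -> 4.75, `m2 = 3`, `kD = 1`, `c = 1`; pitchfork — `m1 = m2 = 1`, `kD`
ramps 1 -> 0.25, `c = 1`; null — fold preset with `c = 0.1`, which
removes the fold while keeping a time-dependent parameter.
Euler-Maruyama integration with dt = 0.01 and noise amplitude 0.05;
ramped parameters update every step; runs start at the deterministic
stable equilibrium of the ramp-start parameters (the natural choice:
the system is prepared on the branch it will follow) and `t_end = 600` gives 600 down-sampled
points (factor 100), putting the deterministic bifurcations near
two-thirds of the trace.

Equilibria come from the real roots of the degree-5 polynomial obtained
by eliminating `g2`, with stability from the 2 x 2 Jacobian; the
transition time of a scenario is located by continuation (fold-type:
the followed stable branch jumps; pitchfork: the symmetric equilibrium
loses stability).  Pseudotime series reuse the wrapped-diagonal
construction over 20 replicate simulations.  The downstream observable
defaults to the leading principal component of the assembled (g1, g2)
series (sign pinned positive against the index) — the same trajectory
coordinate the expression pipeline uses, and the one that weights
whichever gene carries the larger variance signal in a given scenario;
`g1` or `g2` alone are selectable.  With `g1` alone the fold scenario's
pre-transition signature is markedly weaker: its fluctuation asymmetry
is oriented opposite to the normal-form training convention (the
low-`g1` branch escapes upward, while the fold normal form's tracked
branch escapes downward).

## 6. Synthetic expression fixture (`bifurcell.synthexpr`)

The generator emulates the *shape* of pseudotime-ordered scRNA-seq data,
not its biology: a latent fate coordinate follows a randomized
normal-form map ramped to its bifurcation at a configured pseudotime
(default 0.75), then departs along a stylized saturating branch
(amplitude 3 x the pre-transition fluctuation scale) — the diverging
normal form itself is not a meaningful post-transition state.  The
latent trace is standardized by the fluctuation scale of its early
segment (the first 20% of pre-transition cells, before critical slowing
down inflates the variance) and clipped at 8 units — scaling by the
overall variance instead would let the departure amplitude crush the
pre-transition fluctuations that the early-warning statistics must
read.  A random subset of "informative" genes (default 40 of 200) reads
the standardized latent state through N(0, 1) loadings; all genes get
gene-specific baselines and N(0, 0.5) observation noise; cells are
evenly spaced in pseudotime.  Defaults are
sized so PC1 recovers the latent coordinate (|r| > 0.9) when informative
genes are present and nothing when they are absent — the planted-signal
regime a PCA-based pipeline assumes.

What this fixture does *not* model: count noise and dropout, library-
size variation, discrete cell types, regulatory-network kinetics, or
pseudotime estimation error.  Passing tests on it demonstrate that the
pipeline's machinery (PC1, detrending, down-sampling, nulls, sweeps,
perturbation bookkeeping) behaves correctly on data of the right shape,
not that the method succeeds on any particular biological dataset.

## 7. Numerical choices and degenerate inputs

- Normalization guard: segments with mean |value| < 1e-12 raise a
  degenerate-segment error instead of dividing by ~0.
- Transitioned map replicates are frozen at their exceedance value so
  the degree-10 polynomial cannot overflow in the vectorized simulator;
  their post-transition states are never used.
- Equilibria closer than 1e-7 in `g1` are deduplicated; roots with
  |imag| > 1e-8 are discarded.
- Kendall tau drops NaN window values; scipy's NaN for degenerate
  inputs is mapped to 0.
- PC1 sign falls back to a positive largest-magnitude loading when the
  pseudotime correlation is exactly zero or undefined.
- All stochastic tests are seeded; training determinism is a same-
  platform contract (BLAS reduction order may differ across platforms).

## 8. Known limitations

- Hopf and global bifurcations are out of scope; the classifier can
  only assign mass among fold/TC/PF/null.
- The classifier is univariate (PC1 only).
- Desk-scale training does not reach full-scale accuracy; the package
  reports its own measured F1 rather than claiming the full-scale
  numbers.
- The GRN fold scenario is harder for a reduced ensemble than the
  pitchfork scenario: at desk scale the approach to the fold is flagged
  as a bifurcation but typically attributed to the pitchfork class;
  class-exact attribution is a property of full-scale training.
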