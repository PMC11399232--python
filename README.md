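# bifurcell

Predicting the **timing and type of cell-fate transitions** from
pseudotime-ordered single-cell expression data.

Cell differentiation can be viewed as a bifurcation in a high-dimensional
dynamical system: as a control parameter drifts, a stable expression
state loses stability (transcritical), collides with an unstable state
and disappears (fold), or branches symmetrically into two fates
(pitchfork).  Near any such bifurcation, fluctuations show universal
signatures — critical slowing down, rising variance — that precede the
transition.  `bifurcell` trains a CNN-LSTM classifier on pseudotime
series simulated from a large library of randomized normal-form maps,
so that it learns these universal signatures rather than any particular
system, and then applies it to the first principal component of a
cells x genes matrix ordered by pseudotime.  The output at each point in
pseudotime is a probability vector

    (p_null, p_fold, p_transcritical, p_pitchfork),  sum = 1,

computed only from data strictly preceding that point.  The package also
implements the classical early-warning-signal baselines (rolling
variance, lag-1 autocorrelation, sample entropy, Lempel-Ziv complexity,
each trend-scored by Kendall tau), a two-gene gene-regulatory-network
fixture with genuine fold and pitchfork bifurcations, a synthetic
expression generator with a planted transition, ROC comparison of all
methods, and in-silico gene knockout / overexpression analysis.

Who it is for: computational biologists analyzing differentiation
trajectories who want a quantitative early-warning call — and a type
call — for an approaching fate decision, plus the tooling to validate
that call against nulls and classical baselines.

## The model in brief

Training data are 500-point "pseudotime" series assembled from 20
replicate simulations of maps of the form (fold case)

    x_{t+1} = -mu_t + x_t - x_t^2 + sum_{i=3}^{10} a_i (x_t - sqrt(-mu_t))^i + sigma eps_t,

with `mu_t` ramped linearly to the bifurcation at `mu = 0` (forced) or
held fixed (null), via the wrapped diagonal `y[i, t] = x[(i+t) mod 20, t]`
so consecutive points come from different replicates — exactly the
statistical structure of pseudotime data, where each point is a
different cell.  Two network variants (100 864 and 157 364 trainable
parameters) differ in how training inputs are censored; predictions
average an ensemble of both.  See `docs/methods.md` for the full
specification of every component.

## Worked example

Generate a reduced corpus (50 models per class), train one member of
each network variant, and evaluate:

```
$ bifurcell generate-data --models-per-class 50 --seed 3 --out runs/data
wrote 4000 series to runs/data (classes: {'null': 1000, 'fold': 1000,
'transcritical': 1000, 'pitchfork': 1000})

$ bifurcell train --data runs/data --variant 2 --members 1 --scaled \
    --epochs-max 60 --batch-size 256 --seed 12 --out runs/m2
member 0: best val loss 0.2074 at epoch 54

$ bifurcell evaluate --model runs/m2 --data runs/data
multiclass F1 (macro): 0.938
binary F1 (bifurcation vs null): 0.965
row-normalized confusion matrix (rows = truth):
[[1.    0.    0.    0.   ]
 [0.    1.    0.    0.   ]
 [0.    0.    0.889 0.111]
 [0.139 0.    0.    0.861]]
```

The classes are ordered (null, fold, transcritical, pitchfork): this
reduced network separates null and fold perfectly on its 100-series test
split and confuses a fraction of transcritical/pitchfork series — the
two classes whose normal forms differ only in their leading
nonlinearity.

The macro F1 is over the four classes on the held-out test split (100
series); binary collapses the three bifurcation classes against null.
Applying a two-member ensemble (one per variant) to the two-gene GRN
pitchfork scenario — 20 replicate simulations, wrapped-diagonal
pseudotime series, Lowess-detrended, predictions on a grid before the
transition — the class probabilities shift from null-dominated to
pitchfork-dominated as the bifurcation nears, while on the null scenario
(same parameter ramp, fold removed) the null probability stays dominant
at every grid time:

```
pitchfork scenario, argmax per grid time:  0 0 0 0 0 0 3 3 3 3   (3 = pitchfork)
null scenario,      argmax per grid time:  0 0 0 0 0 0 0 0 0 0   (0 = null)
```

`bifurcell run-experiment --out runs/demo --seed 0` reproduces this
whole chain (corpus, training, three GRN scenario sweeps) and writes a
checksummed manifest; `bifurcell summarize runs/demo` tabulates it.

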