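# Methods

## Problem setting

Electronic-nose (e-nose) screening records the transient response of an
array of non-selective gas sensors exposed to a breath sample; the joint
response pattern fingerprints the volatile-organic-compound (VOC) profile,
which shifts with disease state. A recording is a matrix of
`n_channels x n_timesteps` response values (defaults 13 x 675, i.e. 8775
values) with a binary label (1 = disease / positive). Two properties of
the clinical use case drive the design of this package: sample sizes are
small (hundreds of subjects at best), and a missed diagnosis (false
negative) is far costlier than a false alarm, so classification
*sensitivity* matters more than raw accuracy.

The pipeline is: (1) compress each recording to a short feature vector
with a recurrent sequence autoencoder; (2) overproduce a pool of M CART
decision trees on bootstrap sub-samples of the training split;
(3) rank the trees on a held-out pruning split with a per-classifier
mark and keep the top T (ordering-based ensemble pruning); (4) predict
by majority vote of the kept trees.

## Voting margins

For a pool H of M classifiers and a pruning sample (x_i, y_i), the
margin

    margin(x_i) = (#correct votes - #incorrect votes) / M  in [-1, 1]

measures the confidence of the pool's majority decision; with odd M it
is never zero. NF_i^H = (#incorrect votes)/M is the pool's incorrect
fraction, and margin = 1 - 2 NF^H. Margin theory for voting ensembles
motivates preferring classifiers that are correct on low-margin
(hard) samples: they are the ones that can move the ensemble's decision.

## The MSM mark and its relatives

MSM (margin and sensitivity based measure) gives classifier h the mark

    MSM(h) = (1/N_Pr) * sum_i I(h(x_i) = y_i)
                             * I(margin(x_i) > theta)
                             * exp(y_i * NF_i^H)
                             * exp(-margin(x_i))

* `I(h(x_i) = y_i)` — only correct decisions earn anything.
* `I(margin > theta)`, theta in [-1, 0] — samples misclassified by almost
  the whole pool are presumed outliers and excluded; the comparison is
  strict. Default theta = -0.8 retains hard samples while dropping
  near-unanimous errors. theta = 0 drops every negative-margin sample;
  theta = -1 keeps everything except exact margin = -1 rows.
* `exp(-margin)` — continuous on all of [-1, 1] (unlike the logarithmic
  weights below), strictly decreasing: a correct vote on a harder sample
  is worth strictly more.
* `exp(y * NF^H)` — the *bonus* factor: only correct decisions on
  positive (disease) samples are amplified, and the amplification grows
  with how badly the pool does on the sample. This is what tilts
  selection toward high sensitivity. Disabling it (`bonus_enabled=False`)
  yields the MEP ablation; when the pruning split contains no positive
  samples MSM and MEP coincide exactly.

Competitor measures, implemented for comparison on the same vote-matrix
substrate:

* **UMEP** weights a correct decision by `-ln(margin)` and ignores
  samples with margin <= 0 entirely.
* **MDM** mixes a margin term `f_m = -ln(max(|margin|, eps))` with a
  diversity term `f_d = -ln(fraction of pool correct)`, trade-off alpha
  (default 0.5). The absolute value follows the measure's stated intent
  (low margin of either sign = important); eps defaults to 1/M, which
  also keeps f_m finite at margin 0 (the log form is undefined there).
  Both marks accumulate only over the classifier's own correct
  decisions; without that gate every classifier would receive the same
  mark and no ordering would exist.
* **SDAcc** is a *greedy forward-selection* mark, not an ordering: with S
  the current sub-ensemble and NT^S/NF^S its correct/incorrect vote
  fractions on the sample, a correct candidate earns +NF^S whether S is
  right (e11) or wrong (e10); a wrong candidate loses NF^S when S is
  right (e01) and NT^S when S is also wrong (e00). Selection seeds with
  the individually most accurate classifier (ties -> lowest index) and
  adds the candidate with the largest summed mark until |S| = T. The
  well-known weakness — a wrong classifier under e01 with an 80/20
  sub-ensemble and under e00 with a 20/80 sub-ensemble both score
  -0.2 — is reproduced by construction. During growth |S| passes through
  even sizes; a tied sub-ensemble vote is counted as an incorrect
  sub-ensemble decision (the conservative reading; nothing in the
  measure's definition fixes it).

Rankings use a stable descending sort with ties broken by ascending
classifier index, so results are deterministic. Natural logarithms are
used wherever a log appears; rankings are base-invariant.

## Ensemble machinery

The pool trains M (default 101, odd to preclude voting ties) CART trees
(Gini impurity, unlimited depth, min leaf 1) on independent bootstraps of
size round-half-up(0.3 x N_Tr), minimum 2, drawn with replacement.
Bootstrap class balance is not enforced, but a single-class draw is
redrawn up to 10 times before erroring. Per-tree seeds derive
deterministically from the master seed. Prediction over an odd subset is
strict majority vote; the fraction of members voting positive doubles as
the ranking score for AUC.

## Evaluation protocol

Experiments split the feature table 7:2:1 into training / pruning /
test parts, stratified per class with largest-remainder rounding, and
repeat over independent random splits (default 50 repetitions — a
Monte-Carlo protocol; a literal k-fold cannot produce three disjoint
parts). Metrics are accuracy, sensitivity TP/(TP+FN), specificity
TN/(FP+TN) and ties-half Mann-Whitney AUC. A metric with an empty
denominator (e.g. no positives in a tiny test part) is reported as
missing (NaN) and excluded from the mean/std aggregates, never coerced
to 0; `n_defined` records the contributing repetition count. The std is
the population (ddof = 0) std over repetitions, so a single repetition
reports 0.

The rank-scoring rule compares models across metrics: per metric the
best of n models gets n points, the runner-up n-1, and so on, tied
models sharing the mean of their would-be points; a model's score is the
average of its points over the metrics on which it is defined.

## Synthetic data

The curve generator emulates a chemiresistor array transient: per
channel, baseline + class-dependent amplitude x kinetic profile
(saturating rise with time constant T/6 until 0.6 T, then exponential
recovery with constant T/4) + i.i.d. Gaussian noise + a random linear
baseline drift. Time is treated as unitless indices.
`class_separation` scales the gap between class amplitude vectors;
`positive_noise_inflation` (>= 1) multiplies the positive class's noise,
making the disease class harder — the controllable ground truth for
sensitivity experiments. The generator does **not** model real sensor
chemistry, cross-sensitivity to humidity/temperature, nonlinear drift,
inter-subject covariates or acquisition artefacts, so passing tests
demonstrate algorithmic correctness and designed qualitative behaviour,
not clinical performance.

The vote-matrix generator produces correctness indicators directly: a
Gaussian copula with a shared per-sample latent difficulty gives each
column its configured marginal accuracy and each pair of columns the
configured correlation-inducing dependence — the substrate on which all
measures are defined, without training anything.

Study conditions used by the test suite, chosen once as realistic for
the problem class: pipeline tests run 4 channels x 30 steps, 60 samples
per class, class separation 0.8, noise sd 0.8, drift 0.05 (an
imperfectly separable regime); the sensitivity-lift experiment adds
positive_noise_inflation 1.5; near-optimality checks use 15 classifiers
with heterogeneous accuracies U(0.55, 0.85) and correlation 0.3 over 60
pruning samples; the autoencoder convergence check uses noiseless
rank-limited curves (4 x 48, latent 8, 200 epochs).

## Sequence autoencoder

The feature extractor is an encoder-decoder pair of gated recurrent
(GRU) layers, implemented directly in numpy with exact
backprop-through-time (verified against central finite differences) and
Adam. The encoder reads the standardised recording one time step at a
time (each step is the vector of all channel values); its final hidden
state is the latent code z (latent_dim, default 16, strictly smaller
than the flattened input — the model is a compression). The decoder is
conditioned on z both as its initial hidden state and as its input at
every step, and emits the sequence in forward time order through a
linear readout; reconstruction error is direction-agnostic, so the
simplest decoding order is used. Channels are standardised to zero
mean / unit variance over the training set before fitting (the
conventional preprocessing for mixed-scale sensor arrays), and training
history records the per-epoch mean reconstruction error in standardised
units, where the mean signal power is ~1. Defaults (latent 16, 100
epochs, Adam 1e-2, batch 16) are configuration values tuned for
small-sample convergence, not claims about any reference configuration.

## Numerical choices and degenerate inputs

* Margins are computed as 2 x fraction-correct - 1 (exact in floating
  point for the identity tests).
* `sdacc_mark` validates NT + NF = 1 to 1e-8.
* Sigmoid inputs are clipped at +/-500 to avoid overflow warnings.
* Channel stds below 1e-8 are replaced by 1 (constant channels).
* Splits that cannot give every part at least one sample of each class
  raise immediately (resampling cannot fix deterministic part sizes).

## Known limitations

* With perfectly exchangeable base classifiers (identical bagging
  settings, small pruning split), ordering by *any* prune-set mark —
  including plain accuracy — is statistically indistinguishable from
  keeping a random subset, and MSM's emphasis on hard samples can
  slightly overfit a noisy pruning split. The pruning-sanity property is
  therefore demonstrated where classifier quality genuinely varies
  (heterogeneous vote substrate with an independent test realisation);
  on real pools the advantage depends on how much true quality variation
  the overproduction step creates.
* The bonus factor's sensitivity lift is an average tendency; on any
  single split MSM and MEP frequently select identical sub-ensembles.
* The autoencoder is CPU-bound pure numpy: fine for hundreds of samples
  at clinical dimensions, not for large corpora.
* Binary labels only; the bonus factor generalises to multi-class
  reweighting in principle, but that extension is out of scope.
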